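"""Non-parametric two-factor inference on tract extension ratios.

The design is species x tract with repeated measures: every reference
("human"-role) subject contributes one extension ratio per (other species,
other subject, tract) combination.  Inference is by Freedman-Lane
permutation of reduced-model residuals, with the reference subject as the
exchangeability block (rows are only shuffled within a subject), and
family-wise error over the three contrasts (species main effect, tract main
effect, interaction) controlled by Westfall-Young min-p over the same
permutation stream.

This engine is a deliberate fixed-effects approximation of a mixed model:
subject intercepts are nuisance covariates and exchangeability is restricted
to within-subject shuffles.  A 'manly' scheme (permuting raw data within
blocks) is also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ArgumentError

DEFAULT_N_PERM = 5000

CONTRASTS = ("species", "tract", "interaction")

REQUIRED_COLUMNS = (
    "human_id", "other_id", "species", "tract", "hemisphere", "extension_ratio"
)


@dataclass
class PermutationResult:
    contrast: str
    f_stat: float
    df_num: int
    df_den: int
    p_uncorrected: float
    p_fwe: float
    n_permutations: int
    seed: int


def _dummies(labels: np.ndarray) -> tuple[np.ndarray, list]:
    """Sum-to-zero (effect) coding: levels-1 columns."""
    levels = sorted(pd.unique(labels))
    n = len(labels)
    cols = np.zeros((n, len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        cols[labels == lev, j] = 1.0
    cols[labels == levels[-1], :] = -1.0
    return cols, levels


def _interaction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    out = np.empty((n, a.shape[1] * b.shape[1]))
    k = 0
    for i in range(a.shape[1]):
        for j in range(b.shape[1]):
            out[:, k] = a[:, i] * b[:, j]
            k += 1
    return out


def extension_table(records: pd.DataFrame) -> pd.DataFrame:
    """Adapt a comparison-records table (``tract_name`` / ``species_pair``
    columns) to the factor naming the permutation engine expects."""
    out = records.rename(
        columns={"tract_name": "tract", "species_pair": "species"}
    )
    return out[list(REQUIRED_COLUMNS)]


def validate_table(table: pd.DataFrame, hemisphere: str) -> pd.DataFrame:
    """Check required columns and factorial balance for one hemisphere."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ArgumentError(f"table is missing column(s): {', '.join(missing)}")
    sub = table[table["hemisphere"] == hemisphere].reset_index(drop=True)
    if sub.empty:
        raise ArgumentError(f"no rows for hemisphere {hemisphere!r}")
    counts = sub.groupby(["human_id", "species", "tract"], sort=True).size()
    expected = counts.iloc[0]
    if (counts != expected).any():
        bad = counts[counts != expected].index.tolist()
        raise ArgumentError(f"unbalanced table; deviant cells: {bad[:10]}")
    full = (
        sub["human_id"].nunique() * sub["species"].nunique() * sub["tract"].nunique()
    )
    if len(counts) != full:
        raise ArgumentError("table is missing subject x species x tract cells")
    return sub


def _projection(X: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of X (pinv-based)."""
    return X @ np.linalg.pinv(X)


def two_factor_permutation(table: pd.DataFrame, hemisphere: str = "L",
                           n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                           scheme: str = "freedman-lane") -> list[PermutationResult]:
    """Permutation F-tests for species, tract and their interaction.

    Returns one :class:`PermutationResult` per contrast.  p-values use the
    (1 + exceedances) / (1 + n_perm) convention, so the smallest attainable
    p is 1/(n_perm + 1); FWE-corrected p-values are Westfall-Young min-p and
    never smaller than the uncorrected ones.
    """
    if n_perm < 99:
        raise ArgumentError("n_perm must be >= 99")
    if scheme not in ("freedman-lane", "manly"):
        raise ArgumentError("scheme must be 'freedman-lane' or 'manly'")
    sub = validate_table(table, hemisphere)
    y = sub["extension_ratio"].to_numpy(dtype=float)
    n = y.size

    species, _ = _dummies(sub["species"].to_numpy())
    tract, _ = _dummies(sub["tract"].to_numpy())
    inter = _interaction(species, tract)
    subject = pd.get_dummies(sub["human_id"]).to_numpy(dtype=float)

    parts = {"species": species, "tract": tract, "interaction": inter}
    X_full = np.column_stack([subject, species, tract, inter])
    H_full = _projection(X_full)
    R_full = np.eye(n) - H_full
    df_den = n - int(round(np.trace(H_full)))

    # permutation indices: shuffle rows within each reference-subject block
    rng = np.random.default_rng(seed)
    blocks = [np.flatnonzero(sub["human_id"] == s) for s in pd.unique(sub["human_id"])]
    perms = np.tile(np.arange(n), (n_perm, 1))
    for b in blocks:
        keys = rng.random((n_perm, b.size))
        perms[:, b] = b[np.argsort(keys, axis=1)]

    f_obs = {}
    f_perm = {}
    dfs = {}
    for name, cols in parts.items():
        others = [subject] + [parts[k] for k in parts if k != name]
        X_red = np.column_stack(others)
        H_red = _projection(X_red)
        M_hyp = H_full - H_red
        df_num = int(round(np.trace(M_hyp)))
        dfs[name] = df_num
        f_obs[name] = _f_stat(y, M_hyp, R_full, df_num, df_den)
        if scheme == "freedman-lane":
            base = (H_red @ y)
            resid = y - base
            Y = base[None, :] + resid[perms]
        else:  # manly: permute the raw data within blocks
            Y = y[perms]
        f_perm[name] = _f_stat_batch(Y, M_hyp, R_full, df_num, df_den)

    results = []
    # Westfall-Young: per-permutation minimum p across contrasts
    p_perm = {}
    for name in CONTRASTS:
        fp = f_perm[name]
        order = np.argsort(fp)
        ranks = np.empty(n_perm)
        # upper-tail proportion within the permutation distribution
        ranks[order] = np.arange(n_perm)
        p_perm[name] = (n_perm - ranks) / n_perm
    min_p = np.minimum.reduce([p_perm[name] for name in CONTRASTS])
    for name in CONTRASTS:
        fo = f_obs[name]
        p_unc = (1.0 + np.sum(f_perm[name] >= fo - 1e-12)) / (1.0 + n_perm)
        p_obs_equiv = (1.0 + np.sum(f_perm[name] >= fo - 1e-12)) / (1.0 + n_perm)
        p_fwe = (1.0 + np.sum(min_p <= p_obs_equiv + 1e-12)) / (1.0 + n_perm)
        p_fwe = max(p_fwe, p_unc)
        results.append(
            PermutationResult(
                contrast=name,
                f_stat=fo,
                df_num=dfs[name],
                df_den=df_den,
                p_uncorrected=float(p_unc),
                p_fwe=float(min(p_fwe, 1.0)),
                n_permutations=n_perm,
                seed=seed,
            )
        )
    return results


def _f_stat(y: np.ndarray, M_hyp: np.ndarray, R_full: np.ndarray,
            df_num: int, df_den: int) -> float:
    num = float(y @ M_hyp @ y)
    den = float(y @ R_full @ y)
    if den <= 1e-24 or num <= 1e-24:
        return 0.0
    return (num / df_num) / (den / df_den)


def _f_stat_batch(Y: np.ndarray, M_hyp: np.ndarray, R_full: np.ndarray,
                  df_num: int, df_den: int) -> np.ndarray:
    num = np.einsum("pi,ij,pj->p", Y, M_hyp, Y)
    den = np.einsum("pi,ij,pj->p", Y, R_full, Y)
    out = np.zeros(Y.shape[0])
    ok = (den > 1e-24) & (num > 1e-24)
    out[ok] = (num[ok] / df_num) / (den[ok] / df_den)
    return out


def results_frame(results: list[PermutationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
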