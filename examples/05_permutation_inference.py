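"""Two-factor permutation inference on tract extension ratios.

The extension-ratio table from the pairwise comparison has a species x
tract design with the reference subject as a repeated-measures block.
F statistics for the species main effect, tract main effect and their
interaction are tested by Freedman-Lane permutation of reduced-model
residuals within subject blocks, with family-wise error over the three
contrasts controlled by the min-p method.
"""

from tractshift import register_feature_maps, run_comparison, two_factor_permutation
from tractshift.stats import extension_table, results_frame
from tractshift.synth import make_study

study = make_study(seed=7)
ref = study.reference
regs = {
    name: register_feature_maps(sp.mesh, ref.mesh, sp.myelin, ref.myelin)
    for name, sp in study.others.items()
}
records = run_comparison(
    ref.cohorts,
    {name: sp.cohorts for name, sp in study.others.items()},
    regs,
)
results = two_factor_permutation(
    extension_table(records), hemisphere="L", n_perm=1000, seed=7
)
print(results_frame(results).to_string(index=False))
print(
    "\nthe significant species-by-tract interaction is the synthetic truth:\n"
    "only one tract extended, and by different amounts in the two species"
)
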