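"""Does turnover track environmental differences between plots?

Environmental distance = Euclidean distance in the leading principal
components (~90% variance) of the log-transformed, z-scored plot variables.
Pairwise turnover is residualized on geographic distance, then regressed on
environmental distance with a 5000-permutation test, per successional
stage; a 4-plot resampling repeats the test at equal sample size.
"""

import numpy as np

import phyloturn as pt
from phyloturn.env import stagewise_association, subsample_association

bundle = pt.generate_bundle(
    pt.ScenarioConfig(scenario="deep_filtering_late", seed=13)
)
rng = np.random.default_rng(2)

assoc = stagewise_association(bundle, n_perm=5000, rng=rng)
print(assoc[["scope", "slope", "r2", "p", "n_pairs"]].to_string(index=False))

sub = subsample_association(bundle, k=4, n_perm=499, rng=rng)
print("\n4-plot resampling (all C(n,4) subsets per stage):")
print(sub[["stage", "n_plots", "n_subsets", "mean_r2",
           "frac_significant"]].to_string(index=False))
print(
    "\nA positive slope with small p in the late stages only indicates that "
    "clade sorting along the gradient - not sample size - drives the "
    "turnover-environment association."
)
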