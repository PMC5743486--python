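"""Phylogenetic-depth profile: at which divergence times does turnover live?

Turnover is recomputed using only species pairs whose MRCA is younger than
each age threshold, and tested with partial randomizations confined to
clades younger than that threshold.  A signal only at large thresholds
means clustering among anciently diverged clades (deep niche conservatism).
"""

import numpy as np

import phyloturn as pt
from phyloturn.depth import depth_profile, threshold_grid
from phyloturn.synthetic import planted_split_age

bundle = pt.generate_bundle(
    pt.ScenarioConfig(scenario="deep_filtering_late", seed=11)
)
split = bundle.manifest.get("planted_split_age",
                            planted_split_age(bundle.pool))
grid = threshold_grid(30.0, 128.0, 20.0)
prof = depth_profile(bundle, grid=grid, R=199,
                     rng=np.random.default_rng(1), stages=["1", "5"])
print(f"planted clade split at {split:.1f} Myr\n")
print(prof[["stage", "threshold", "statistic", "ses", "significant",
            "n_pairs_retained"]].to_string(index=False))
print(
    "\nStage 5 (late succession) shows significant positive SES only at "
    "thresholds above the planted split age; stage 1 (neutral assembly) "
    "stays within the null band everywhere."
)
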