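"""Test turnover against the 1p tip-shuffle null model.

The shuffle permutes species names across the regional-pool phylogeny,
keeping community composition, richness and abundances fixed.  The
standardized effect size (SES) and rank p-value tell whether co-occurring
species are more related than expected (SES > 0, clustering) or less
(SES < 0, overdispersion).
"""

import numpy as np

import phyloturn as pt

bundle = pt.generate_bundle(
    pt.ScenarioConfig(scenario="deep_filtering_late", seed=11)
)
rng = np.random.default_rng(0)

for scope, stage in [("overall", None), ("within", None), ("between", None),
                     ("within", ("4", "5"))]:
    fn = pt.stage_statistic_fn(bundle, "presence", scope=scope, stage=stage)
    obs = fn(bundle.community_distances())
    null = pt.null_distribution(fn, bundle, R=999, rng=rng)
    res = pt.significance(obs, null)
    label = f"{scope}{' stages 4-5' if stage else ''}"
    print(f"{label:20s} PIst={res.observed:+.4f}  SES={res.ses:+6.2f}  "
          f"p={res.p_two_sided:.3f}  95% null CI=({res.ci_low:+.4f}, {res.ci_high:+.4f})")

print(
    "\nIn the deep-filtering scenario the late stages are assembled along "
    "the gradient, so the within-late-stage turnover shows the strongest "
    "clustering; the overall and between-stage statistics also sit above "
    "the null because pairs involving the filtered late-stage plots "
    "contribute to them too."
)
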