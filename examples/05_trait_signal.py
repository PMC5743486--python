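"""Phylogenetic signal in six functional traits.

Blomberg's K (1 under Brownian motion), Pagel's lambda (0 = no signal,
1 = Brownian) and Abouheif/Moran's I (positive = related species have
similar values), each with its test.  Significant signal in niche-related
traits is what licenses reading phylogenetic turnover as trait-based
sorting.
"""

import numpy as np

import phyloturn as pt
from phyloturn.signal import signal_table

bundle = pt.generate_bundle(pt.ScenarioConfig(seed=21))
table = signal_table(bundle.tree, bundle.traits, R=999,
                     rng=np.random.default_rng(3))
print(table.to_string(index=False))
print(
    "\nAll six traits are simulated as Brownian (conserved), so every "
    "metric detects significant signal: K near 1, lambda near 1, I > 0."
)
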