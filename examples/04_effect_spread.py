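"""Quantify how much stronger the proximal effect is than the distal one.

Builds a grid whose distal increments are drawn within ±0.5 kcal/mol (the
scale of real distal effects), tabulates the activation energy over the
proximal × distal grid and compares the spread down columns (proximal
variation) with the spread along rows (distal variation).
"""

import numpy as np

from ptbridge import (
    SyntheticConfig,
    build_matrix,
    canonical_patterns,
    effect_spread,
    generate_dataset,
    load_table3,
)

truth = load_table3()
rng = np.random.default_rng(7)
for pat in canonical_patterns(include_unsubstituted=False):
    truth.e_dist[pat] = float(rng.uniform(-0.5, 0.5))
    truth.s_dist[pat] = float(rng.uniform(-0.5, 0.5))

records = generate_dataset(SyntheticConfig(truth=truth, seed=7))
for group in ("para", "meta"):
    matrix = build_matrix(records, group, "activation_energy")
    spread = effect_spread(matrix)
    print(
        f"{group:5s} proximal SD {spread.proximal_sd_mean:.2f} ± "
        f"{spread.proximal_sd_sd:.2f} | distal SD "
        f"{spread.distal_sd_mean:.2f} ± {spread.distal_sd_sd:.2f} kcal/mol"
    )
# The proximal spread (variation across proximal patterns at fixed distal
# substitution) is several times the distal spread: substitution on the
# ring carrying the scanned bridge dominates the barrier.
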