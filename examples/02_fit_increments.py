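"""Fit substituent increments from a synthetic substitution grid.

Generates a noiseless para+meta grid from the packaged empirical
increment table (the ground truth), fits the additive model back and
shows that every increment is recovered exactly — the package's central
round-trip.
"""

from ptbridge import SyntheticConfig, fit_increments, generate_dataset, load_table3

truth = load_table3()
records = generate_dataset(SyntheticConfig(seed=1))
print(f"generated {len(records)} records (2 groups x 13 proximal x 13 distal)")

fitted = fit_increments(records)  # default: average over para and meta
frame = fitted.to_frame()
print(frame.to_string(index=False))

worst = max(
    abs(getattr(fitted, attr)[key] - value)
    for attr in ("e_sub", "e_ster", "s_sub", "s_ster")
    for key, value in getattr(truth, attr).items()
)
print(f"\nlargest deviation from the ground-truth table: {worst:.2e} kcal/mol")
# e_sub is the classical (resonance/induction) effect, shared by the 1/3
# and 2/4 position pairs; e_ster is the extra proximity effect of
# bridge-adjacent positions 1 and 4; s_* are the analogues for the
# second minimum. Exact recovery shows the fit inverts the model.
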