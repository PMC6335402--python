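"""Perinuclear vs peripheral organelle distribution.

Builds synthetic cells with a controllable peripheral placement bias, grows
the perinuclear band (the 20% of cytoplasm nearest the nucleus), and
quantifies each cell as the percentage of total cell intensity in the
periphery: 100 * (I_total - I_perinuclear) / I_total. Two conditions are
then compared with a t-test and a test of proportions.
"""

import cargoquant as cq

fractions = {"dispersed": [], "clustered": []}
for condition, bias in (("dispersed", 0.85), ("clustered", 0.45)):
    for cell in range(8):
        image, cell_mask, nucleus_mask, truth = cq.gen_cell_image(
            cyto_area=20000, nucleus_area=5000, peripheral_bias=bias, seed=10 * cell
            + (0 if condition == "dispersed" else 1),
        )
        masks = cq.perinuclear_mask(cell_mask, nucleus_mask, fraction=0.20)
        fractions[condition].append(cq.peripheral_fraction(image, masks))
    values = fractions[condition]
    print(f"{condition}: peripheral % per cell = {[round(v, 1) for v in values]}")

results = cq.compare_conditions(fractions)[("dispersed", "clustered")]
for kind, res in results.items():
    print(f"{kind}: statistic = {res.statistic:.2f}, p = {res.p_value:.2g} {res.stars}")
print(
    "Higher percentages mean organelles sit in the outer 80% of the "
    "cytoplasm; impaired inward (dynein) transport shifts cells upward."
)
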