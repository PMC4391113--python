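"""Analyse one simulated exam the way a Statpac-style printout would.

We build a normative model from simulated normal observers, create one
patient with the vigabatrin loss pattern (peripheral, nasal-predominant,
centrally sparing), measure them with the Full Threshold staircase, and
run the single-field analysis: total deviation, general height, pattern
deviation, probability maps, global indices and a grey-scale plot.

Run: python examples/02_single_field_analysis.py
"""

import numpy as np

import perimsim as ps
from perimsim import pipeline

model = ps.generate_normative_database(n_subjects=300, seed=11)
patient = ps.generate_vgb_field(model, age=36.0, severity=0.8, seed=11)
field, result = ps.simulate_exam(
    patient, "full_threshold", model, np.random.default_rng(11)
)
print(
    f"exam: {field.algorithm}, {result.total_presentations} presentations, "
    f"{field.duration_s / 60:.1f} min"
)

res = pipeline.analyze_field(field, model)
gi = res["indices"]
print(f"MS {gi.MS:.2f} dB   MD {gi.MD:.2f} dB   PSD {gi.PSD:.2f} dB")
print(f"general height: {res['gh']:.2f} dB")

# how many locations each probability map flags, by zone
grid = ps.GRID_30_2
for name in ("td_prob", "pd_prob"):
    cats = res[name].categories
    print(f"{name}: ", end="")
    for zone in ("inner", "middle", "outer"):
        n = int((cats[grid.zone_mask(zone)] >= ps.Category.P1).sum())
        print(f"{zone} {n:2d}/{grid.zone_mask(zone).sum()} at p<1%", end="  ")
    print()

label = ps.classify_severity(res["td_prob"])
print(f"severity classification: {label}")

img = ps.greyscale_render(field)
img.save("single_field.png")
print("wrote single_field.png (dark = low sensitivity; note the dark rim)")
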