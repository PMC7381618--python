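"""Predict T-tubule vs sarcolemmal membrane area across development.

Evaluates the closed-form geometric model at the four shipped fibre-size
presets (48 hpf, 5 dpf, 10 dpf, adult zebrafish), derives the membrane
growth rates between stages, and locates the fibre sizes at which the
internal T-system overtakes the plasma membrane.
"""

from ttubule import (
    STAGE_PRESETS,
    intercept_diameter,
    intercept_length,
    membrane_addition_rate,
    surface_summary,
)

stages = {p.stage_name: surface_summary(p.geometry) for p in STAGE_PRESETS}

print(f"{'stage':8s} {'TT (µm²)':>12s} {'SL (µm²)':>12s} {'TT fraction':>12s}")
for name, s in stages.items():
    print(f"{name:8s} {s.tt_area:12.1f} {s.sl_area:12.1f} {s.tt_fraction:12.2%}")

r1 = membrane_addition_rate(stages["48 hpf"], stages["5 dpf"], 4320.0)
r2 = membrane_addition_rate(stages["5 dpf"], stages["10 dpf"], 7200.0)
print(f"\nmembrane addition 48 hpf -> 5 dpf : {r1:.2f} µm²/min")
print(f"membrane addition 5 dpf -> 10 dpf : {r2:.2f} µm²/min")

# Where do the two membrane systems have equal area?  For a 40 µm-diameter
# fibre the crossing sits near L = 36 µm; an adult-length (580 µm) fibre
# crosses at D ≈ 26.6 µm — adult fibres are past it, embryonic ones are not.
print(f"\nequal-area length at D = 40 µm   : {intercept_length(40.0):.2f} µm")
print(f"equal-area diameter at L = 580 µm: {intercept_diameter(580.0):.2f} µm")
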