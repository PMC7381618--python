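"""Measure T-tubule perturbation as a stripe-amplitude percentage.

Generates a scene in which the expressing cell's tubule contrast is halved
(perturbation factor 0.5) next to an untouched wildtype neighbour, places a
box over an array of eight tubules in each cell, and reports the expressing
amplitude as a percentage of the wildtype — the internal-control statistic.
Also estimates the inter-tubule spacing from the wildtype profile.
"""

from ttubule import (
    SceneParams,
    box_profile,
    estimate_spacing,
    make_fluorescence_scene,
    perturbation_percent,
)

params = SceneParams(seed=4, perturbation_factor=0.5)
img, truth = make_fluorescence_scene(params)

res = perturbation_percent(img, "caax", truth.box("expressing"), truth.box("wildtype"))
print(f"amplitude, expressing cell : {res.amplitude_expressing:8.2f} counts")
print(f"amplitude, wildtype cell   : {res.amplitude_wildtype:8.2f} counts")
print(f"percent of wildtype        : {res.percent_of_wildtype:8.1f} %  (true 50%)")

trace = box_profile(img, "caax", truth.box("wildtype"))
print(f"inter-tubule spacing       : {estimate_spacing(trace):8.3f} µm (true 1.900)")
print("\nA percentage near 50 shows the halved tubule contrast is recovered")
print("despite Poisson + read noise; the spacing matches the sarcomere length.")
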