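"""Organoid size morphometry on a simulated brightfield microwell array.

Renders one 4x4 array of organoids (diameters drawn from the default
morphology model: normal, mean 235 µm, SD 25 µm), segments it, and prints
the per-experiment size summary. The mean/SD recover the generative model;
CV quantifies intra-experiment size homogeneity.
"""

from bbbarray import arraymorph, simdata

config = simdata.SimulationConfig(n_rows=4, n_cols=4, occupancy=1.0)
image, truth = simdata.render_brightfield_array(config, seed=1)

detections = arraymorph.segment_brightfield(image, config.pixel_size_um)
summary = arraymorph.summarize_sizes({"experiment_1": detections})

print(summary.per_experiment.round(2).to_string())
print(f"\ntrue mean diameter in this array: {truth.true_diameter_um.mean():.1f} µm")
print(
    "n organoids segmented, their mean/SD diameter (µm) and CV (%); the\n"
    "estimated mean tracks the simulated truth to within a pixel or two."
)
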