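"""Core-intensity quantification of one confocal organoid stack.

Renders a single shuttle-treated organoid (100 nM, 4 h), then runs the full
measurement chain: find the organoid bottom, select the core window (25 µm
above the bottom, 3.5 µm deep), maximum-intensity project, segment the
cross-section on the nuclei channel, shrink the mask to 75% of its area and
measure the mean tracer intensity inside that core ROI.
"""

from bbbarray import corequant, simdata

config = simdata.SimulationConfig()
params = simdata.default_transport_params("human_shuttle")
condition = simdata.Condition("human_shuttle", "shuttle", dose_nM=100.0, time_min=240.0)

stack, truth = simdata.render_confocal_stack(
    config.geometry(235.0), params, condition, config, seed=11
)

bottom = corequant.find_organoid_bottom(stack)
measurement = corequant.measure_stack(stack)

print(f"organoid bottom slice:   {bottom}")
print(f"core ROI area fraction:  {measurement.achieved_fraction:.3f} (target 0.75)")
print(f"measured core mean:      {measurement.core_mean:.1f} AU")
print(f"noise-free truth:        {truth['true_core_mean']:.1f} AU")
print(
    "\nThe measured mean sits slightly above truth: a maximum-intensity\n"
    "projection of noisy, punctate voxels is upward-biased, exactly as in\n"
    "the physical assay; group comparisons are unaffected."
)
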