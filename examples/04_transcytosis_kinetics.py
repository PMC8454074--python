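"""Transcytosis kinetics: one-phase association fit with a 95% band.

Simulates per-organoid core intensities of a transferrin-receptor shuttle
(100 nM) at the six standard incubation times, fits
I(t) = B + A(1 - exp(-k t)) on the individual organoid points, and reports
the rate, the 95% confidence band at a few times, and the time to reach 95%
of the plateau (steady state).
"""

import numpy as np

from bbbarray import simdata, transport_fit

params = simdata.TransportParams(baseline=10.0, alpha=1.0, k_rate=0.05)
data = simdata.simulate_core_measurements(
    params,
    "shuttle",
    times=[15, 30, 60, 120, 240, 360],
    doses=100.0,
    n_per_point=50,
    noise_cv=0.1,
    rng=np.random.default_rng(7),
)

fit = transport_fit.fit_association(data["time_min"], data["core_mean"])
band = transport_fit.confidence_band(fit, [30.0, 60.0, 240.0])
t95 = transport_fit.time_to_steady_state(fit, 0.95)

print(f"baseline  B = {fit.baseline:6.2f} AU")
print(f"amplitude A = {fit.amplitude:6.2f} AU")
print(f"rate      k = {fit.k:6.4f} /min")
for t, lo, mid, hi in zip(band.grid, band.lower, band.fitted, band.upper):
    print(f"I({t:5.0f} min) = {mid:6.1f} AU, 95% band [{lo:6.1f}, {hi:6.1f}]")
print(f"time to 95% of plateau: {t95:.1f} min")
print(
    "\nThe generator used k = 0.05/min, so the true steady-state time is\n"
    "ln(20)/0.05 = 59.9 min; the fit recovers it from noisy organoid data."
)
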