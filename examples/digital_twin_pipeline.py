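"""Full digital-twin chain on grouped voxel-like signals.

Forty channels in four areas are generated from five slow oscillatory
latent modes (periods 15-50 s) plus sensor noise, low-pass filtered,
compressed area-by-area with block PCA, and handed to a stochastic
reservoir.  The pipeline tunes the endogenous noise, trains the
readout, runs the twin autonomously, and scores it against the data:
forecast correlation, functional-connectivity (FC) correlation and the
Jensen-Shannon distance (JSd) between FC-dynamics distributions.
"""

import numpy as np

from lintwin import lowpass_filter, make_grouped_mode_signals, run_twin_pipeline

rng = np.random.default_rng(0)
poles = np.array([-0.005 + 0.17j, -0.008 + 0.28j, -0.006 + 0.12j,
                  -0.01 + 0.4j, -0.012 + 0.22j])
areas = np.repeat([f"area{i}" for i in range(4)], 10)
loading = 0.2 * rng.standard_normal((40, 5))
for i in range(4):
    loading[10 * i : 10 * (i + 1), i % 5] += 1.0

dt = 2.5  # imaging-style sampling interval, s
_, X, _ = make_grouped_mode_signals(
    poles, loading, areas, duration=1600.0, dt=dt, seed=3, measurement_noise=0.03
)
X = lowpass_filter(X, 0.5, dt)

report = run_twin_pipeline(
    X, areas, dt=dt, seed=0, n_units=300,
    gammas=np.array([1.0, 1.8, 3.0, 5.0, 8.0]), n_tune_realizations=3,
)

print(f"compressed observables      : {report['n_observables']} "
      f"(from {X.shape[0]} channels, {report['components_per_area']})")
print(f"selected noise intensity    : {report['gamma_opt']:g}")
print(f"forecast correlation        : {report['accuracy']:.3f}")
print(f"FC correlation with data    : {report['fc_corr']:.3f}")
print(f"FCD Jensen-Shannon distance : {report['jsd']:.3f}")
print(f"relevant modes in the twin  : {report['n_relevant_modes']}")
if report["spectrum_regression"]:
    sr = report["spectrum_regression"]
    print(f"pole-line regression        : slope {sr['slope']:.3f}, "
          f"R^2 {sr['r_squared']:.3f}")
print(
    "\nThe twin reproduces the spatial correlation structure (FC) of the\n"
    "channels; the FCD distance reflects how well its temporal FC\n"
    "fluctuations match the data (values near the sampling floor ~0.1-0.2\n"
    "indicate distributions as close as two independent realizations)."
)
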