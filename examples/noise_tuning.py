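"""Tune the endogenous noise of a stochastic reservoir twin.

Scans the unit-wise white-noise intensity gamma and reports, for each
level: the maximum real part of the learned poles (stability margin),
the forecast correlation on the held-out 20% of the data, and the
mismatch between the stochastic twin's long-run covariance and the
training covariance.  Too little noise leaves marginally unstable
modes; too much over-damps the model.  The useful level sits in the
stable region next to the stability boundary.
"""

import numpy as np

from lintwin import (
    MouSpec,
    lowpass_filter,
    make_reservoir,
    random_stable_generator,
    select_gamma,
    simulate_mou,
    tune_noise,
)

A = random_stable_generator(d=10, slowest=-0.2, seed=0)
dt = 0.05
_, X = simulate_mou(MouSpec(A, 1.0, dt, 1250, seed=1))
Xf = lowpass_filter(X, 1.0, dt)

model = make_reservoir(N=300, M=10, rho=0.5, tau=1.0, gin=1.0, seed=0)
report = tune_noise(
    model, Xf, dt, np.logspace(-5, 0.5, 12), n_realizations=5, seed=7
)
print(report.to_frame().to_string(index=False, float_format=lambda v: f"{v:10.4g}"))
gamma = select_gamma(report)
print(f"\nselected gamma: {gamma:g}")
print(
    "\nReading the table: max_re_pole_mean decreases as gamma grows (noise\n"
    "acts as regularization, pushing poles left); rows flagged unstable\n"
    "have poles significantly right of the imaginary axis; the selected\n"
    "gamma is the best forecaster inside the contiguous stable tail."
)
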