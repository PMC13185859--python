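"""Spectral recovery from filtered data: stochastic reservoir vs Hankel DMD.

A 10-D Ornstein-Uhlenbeck process with known generator is simulated and
zero-phase low-pass filtered at 1 rad/s (the standard preprocessing in
resting-state imaging pipelines).  Hankel DMD estimates the generator
spectrum well on raw data, but on filtered data its decay-rate
estimates collapse toward zero (a Fourier-like artefact).  A reservoir
trained with tuned endogenous noise keeps the decay structure.

Scaled-down run (5 realizations) so the script finishes in ~1 minute.
"""

from lintwin import run_spectral_comparison

res = run_spectral_comparison(seed=1, n_realizations=5, gamma=0.3)

truth = res["truth_slowest3"]
print("ground-truth slowest 3 eigenvalues (1/s):")
for ev in truth:
    print(f"  {ev:+.3f}")
print(f"\nreservoir noise intensity gamma = {res['gamma']}")
print("\nmean |Re| error of the slowest 3 modes (10,000-sample filtered data):")
f = res["filtered"][10000]
print(f"  Hankel DMD : {f['hdmd_re_mean']:.3f}")
print(f"  reservoir  : {f['lrnn_re_mean']:.3f}")
print(f"\nHDMD's own slowest-3 mean |Re| after filtering: "
      f"{f['hdmd_slow_re_mean']:.3f}  (truth {abs(truth.real).mean():.3f})")
print(
    "\nFiltering has pushed the DMD poles onto the imaginary axis — the\n"
    "dissipative structure is lost — while the noisy reservoir, forced to\n"
    "behave as a stable stochastic surrogate, still reports decay rates\n"
    "close to the true ones."
)
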