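"""Copy a nonlinear system with a linear reservoir and read off its spectrum.

A quadratically coupled system (5 linear variables x, 10 nonlinear
variables y driven by x*x) is exactly linearizable: its finite Koopman
generator has 20 eigenvalues.  A 500-unit linear reservoir trained on
the 15 observables [x; y] recovers exactly those 20 modes: the mode
count and the pole positions are read directly off the learned matrix.
"""

import numpy as np

from lintwin import run_nonlinear_benchmark

report = run_nonlinear_benchmark(seed=0)

print(f"observables fed to the reservoir : {report['n_observables']}")
print(f"linearized system dimension      : {report['linearized_dimension']}")
print(f"relevant modes found (>5% of max): {report['n_relevant_modes']}")
print(f"pole error of the top 20 modes   : {report['pole_mae_top_modes']:.4f}")
print()
print("slowest recovered poles vs ground truth (1/s):")
truth = sorted(report["truth_eigenvalues"], key=lambda z: -z.real)
top = np.argsort(report["relevance"])[::-1][:20]
poles = report["poles"][top]
for ev in truth[:5]:
    if ev.imag < 0:
        continue
    nearest = poles[np.argmin(np.abs(poles - ev))]
    print(f"  truth {ev:+.3f}   estimated {nearest:+.3f}")
print()
print(
    "The reservoir never sees the hidden quadratic observables z = x*x,\n"
    "yet the closed-loop spectrum contains their modes (eigenvalues 2*Cx):\n"
    "the linear network has built a finite Koopman representation of a\n"
    "nonlinear system purely from data."
)
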