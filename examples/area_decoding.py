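"""Discriminate channel groups by their spectral fingerprints.

Each "area" is characterised by a frequency vector: the histogram of
mode frequencies weighted by the modes' relevance to that area's
channels.  On a synthetic panel where areas prefer different latent
frequencies, linear discriminant analysis separates the areas and
minimum-norm least-squares decoders identify which frequencies carry
the discriminative information.
"""

import numpy as np

from lintwin import FeatureTable, fit_decoders, lda_project, one_hot

rng = np.random.default_rng(0)

# synthetic frequency-vector panel: 4 areas x 60 samples, 40 bins;
# each area has a characteristic spectral peak plus shared background
D, per_area, n_areas = 40, 60, 4
centers = [8, 16, 24, 32]
F, labels = [], []
background = np.exp(-0.5 * ((np.arange(D) - 20) / 12.0) ** 2)
for a in range(n_areas):
    peak = np.exp(-0.5 * ((np.arange(D) - centers[a]) / 2.0) ** 2)
    for _ in range(per_area):
        f = background + 1.5 * peak + 0.25 * rng.standard_normal(D)
        F.append(f)
        labels.append(f"area{a}")
F = np.array(F).T
labels = np.array(labels)

L, projected = lda_project(F, labels, k=3)
sil = []
for a in range(n_areas):
    own = projected[0, labels == f"area{a}"]
    rest = projected[0, labels != f"area{a}"]
    sil.append(abs(own.mean() - rest.mean()) / (own.std() + rest.std()))
print(f"LDA latent-1 class separation (mean over areas): {np.mean(sil):.2f}")

Y, names = one_hot(labels)
dec = fit_decoders(FeatureTable(F, Y, names))
print("\nper-area decoder accuracy (training panel):")
for name, acc in zip(names, dec.per_class_accuracy):
    print(f"  {name}: {acc:.2f}")
print(f"chance level: {1 / n_areas:.2f}")
print("\ndecoder peak bin vs area's true spectral peak:")
for a, name in enumerate(names):
    print(f"  {name}: decoder argmax bin {np.argmax(dec.Wdec[a])}, true {centers[a]}")
print(
    "\nDecoders weight exactly the frequencies that make an area unique,\n"
    "even though the raw frequency vectors share a broad common profile."
)
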