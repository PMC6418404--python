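"""Difference spectra, PCA separation and random-forest band ranking.

Three escalating views of the same preprocessed mean-spectrum table:
pointwise group differences, unsupervised projection, and supervised
feature importance.
"""

import numpy as np
from sklearn.metrics import silhouette_score

from thermospec import (
    GROUPS,
    SyntheticConfig,
    build_mean_spectrum_table,
    difference_spectra,
    fit_pca,
    fit_random_forest,
    generate_study,
    group_mean_spectrum,
    intensity_at,
    preprocess_dataset,
    rank_wavenumbers_by_gini,
)

ds = generate_study(SyntheticConfig(seed=1))
means = build_mean_spectrum_table(preprocess_dataset(ds), k=10, seed=2)

by_group = {
    g: group_mean_spectrum([s for s in means if s.meta["group"] == g])
    for g in GROUPS
}
diffs = difference_spectra(by_group)
print("difference-spectrum amplitudes at reporter bands:")
for name, d in diffs.items():
    print(f"  {name:28s} 2920: {intensity_at(d, 2920.0):+.3f}   "
          f"1622: {intensity_at(d, 1622.0):+.3f}   "
          f"1126: {intensity_at(d, 1126.0):+.3f}")
print("(positive = first-named group absorbs more at that band)")

print("\npairwise PCA separation on the first three components:")
for pair in (("hypothermia", "normothermia"),
             ("hyperthermia", "normothermia"),
             ("hypothermia", "hyperthermia")):
    sub = means.subset(pair)
    res = fit_pca(sub.to_matrix(), n_components=3)
    sil = silhouette_score(res.scores, sub.groups())
    print(f"  {pair[0]:12s} vs {pair[1]:12s} silhouette {sil:.2f}  "
          f"PC-1 explains {res.explained_variance_ratio[0]:.0%}")
print("(silhouette > 0 means the two groups form separated score clusters)")

axis = means.spectra[0].axis.values
imp = fit_random_forest(means.to_matrix(), means.groups(), axis,
                        n_trees=500, seed=3)
top = rank_wavenumbers_by_gini(imp, 10)
print(f"\nrandom forest OOB accuracy: {imp.oob_accuracy:.3f}")
print(f"top-10 Gini wavenumbers (cm^-1): {np.sort(top).astype(int)}")
print("(the nucleic-acid bands near 1122 and 972 cm^-1 dominate the "
      "three-group discrimination)")
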