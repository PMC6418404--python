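"""Exploratory chemometrics: mean spectra, difference spectra, PCA, RF.

The unit of multivariate analysis is the *mean spectrum*: within each
image, pixels are randomly partitioned (seeded) into disjoint groups of
ten and averaged, so no pixel contributes to more than one observation.
With the default study geometry this yields 272/272/208 mean spectra for
the hypothermia/hyperthermia/normothermia groups.

PCA is computed on the column-mean-centered mean-spectrum matrix by SVD,
with a deterministic sign convention (each loading's largest-magnitude
element is positive).  Random-forest Gini importance ranks wavenumbers by
their contribution to the three-group discrimination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .core import GROUPS, Spectrum, SpectralDataset, SpectralImage

__all__ = [
    "MeanSpectrumSet",
    "PCAResult",
    "GiniImportance",
    "average_disjoint_groups",
    "build_mean_spectrum_table",
    "group_mean_spectrum",
    "difference_spectra",
    "fit_pca",
    "fit_random_forest",
    "rank_wavenumbers_by_gini",
]


@dataclass
class MeanSpectrumSet:
    """Mean spectra with their provenance (source image, member pixels)."""

    spectra: list[Spectrum]

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    def groups(self) -> list[str]:
        return [s.meta["group"] for s in self.spectra]

    def to_matrix(self) -> np.ndarray:
        return np.vstack([s.absorbance for s in self.spectra])

    def subset(self, groups) -> "MeanSpectrumSet":
        keep = set(groups)
        return MeanSpectrumSet([s for s in self.spectra if s.meta["group"] in keep])

    def counts(self) -> dict[str, int]:
        c = {g: 0 for g in GROUPS}
        for s in self.spectra:
            c[s.meta["group"]] += 1
        return c


def average_disjoint_groups(img: SpectralImage, k: int = 10,
                            seed: int = 0) -> MeanSpectrumSet:
    """Average seeded disjoint random groups of ``k`` pixels of one image.

    Pixels are permuted, split into floor(n/k) groups of exactly k (any
    remainder discarded, never reused), and each group is averaged into
    one mean spectrum inheriting the image's sample_id and group label.
    """
    n = len(img.spectra)
    if k <= 0:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"image {img.sample_id} has {n} < k={k} spectra")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    Y = img.to_matrix()
    out = []
    for g in range(n // k):
        members = np.sort(perm[g * k:(g + 1) * k])
        out.append(
            Spectrum(
                img.axis,
                Y[members].mean(axis=0),
                {
                    "sample_id": img.sample_id,
                    "group": img.group,
                    "member_pixels": members.tolist(),
                },
            )
        )
    return MeanSpectrumSet(out)


def build_mean_spectrum_table(ds: SpectralDataset, k: int = 10,
                              seed: int = 0) -> MeanSpectrumSet:
    """Concatenate per-image disjoint-group averaging over a dataset.

    Each image's partition seed is derived from (seed, sample_id), so the
    partition is reproducible per image and independent of dataset order.
    """
    import zlib

    spectra: list[Spectrum] = []
    for img in ds:
        img_seed = np.random.SeedSequence(
            [seed, zlib.crc32(img.sample_id.encode())]
        ).generate_state(1)[0]
        sub = average_disjoint_groups(img, k=k, seed=int(img_seed))
        spectra.extend(sub.spectra)
    return MeanSpectrumSet(spectra)


def group_mean_spectrum(spectra) -> Spectrum:
    """Pointwise mean of spectra sharing a group label."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot average an empty set of spectra")
    mean = np.mean([s.absorbance for s in spectra], axis=0)
    meta = {"group": spectra[0].meta.get("group"), "n": len(spectra)}
    return Spectrum(spectra[0].axis, mean, meta)


def difference_spectra(means: dict[str, Spectrum]) -> dict[str, Spectrum]:
    """The three signed group-mean differences.

    Returns ``hypothermia-normothermia``, ``hyperthermia-normothermia``
    and ``hypothermia-hyperthermia`` (in that conventional order).
    """
    for g in GROUPS:
        if g not in means:
            raise ValueError(f"missing group mean for {g!r}")
    pairs = [
        ("hypothermia", "normothermia"),
        ("hyperthermia", "normothermia"),
        ("hypothermia", "hyperthermia"),
    ]
    out = {}
    for a, b in pairs:
        name = f"{a}-{b}"
        out[name] = Spectrum(
            means[a].axis,
            means[a].absorbance - means[b].absorbance,
            {"difference": name},
        )
    return out


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a PCA."""

    scores: np.ndarray  # (n_obs, n_components)
    loadings: np.ndarray  # (n_components, n_wavenumbers)
    explained_variance_ratio: np.ndarray
    mean: np.ndarray
    component_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.component_labels:
            self.component_labels = [
                f"PC-{i + 1}" for i in range(self.loadings.shape[0])
            ]


def fit_pca(X: np.ndarray, n_components: int = 3) -> PCAResult:
    """PCA of the column-mean-centered matrix via SVD.

    Deterministic up to the stated sign convention: each loading's
    largest-magnitude element is made positive (scores flipped to match).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 observations")
    if not 1 <= n_components <= min(X.shape):
        raise ValueError(
            f"n_components must be in [1, {min(X.shape)}], got {n_components}"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s**2))
    # guard: identical observations leave only rounding-noise variance
    degenerate = total_var <= 1e-20 * max(1.0, float(np.sum(X**2)))
    evr = (np.zeros(n_components) if degenerate
           else s[:n_components] ** 2 / total_var)
    loadings = Vt[:n_components]
    scores = U[:, :n_components] * s[:n_components]
    # sign convention: largest-|.| element of each loading positive
    for i in range(n_components):
        j = int(np.argmax(np.abs(loadings[i])))
        if loadings[i, j] < 0:
            loadings[i] = -loadings[i]
            scores[:, i] = -scores[:, i]
    return PCAResult(scores, loadings, np.asarray(evr), mean)


@dataclass
class GiniImportance:
    """Per-wavenumber mean decrease in Gini impurity from a random forest."""

    wavenumbers: np.ndarray
    importance: np.ndarray
    n_trees: int
    seed: int
    oob_accuracy: float

    def __post_init__(self) -> None:
        if self.wavenumbers.shape != self.importance.shape:
            raise ValueError("wavenumbers and importance must align")
        if np.any(self.importance < 0):
            raise ValueError("Gini importances must be >= 0")


def fit_random_forest(X: np.ndarray, labels, wavenumbers: np.ndarray,
                      n_trees: int = 500, seed: int = 0) -> GiniImportance:
    """Train a classification forest and extract Gini importances.

    Uses sqrt(p) features per split and unlimited depth (the conventions
    of the R randomForest package); importances are impurity decreases
    normalized to sum 1 over wavenumbers.  Out-of-bag accuracy is
    reported as a diagnostic.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("random forest needs >= 2 classes")
    if counts.min() < 5:
        raise ValueError("each class needs >= 5 observations")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small OOB samples warn harmlessly
        rf.fit(np.asarray(X, dtype=float), labels)
    return GiniImportance(
        wavenumbers=np.asarray(wavenumbers, dtype=float),
        importance=rf.feature_importances_,
        n_trees=n_trees,
        seed=seed,
        oob_accuracy=float(rf.oob_score_),
    )


def rank_wavenumbers_by_gini(imp: GiniImportance, top_n: int = 10) -> np.ndarray:
    """Wavenumbers sorted by descending importance (ties: ascending cm^-1)."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    n = imp.wavenumbers.size
    if top_n > n:
        warnings.warn(
            f"top_n={top_n} exceeds the {n} available wavenumbers; clamping"
        )
        top_n = n
    order = np.lexsort((imp.wavenumbers, -imp.importance))
    return imp.wavenumbers[order[:top_n]]
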