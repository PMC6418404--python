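"""Preprocessing chain: anchored baseline, EMSC, region reduction.

The chain runs in the fixed order baseline -> EMSC -> region reduction:

1. a 4-point piecewise-linear baseline through the absorbances at
   3100, 2800, 1800 and 899 cm^-1 is subtracted from each spectrum;
2. extended multiplicative signal correction (EMSC) regresses each
   spectrum on a reference spectrum plus polynomial wavenumber terms and
   rescales it, removing residual additive baselines and multiplicative
   scatter while normalizing the chemical signal;
3. the axis is reduced to the lipid (3100-2800 cm^-1) and fingerprint
   (1800-900 cm^-1) regions.

The EMSC reference is the pointwise mean of all baseline-corrected spectra
in the dataset (the conventional choice), computed once per dataset.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import (
    Spectrum,
    SpectralDataset,
    SpectralRangeError,
    WavenumberAxis,
    intensity_at,
)

__all__ = [
    "DEFAULT_ANCHORS",
    "DEFAULT_REGIONS",
    "EMSCModel",
    "DegenerateFitError",
    "subtract_anchored_baseline",
    "fit_emsc_reference",
    "apply_emsc",
    "select_regions",
    "preprocess_dataset",
]

DEFAULT_ANCHORS: tuple[float, ...] = (3100.0, 2800.0, 1800.0, 899.0)
DEFAULT_REGIONS: tuple[tuple[float, float], ...] = ((2800.0, 3100.0), (900.0, 1800.0))


class DegenerateFitError(ValueError):
    """EMSC fit produced a near-zero multiplicative coefficient.

    The spectrum carries essentially no reference-like signal, so dividing
    by ``b`` would be meaningless.
    """


@dataclass
class EMSCModel:
    """EMSC reference spectrum and polynomial degree.

    The correction fits s(w) ~ a + b*m(w) + sum_j d_j * wt^j with wt the
    wavenumber rescaled to [-1, 1], then returns (s - a - sum d_j wt^j)/b.
    """

    reference: Spectrum
    degree: int = 2

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("polynomial degree must be >= 0")
        if not np.any(self.reference.absorbance):
            raise ValueError("EMSC reference must not be identically zero")

    def design_matrix(self) -> np.ndarray:
        """Columns: 1, m(w), wt, wt^2, ... wt^degree."""
        w = self.reference.axis.values
        wt = 2.0 * (w - w.min()) / (w.max() - w.min()) - 1.0
        cols = [np.ones_like(w), self.reference.absorbance]
        cols += [wt**j for j in range(1, self.degree + 1)]
        return np.column_stack(cols)


def subtract_anchored_baseline(
    s: Spectrum, anchors: Sequence[float] = DEFAULT_ANCHORS
) -> Spectrum:
    """Subtract the piecewise-linear baseline through the anchor points.

    Anchor absorbances are read by linear interpolation (anchors need not
    be grid points); beyond the outer anchors the end segments are
    extended linearly.  The output is (numerically) zero at every anchor
    and the subtraction is exactly idempotent.
    """
    if len(anchors) < 2:
        raise ValueError("need at least two baseline anchors")
    axis = s.axis
    for a in anchors:
        if not (axis.min <= a <= axis.max):
            raise SpectralRangeError(
                f"baseline anchor {a} outside axis range [{axis.min}, {axis.max}]"
            )
    anchors_asc = np.sort(np.asarray(anchors, dtype=float))
    heights = np.array([intensity_at(s, a) for a in anchors_asc])
    baseline = _piecewise_linear(axis.values, anchors_asc, heights)
    return s.with_absorbance(s.absorbance - baseline)


def _piecewise_linear(w: np.ndarray, anchors_asc: np.ndarray,
                      heights: np.ndarray) -> np.ndarray:
    """Interpolant through the anchors, end segments extended linearly.

    Linear (not constant) extension keeps the baseline kink-free at
    off-grid outer anchors, which makes the subtraction exactly
    idempotent; beyond the outer anchors the choice is immaterial since
    region reduction discards those wavenumbers.
    """
    out = np.interp(w, anchors_asc, heights)
    lo_slope = (heights[1] - heights[0]) / (anchors_asc[1] - anchors_asc[0])
    hi_slope = (heights[-1] - heights[-2]) / (anchors_asc[-1] - anchors_asc[-2])
    below = w < anchors_asc[0]
    above = w > anchors_asc[-1]
    out[below] = heights[0] + lo_slope * (w[below] - anchors_asc[0])
    out[above] = heights[-1] + hi_slope * (w[above] - anchors_asc[-1])
    return out


def fit_emsc_reference(
    spectra: SpectralDataset | Iterable[Spectrum],
) -> Spectrum:
    """Pointwise mean spectrum of all inputs (the EMSC reference)."""
    if isinstance(spectra, SpectralDataset):
        spectra = [s for img in spectra for s in img.spectra]
    else:
        spectra = list(spectra)
    if not spectra:
        raise ValueError("cannot fit an EMSC reference from no spectra")
    axis = spectra[0].axis
    for s in spectra[1:]:
        if not np.array_equal(s.axis.values, axis.values):
            raise ValueError("all spectra must share one axis")
    mean = np.mean([s.absorbance for s in spectra], axis=0)
    return Spectrum(axis, mean, {"role": "emsc_reference", "n": len(spectra)})


def apply_emsc(s: Spectrum, model: EMSCModel) -> tuple[Spectrum, np.ndarray]:
    """Correct one spectrum; returns (corrected, coefficients [a, b, d1..]).

    Raises :class:`DegenerateFitError` when |b| < 1e-8.
    """
    if not np.array_equal(s.axis.values, model.reference.axis.values):
        raise ValueError("spectrum axis does not match EMSC reference axis")
    X = model.design_matrix()
    coef, *_ = np.linalg.lstsq(X, s.absorbance, rcond=None)
    b = coef[1]
    if abs(b) < 1e-8:
        raise DegenerateFitError(
            "EMSC multiplicative coefficient ~ 0: spectrum carries no "
            "reference-like signal"
        )
    # nuisance = a + d·poly, computed as (full fit) - b*m
    nuisance = X @ coef - b * model.reference.absorbance
    corrected = s.with_absorbance((s.absorbance - nuisance) / b)
    return corrected, coef


def _apply_emsc_matrix(Y: np.ndarray, model: EMSCModel) -> np.ndarray:
    """Vectorized EMSC over a (n_spectra, n_wavenumbers) matrix."""
    X = model.design_matrix()
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (n_terms, n_spectra)
    b = coef[1]
    if np.any(np.abs(b) < 1e-8):
        bad = int(np.argmin(np.abs(b)))
        raise DegenerateFitError(
            f"EMSC multiplicative coefficient ~ 0 for spectrum index {bad}"
        )
    nuisance = (X @ coef).T - b[:, None] * model.reference.absorbance[None, :]
    return (Y - nuisance) / b[:, None]


def select_regions(
    s: Spectrum, regions: Sequence[tuple[float, float]] = DEFAULT_REGIONS
) -> Spectrum:
    """Restrict the spectrum to grid points inside the closed regions.

    Regions are given as ascending (lo, hi) pairs and must not overlap;
    the output keeps the descending axis order.
    """
    mask = _region_mask(s.axis, regions)
    return Spectrum(
        WavenumberAxis(s.axis.values[mask]), s.absorbance[mask], dict(s.meta)
    )


def _region_mask(axis: WavenumberAxis, regions: Sequence[tuple[float, float]]) -> np.ndarray:
    if not regions:
        raise ValueError("need at least one region")
    checked = sorted((float(lo), float(hi)) for lo, hi in regions)
    for (lo, hi) in checked:
        if lo >= hi:
            raise ValueError(f"region ({lo}, {hi}) must have lo < hi")
    for (_, hi_prev), (lo_next, _) in zip(checked, checked[1:]):
        if lo_next <= hi_prev:
            raise ValueError("regions must not overlap")
    mask = np.zeros(len(axis), dtype=bool)
    for lo, hi in checked:
        m = (axis.values >= lo) & (axis.values <= hi)
        if not m.any():
            raise ValueError(
                f"region ({lo}, {hi}) contains no grid points of the axis"
            )
        mask |= m
    return mask


def preprocess_dataset(
    ds: SpectralDataset,
    anchors: Sequence[float] = DEFAULT_ANCHORS,
    regions: Sequence[tuple[float, float]] = DEFAULT_REGIONS,
    emsc_degree: int = 2,
    return_model: bool = False,
):
    """Run the full chain on every pixel spectrum of a dataset.

    The EMSC reference is the mean of all baseline-corrected spectra,
    computed once.  Errors from any stage are re-raised annotated with the
    offending sample_id and pixel index.
    """
    if not ds.images:
        raise ValueError("cannot preprocess an empty dataset")
    axis = ds.images[0].axis

    corrected_imgs: list[np.ndarray] = []
    for img in ds:
        try:
            Y = img.to_matrix()
            anchors_asc = np.sort(np.asarray(anchors, dtype=float))
            w_asc = axis.ascending()
            heights = np.vstack(
                [np.interp(anchors_asc, w_asc, y[::-1]) for y in Y]
            )
            base = np.vstack(
                [_piecewise_linear(axis.values, anchors_asc, h) for h in heights]
            )
            corrected_imgs.append(Y - base)
        except Exception as e:  # pragma: no cover - annotation path
            raise type(e)(f"[sample {img.sample_id}] baseline stage: {e}") from e

    reference = Spectrum(
        axis, np.vstack(corrected_imgs).mean(axis=0), {"role": "emsc_reference"}
    )
    model = EMSCModel(reference, degree=emsc_degree)

    mask = _region_mask(axis, regions)
    reduced_axis = WavenumberAxis(axis.values[mask])

    new_images = []
    for img, Y in zip(ds, corrected_imgs):
        try:
            Z = _apply_emsc_matrix(Y, model)[:, mask]
        except DegenerateFitError as e:
            raise DegenerateFitError(f"[sample {img.sample_id}] EMSC stage: {e}") from e
        spectra = [
            Spectrum(reduced_axis, Z[i], dict(img.spectra[i].meta))
            for i in range(Z.shape[0])
        ]
        new_images.append(dataclasses.replace(img, spectra=spectra))

    out = SpectralDataset(
        new_images,
        {**ds.provenance, "preprocessed": True, "anchors": list(anchors),
         "regions": [list(r) for r in regions], "emsc_degree": emsc_degree},
    )
    if return_model:
        return out, model
    return out
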