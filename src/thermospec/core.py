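"""Shared spectral data model: wavenumber axes, spectra, hyperspectral images.

Axes follow the FTIR plotting convention of strictly decreasing wavenumber
(high -> low, cm^-1).  Every downstream stage (preprocessing, chemometrics,
biomarkers) operates on these containers, and the band-intensity primitives
``intensity_at``, ``band_sum`` and ``fwhm`` defined here are the building
blocks of the biomarker panel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Iterator, Sequence

import numpy as np

__all__ = [
    "GROUPS",
    "WavenumberAxis",
    "Spectrum",
    "SpectralImage",
    "SpectralDataset",
    "SpectralRangeError",
    "BandShapeError",
    "intensity_at",
    "band_sum",
    "fwhm",
]

#: The three study conditions.
GROUPS = ("hypothermia", "hyperthermia", "normothermia")


class SpectralRangeError(ValueError):
    """A requested wavenumber lies outside the spectrum's axis range."""


class BandShapeError(ValueError):
    """A band-shape measurement (e.g. FWHM) failed on this spectrum.

    Carries ``side`` ("left", "right" or "peak") identifying which part of
    the measurement failed.
    """

    def __init__(self, message: str, side: str):
        super().__init__(message)
        self.side = side


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly decreasing wavenumber grid in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("axis needs at least two wavenumbers")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("wavenumbers must be finite and positive")
        if not np.all(np.diff(v) < 0):
            raise ValueError("axis must be strictly decreasing (high -> low)")

    def __len__(self) -> int:
        return self.values.size

    @property
    def max(self) -> float:
        return float(self.values[0])

    @property
    def min(self) -> float:
        return float(self.values[-1])

    def is_uniform(self, rel_tol: float = 0.1) -> bool:
        """True when grid spacing deviates < ``rel_tol`` from its median.

        Acquisition axes are uniform; region-reduced axes (which carry the
        gap between the lipid and fingerprint windows) are not.
        """
        spacing = -np.diff(self.values)
        med = np.median(spacing)
        return bool(np.max(np.abs(spacing - med)) < rel_tol * med)

    def ascending(self) -> np.ndarray:
        """The axis values in ascending order (for ``np.interp``)."""
        return self.values[::-1]


@dataclass
class Spectrum:
    """One absorbance trace on a shared wavenumber axis."""

    axis: WavenumberAxis
    absorbance: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.shape != self.axis.values.shape:
            raise ValueError(
                f"absorbance length {a.size} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance values must be finite")
        self.absorbance = a

    def with_absorbance(self, absorbance: np.ndarray, **extra_meta: Any) -> "Spectrum":
        return Spectrum(self.axis, absorbance, {**self.meta, **extra_meta})


@dataclass
class SpectralImage:
    """Rectangular grid of pixel spectra from one tissue section.

    Spectra are stored row-major; each carries its pixel coordinates in
    ``meta['row']`` / ``meta['col']``.
    """

    sample_id: str
    group: str
    n_rows: int
    n_cols: int
    spectra: list[Spectrum]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"unknown group {self.group!r}; expected one of {GROUPS}"
            )
        if len(self.spectra) != self.n_rows * self.n_cols:
            raise ValueError(
                f"expected {self.n_rows * self.n_cols} spectra, got {len(self.spectra)}"
            )
        axis = self.spectra[0].axis
        for s in self.spectra[1:]:
            if s.axis is not axis and not np.array_equal(s.axis.values, axis.values):
                raise ValueError("all spectra in an image must share one axis")

    @property
    def axis(self) -> WavenumberAxis:
        return self.spectra[0].axis

    def to_matrix(self) -> np.ndarray:
        """(n_pixels, n_wavenumbers) absorbance matrix, row-major pixels."""
        return np.vstack([s.absorbance for s in self.spectra])


@dataclass
class SpectralDataset:
    """All images of one study, with provenance."""

    images: list[SpectralImage]
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [img.sample_id for img in self.images]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids must be unique")

    def __iter__(self) -> Iterator[SpectralImage]:
        return iter(self.images)

    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_spectra(self) -> int:
        return sum(len(img.spectra) for img in self.images)

    def group_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in GROUPS}
        for img in self.images:
            sizes[img.group] += 1
        return sizes

    def map_spectra(self, fn) -> "SpectralDataset":
        """Apply ``fn(Spectrum) -> Spectrum`` to every pixel spectrum."""
        new_images = []
        for img in self.images:
            new_images.append(
                dataclasses.replace(img, spectra=[fn(s) for s in img.spectra])
            )
        return SpectralDataset(new_images, dict(self.provenance))


# ---------------------------------------------------------------------------
# Band-intensity primitives
# ---------------------------------------------------------------------------

def intensity_at(s: Spectrum, w: float) -> float:
    """Absorbance at wavenumber ``w``, linearly interpolated (I_w).

    Equals the grid value exactly when ``w`` falls on a grid point.
    """
    axis = s.axis
    if not (axis.min <= w <= axis.max):
        raise SpectralRangeError(
            f"wavenumber {w} outside axis range [{axis.min}, {axis.max}]"
        )
    return float(np.interp(w, axis.ascending(), s.absorbance[::-1]))


def band_sum(s: Spectrum, lo: float, hi: float) -> float:
    """Sum of absorbance at all grid points with lo <= w <= hi (inclusive)."""
    if not lo < hi:
        raise ValueError(f"band window requires lo < hi, got ({lo}, {hi})")
    axis = s.axis
    if lo < axis.min or hi > axis.max:
        raise SpectralRangeError(
            f"window ({lo}, {hi}) outside axis range [{axis.min}, {axis.max}]"
        )
    mask = (s.axis.values >= lo) & (s.axis.values <= hi)
    if not mask.any():
        raise ValueError(f"window ({lo}, {hi}) contains no grid points")
    return float(s.absorbance[mask].sum())


def fwhm(s: Spectrum, center: float, window: float) -> float:
    """Full width at half maximum of the band near ``center``, in cm^-1.

    The local maximum is located inside [center - window, center + window];
    its height is measured above the lower of the two window-edge
    absorbances (the local base), and the two half-height crossings are
    found by linear interpolation between grid points walking outward from
    the peak.  Raises :class:`BandShapeError` naming the side that failed
    when no interior maximum exists or a half-height crossing is missing.
    """
    lo, hi = center - window, center + window
    axis = s.axis
    if lo < axis.min or hi > axis.max:
        raise SpectralRangeError(
            f"window ({lo}, {hi}) outside axis range [{axis.min}, {axis.max}]"
        )
    # work in ascending wavenumber order for clarity
    w_asc = axis.ascending()
    a_asc = s.absorbance[::-1]
    mask = (w_asc >= lo) & (w_asc <= hi)
    w = w_asc[mask]
    a = a_asc[mask]
    if w.size < 3:
        raise BandShapeError("window too narrow for a band measurement", side="peak")
    ipk = int(np.argmax(a[1:-1])) + 1
    peak = a[ipk]
    if peak <= a[0] or peak <= a[-1]:
        raise BandShapeError(
            f"no interior maximum above both window edges near {center} cm^-1",
            side="peak",
        )
    base = min(a[0], a[-1])
    half = base + 0.5 * (peak - base)

    def _crossing(indices: np.ndarray, side: str) -> float:
        prev = ipk
        for i in indices:
            if a[i] <= half:
                # linear interpolation between grid points prev and i
                frac = (half - a[prev]) / (a[i] - a[prev])
                return float(w[prev] + frac * (w[i] - w[prev]))
            prev = i
        raise BandShapeError(
            f"half height not crossed on the {side} side of the band near "
            f"{center} cm^-1",
            side=side,
        )

    x_left = _crossing(np.arange(ipk - 1, -1, -1), "left")
    x_right = _crossing(np.arange(ipk + 1, w.size), "right")
    return x_right - x_left
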