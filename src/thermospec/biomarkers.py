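"""The ten band-intensity biomarkers of the thermal-death panel.

Each marker is a simple functional of a preprocessed (baseline-corrected,
EMSC-normalized, region-reduced) spectrum:

======================  =====================================================
marker                  definition
======================  =====================================================
total_lipids            I2850 + I2920 (CH2 sym + asym stretching heights)
unsaturation            I3012 / (I2850 + I2920) (olefinic / total lipid)
membrane_fluidity       FWHM (cm^-1) of the CH2 asym band near 2920
total_proteins          sum of absorbance over the amide I window 1600-1700
protein_aggregates      I1622 (beta-sheet / aggregate component)
protein_dysfunction     I1545 / I1655 (amide II / amide I heights)
total_nucleic_acids     I1122 + I972 (RNA + DNA markers)
glycogen                I1151
lactate                 I1126
glycolysis              I1126 / I1151 (lactate / glycogen)
======================  =====================================================

I_w denotes interpolated peak height at wavenumber w.  Ratios whose
denominator falls below a configurable floor, and FWHM measurements with
no resolvable band, are reported as NaN with a warning rather than raised.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import BandShapeError, Spectrum, band_sum, fwhm, intensity_at
from .chemometrics import MeanSpectrumSet

__all__ = ["MARKERS", "RATIO_OR_WIDTH_MARKERS", "compute_biomarker_panel",
           "panel_for_dataset"]

#: Panel column order.
MARKERS = (
    "total_lipids",
    "unsaturation",
    "membrane_fluidity",
    "total_proteins",
    "protein_aggregates",
    "protein_dysfunction",
    "total_nucleic_acids",
    "glycogen",
    "lactate",
    "glycolysis",
)

#: Markers invariant under positive rescaling of the spectrum (the other
#: six scale linearly with it).
RATIO_OR_WIDTH_MARKERS = (
    "unsaturation", "membrane_fluidity", "protein_dysfunction", "glycolysis",
)

AMIDE_I_WINDOW = (1600.0, 1700.0)
FWHM_CENTER = 2920.0
FWHM_WINDOW = 40.0


def _ratio(num: float, den: float, name: str, floor: float) -> float:
    if abs(den) <= floor:
        warnings.warn(
            f"{name}: denominator {den:.3g} below floor {floor:.1g}; "
            "marker undefined"
        )
        return float("nan")
    return num / den


def compute_biomarker_panel(
    s: Spectrum,
    denominator_floor: float = 1e-8,
    fwhm_center: float = FWHM_CENTER,
    fwhm_window: float = FWHM_WINDOW,
) -> dict[str, float]:
    """All ten markers for one preprocessed spectrum.

    The spectrum must cover the lipid (2800-3100) and fingerprint
    (900-1800 cm^-1) regions.
    """
    i2850 = intensity_at(s, 2850.0)
    i2920 = intensity_at(s, 2920.0)
    i3012 = intensity_at(s, 3012.0)
    i1622 = intensity_at(s, 1622.0)
    i1545 = intensity_at(s, 1545.0)
    i1655 = intensity_at(s, 1655.0)
    i1122 = intensity_at(s, 1122.0)
    i972 = intensity_at(s, 972.0)
    i1151 = intensity_at(s, 1151.0)
    i1126 = intensity_at(s, 1126.0)

    total_lipids = i2850 + i2920
    try:
        width = fwhm(s, fwhm_center, fwhm_window)
    except BandShapeError as e:
        warnings.warn(f"membrane_fluidity undefined: {e}")
        width = float("nan")

    row = {
        "total_lipids": total_lipids,
        "unsaturation": _ratio(i3012, total_lipids, "unsaturation",
                               denominator_floor),
        "membrane_fluidity": width,
        "total_proteins": band_sum(s, *AMIDE_I_WINDOW),
        "protein_aggregates": i1622,
        "protein_dysfunction": _ratio(i1545, i1655, "protein_dysfunction",
                                      denominator_floor),
        "total_nucleic_acids": i1122 + i972,
        "glycogen": i1151,
        "lactate": i1126,
        "glycolysis": _ratio(i1126, i1151, "glycolysis", denominator_floor),
    }
    return row


def panel_for_dataset(ms: MeanSpectrumSet, **kwargs) -> pd.DataFrame:
    """One panel row per mean spectrum, carrying sample_id and group."""
    if len(ms) == 0:
        raise ValueError("cannot compute a panel for an empty spectrum set")
    rows = []
    for s in ms:
        try:
            row = compute_biomarker_panel(s, **kwargs)
        except Exception as e:
            raise type(e)(
                f"[sample {s.meta.get('sample_id')!r}] {e}"
            ) from e
        row["sample_id"] = s.meta.get("sample_id")
        row["group"] = s.meta.get("group")
        rows.append(row)
    return pd.DataFrame(rows, columns=[*MARKERS, "sample_id", "group"])
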