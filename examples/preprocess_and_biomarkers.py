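"""Preprocess a study and compute the ten-marker biomarker panel.

The chain: 4-point anchored baseline (3100/2800/1800/899 cm^-1) ->
EMSC normalization against the dataset mean -> reduction to the lipid
(3100-2800) and fingerprint (1800-900 cm^-1) regions.  Each image's
pixels are then averaged in disjoint random groups of ten, and every
mean spectrum is scored on ten band-intensity markers.
"""

from thermospec import (
    MARKERS,
    SyntheticConfig,
    build_mean_spectrum_table,
    generate_study,
    panel_for_dataset,
    preprocess_dataset,
)

ds = generate_study(SyntheticConfig(seed=1))
processed = preprocess_dataset(ds)
means = build_mean_spectrum_table(processed, k=10, seed=2)
print(f"mean spectra per group: {means.counts()}")

panel = panel_for_dataset(means)
medians = panel.groupby("group")[list(MARKERS)].median().T
print("\nper-group biomarker medians:")
print(medians.round(3))
print(
    "\nReading the table: both fatal groups show elevated total lipids and\n"
    "reduced unsaturation and CH2 bandwidth (membrane rigidity); the heat\n"
    "group uniquely loses total protein while gaining beta-sheet aggregates\n"
    "and amide II/I dysfunction; the cold group carries the most nucleic\n"
    "acids and the most active lactate/glycogen (glycolysis) ratio."
)
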