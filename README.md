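# thermospec

FTIR hyperspectral chemometrics for discriminating fatal hypothermia,
fatal hyperthermia and normothermia in brain tissue.

## The problem

Death from environmental cold or heat leaves few specific macroscopic or
histological traces, which makes it one of the harder calls in forensic
pathology. Mid-infrared (FTIR) imaging of hypothalamus tissue offers a
biochemical route: absorbance bands in the 3100–2800 cm⁻¹ (lipid) and
1800–900 cm⁻¹ (fingerprint) regions report lipid content and saturation,
protein secondary structure, nucleic acids and carbohydrate metabolites,
and these profiles shift differently under fatal cold and heat stress.

`thermospec` is a reusable implementation of the full analysis chain for
such a study, usable from Python (the primary interface), from four
narrative scripts in `examples/`, or from a thin `thermospec` CLI. Because
no public dataset accompanies this design, the package includes a
first-class synthetic study generator that emulates the experiment —
47 animals (17 cold / 17 heat / 13 control), one 10 × 16 pixel image per
animal, 160 spectra per image — with calibrated group effects, so every
downstream stage is testable end to end.

## The method

1. **Preprocessing.** Each pixel spectrum gets a 4-point anchored baseline
   (through 3100, 2800, 1800 and 899 cm⁻¹) subtracted, is normalized by
   extended multiplicative signal correction (EMSC) against the dataset
   mean — the least-squares fit *s(ν̃) ≈ a + b·m(ν̃) + d₁ν̃ + d₂ν̃²*, with
   the corrected spectrum *(s − a − d₁ν̃ − d₂ν̃²)/b* — and is reduced to
   the lipid and fingerprint regions.
2. **Mean spectra.** Within each image, pixels are partitioned into
   disjoint random groups of ten and averaged (272/272/208 mean spectra
   per group under the default design).
3. **Chemometrics.** Group difference spectra; pairwise and three-group
   PCA (mean-centered, SVD); random-forest classification with
   mean-decrease-in-Gini ranking of wavenumbers.
4. **Biomarker panel.** Ten per-spectrum markers built from interpolated
   band heights *I_ν̃*, the amide I band sum, and the CH₂ bandwidth:
   total lipids *I₂₈₅₀ + I₂₉₂₀*; unsaturation *I₃₀₁₂/(I₂₈₅₀ + I₂₉₂₀)*;
   membrane fluidity (FWHM of the 2920 cm⁻¹ band); total proteins
   *∑(I₁₆₀₀₋₁₇₀₀)*; aggregates *I₁₆₂₂*; dysfunction *I₁₅₄₅/I₁₆₅₅*; total
   nucleic acids *I₁₁₂₂ + I₉₇₂*; glycogen *I₁₁₅₁*; lactate *I₁₁₂₆*;
   glycolysis *I₁₁₂₆/I₁₁₅₁*.
5. **Statistics.** Per marker: medians with interquartile ranges,
   Kruskal–Wallis *H* (tie-corrected, χ² reference), and chi-square
   Nemenyi all-pairs post-hoc p-values, flagged at α = 0.05.

## Worked example

```python
from thermospec import (SyntheticConfig, generate_study, preprocess_dataset,
                        build_mean_spectrum_table, panel_for_dataset, MARKERS)

ds = generate_study(SyntheticConfig(seed=1))          # 47 images, 7520 spectra
means = build_mean_spectrum_table(preprocess_dataset(ds), k=10, seed=2)
panel = panel_for_dataset(means)
print(panel.groupby("group")[list(MARKERS)].median().T.round(3))
```

```
group                hyperthermia  hypothermia  normothermia
total_lipids                1.282        1.193         1.002
unsaturation                0.054        0.058         0.098
membrane_fluidity          23.304       23.292        26.827
total_proteins             25.332       26.456        26.756
protein_aggregates          0.445        0.339         0.304
protein_dysfunction         0.650        0.531         0.520
total_nucleic_acids         0.305        0.399         0.350
glycogen                    0.096        0.114         0.115
lactate                     0.150        0.200         0.176
glycolysis                  1.559        1.758         1.523
```

Both fatal groups carry more total lipid, less unsaturation and narrower
CH₂ bands (stiffer membranes) than the controls; the heat group uniquely
shows protein loss, β-sheet aggregation and an elevated amide II/I ratio;
the cold group shows the highest nucleic-acid content and the most active
glycolysis ratio. `examples/group_comparison.py` prints the corresponding
Kruskal–Wallis/Nemenyi table (every contrast above is significant at
α = 0.05 on the default study), and `examples/chemometrics_overview.py`
shows pairwise PCA silhouettes of 0.86–0.93 and a top-10 Gini ranking
dominated by the nucleic-acid bands near 1122 and 972 cm⁻¹.

The same analysis runs from the shell:

```bash
thermospec all --seed 1 --out runs/demo        # full pipeline, CSV outputs
thermospec simulate --seed 1 --out data/demo   # just write a dataset
```

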