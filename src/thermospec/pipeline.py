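"""End-to-end pipeline: simulate/load -> preprocess -> analyze.

``run_pipeline`` composes every stage of the analysis into one
reproducible, logged run that writes plain CSV tables plus a JSON
run-metadata file.  A single master seed is mixed with a fixed per-stage
tag (crc32 of the stage name) so each stage is independently re-runnable
and changing only the forest seed changes only the forest outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tsio
from .biomarkers import panel_for_dataset
from .chemometrics import (
    MeanSpectrumSet,
    build_mean_spectrum_table,
    difference_spectra,
    fit_pca,
    fit_random_forest,
    group_mean_spectrum,
    rank_wavenumbers_by_gini,
)
from .core import GROUPS, SpectralDataset
from .preprocess import (
    DEFAULT_ANCHORS,
    DEFAULT_REGIONS,
    preprocess_dataset,
)
from .simulate import SyntheticConfig, generate_study
from .stats import compare_biomarkers, comparisons_to_frame

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]

logger = logging.getLogger(__name__)

_CSV_FMT = "%.12g"

PAIRWISE = (
    ("hypothermia", "normothermia"),
    ("hyperthermia", "normothermia"),
    ("hypothermia", "hyperthermia"),
)


def stage_seed(master: int, stage: str) -> int:
    """Derived stage seed: first state word of SeedSequence([master, crc32(stage)])."""
    return int(
        np.random.SeedSequence([master, zlib.crc32(stage.encode())])
        .generate_state(1)[0] % (2**31)
    )


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    Exactly one of ``synthetic`` / ``input_manifest`` must be set.
    """

    synthetic: SyntheticConfig | None = None
    input_manifest: str | None = None
    anchors: tuple = DEFAULT_ANCHORS
    regions: tuple = DEFAULT_REGIONS
    emsc_degree: int = 2
    k_average: int = 10
    seed: int = 0
    rf_trees: int = 500
    rf_seed: int | None = None  # default: derived from master seed
    stats_unit: str = "mean_spectrum"
    alpha: float = 0.05
    top_n_wavenumbers: int = 10
    write_datasets: bool = False
    out_dir: str = "thermospec_run"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.input_manifest is None):
            raise ValueError(
                "exactly one of synthetic config or input_manifest must be set"
            )

    @classmethod
    def from_dict(cls, d) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d and d["synthetic"] is not None:
            d["synthetic"] = SyntheticConfig.from_dict(d["synthetic"])
        for key in ("anchors",):
            if key in d:
                d[key] = tuple(d[key])
        if "regions" in d:
            d["regions"] = tuple(tuple(r) for r in d["regions"])
        return cls(**d)


def _save(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_CSV_FMT)


def _spectra_frame(named_spectra: dict[str, "object"]) -> pd.DataFrame:
    first = next(iter(named_spectra.values()))
    out = {"wavenumber": first.axis.values}
    for name, s in named_spectra.items():
        out[name] = s.absorbance
    return pd.DataFrame(out)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis; returns the run directory.

    Outputs (all CSV + one JSON): dataset manifest (when written), group
    mean and difference spectra, pairwise and 3-group PCA scores /
    loadings / explained variance, Gini importance, biomarker panel,
    group-comparison table, run metadata.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict = {"seed": cfg.seed, "stages": {}}

    # ---- input ----
    stage = "input"
    try:
        if cfg.synthetic is not None:
            sim_cfg = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
            ds = generate_study(sim_cfg)
            meta["input"] = {"kind": "synthetic",
                             "group_sizes": dict(sim_cfg.group_sizes)}
            if cfg.write_datasets:
                tsio.write_dataset(ds, out / "raw", overwrite=True)
        else:
            ds = tsio.read_dataset(cfg.input_manifest)
            meta["input"] = {"kind": "manifest", "path": cfg.input_manifest}
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e
    meta["n_images"] = len(ds)
    meta["n_spectra"] = ds.n_spectra

    # ---- preprocess ----
    stage = "preprocess"
    try:
        processed = preprocess_dataset(
            ds, anchors=cfg.anchors, regions=cfg.regions,
            emsc_degree=cfg.emsc_degree,
        )
        if cfg.write_datasets:
            tsio.write_dataset(processed, out / "processed", overwrite=True)
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    # ---- averaging ----
    stage = "average"
    avg_seed = stage_seed(cfg.seed, stage)
    means = build_mean_spectrum_table(processed, k=cfg.k_average, seed=avg_seed)
    meta["stages"]["average"] = {"k": cfg.k_average, "seed": avg_seed,
                                 "counts": means.counts()}

    # ---- group means and difference spectra ----
    by_group = {
        g: group_mean_spectrum([s for s in means if s.meta["group"] == g])
        for g in GROUPS
    }
    _save(_spectra_frame(by_group), out / "group_mean_spectra.csv")
    _save(_spectra_frame(difference_spectra(by_group)),
          out / "difference_spectra.csv")

    # ---- PCA: three pairwise runs + one 3-group run ----
    axis = means.spectra[0].axis.values
    for tag, subset in _pca_subsets(means):
        res = fit_pca(subset.to_matrix(), n_components=3)
        scores = pd.DataFrame(res.scores, columns=res.component_labels)
        scores.insert(0, "group", subset.groups())
        scores.insert(0, "sample_id", [s.meta["sample_id"] for s in subset])
        _save(scores, out / f"pca_scores_{tag}.csv")
        loadings = pd.DataFrame(
            {"wavenumber": axis,
             **{lab: res.loadings[i] for i, lab in enumerate(res.component_labels)}}
        )
        _save(loadings, out / f"pca_loadings_{tag}.csv")
        _save(pd.DataFrame({"component": res.component_labels,
                            "explained_variance_ratio": res.explained_variance_ratio}),
              out / f"pca_explained_{tag}.csv")

    # ---- random forest ----
    stage = "random_forest"
    rf_seed = cfg.rf_seed if cfg.rf_seed is not None else stage_seed(cfg.seed, stage)
    imp = fit_random_forest(means.to_matrix(), means.groups(), axis,
                            n_trees=cfg.rf_trees, seed=rf_seed)
    _save(pd.DataFrame({"wavenumber": imp.wavenumbers,
                        "mean_decrease_gini": imp.importance}),
          out / "gini_importance.csv")
    top = rank_wavenumbers_by_gini(imp, cfg.top_n_wavenumbers)
    _save(pd.DataFrame({"rank": np.arange(1, top.size + 1), "wavenumber": top}),
          out / "gini_top_wavenumbers.csv")
    meta["stages"]["random_forest"] = {
        "n_trees": cfg.rf_trees, "seed": rf_seed,
        "oob_accuracy": imp.oob_accuracy,
    }

    # ---- biomarkers + statistics ----
    panel = panel_for_dataset(means)
    _save(panel, out / "biomarker_panel.csv")
    comparisons = compare_biomarkers(panel, alpha=cfg.alpha, unit=cfg.stats_unit)
    _save(comparisons_to_frame(comparisons), out / "group_comparison.csv")
    meta["stages"]["stats"] = {
        "unit": cfg.stats_unit, "alpha": cfg.alpha,
        "n_dropped": {r.marker: r.n_dropped for r in comparisons},
        "not_testable": [r.marker for r in comparisons if not r.testable],
    }

    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    logger.info("pipeline run complete: %s", out)
    return out


def _pca_subsets(means: MeanSpectrumSet):
    for a, b in PAIRWISE:
        yield f"{a[:4]}_vs_{b[:4]}", means.subset([a, b])
    yield "all_groups", means
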