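"""Dataset I/O: CSV spectra matrices and single-block JCAMP-DX files.

Two on-disk dialects, both accompanied by a small CSV manifest
(sample_id, group, path, n_rows, n_cols, format):

* ``csv_matrix`` — one CSV per image; header row carries ``row``, ``col``
  and the descending wavenumber axis, one data row per pixel spectrum.
* ``jcampdx`` — one JCAMP-DX file per pixel spectrum (AFFN ``(XY..XY)``
  data table, single block), grouped in one directory per image.

Numbers are serialized with 12 significant digits, which bounds the
write-read round-trip error below 1e-9 for absorbances of laboratory
magnitude.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GROUPS, Spectrum, SpectralDataset, SpectralImage, WavenumberAxis

__all__ = ["DatasetManifest", "write_dataset", "read_dataset"]

_FORMATS = ("csv_matrix", "jcampdx")
_FMT = "%.12g"
MANIFEST_NAME = "manifest.csv"


@dataclass
class DatasetManifest:
    """Tabular index of a written dataset."""

    records: pd.DataFrame  # sample_id, group, path, n_rows, n_cols, format
    path: Path

    def __len__(self) -> int:
        return len(self.records)


def _format_floats(values: np.ndarray) -> list[str]:
    return [_FMT % v for v in values]


def _write_csv_image(img: SpectralImage, path: Path) -> None:
    header = ["row", "col"] + _format_floats(img.axis.values)
    lines = [",".join(header)]
    for s in img.spectra:
        row = [str(s.meta["row"]), str(s.meta["col"])]
        row += _format_floats(s.absorbance)
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")


def _read_csv_image(path: Path, sample_id: str, group: str,
                    n_rows: int, n_cols: int) -> SpectralImage:
    if not path.exists():
        raise FileNotFoundError(f"missing image file: {path}")
    df = pd.read_csv(path)
    axis = WavenumberAxis(np.array([float(c) for c in df.columns[2:]]))
    spectra = []
    for _, rec in df.iterrows():
        spectra.append(
            Spectrum(
                axis,
                rec.iloc[2:].to_numpy(dtype=float),
                {"sample_id": sample_id, "group": group,
                 "row": int(rec.iloc[0]), "col": int(rec.iloc[1])},
            )
        )
    return SpectralImage(sample_id, group, n_rows, n_cols, spectra)


def _write_jcamp_spectrum(s: Spectrum, path: Path, title: str) -> None:
    w = s.axis.values
    lines = [
        f"##TITLE={title}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=INFRARED SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ABSORBANCE",
        "##XFACTOR=1",
        "##YFACTOR=1",
        f"##FIRSTX={_FMT % w[0]}",
        f"##LASTX={_FMT % w[-1]}",
        f"##NPOINTS={w.size}",
        "##XYDATA=(XY..XY)",
    ]
    for x, y in zip(w, s.absorbance):
        lines.append(f"{_FMT % x}, {_FMT % y}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")


def _read_jcamp_spectrum(path: Path) -> tuple[np.ndarray, np.ndarray]:
    if not path.exists():
        raise FileNotFoundError(f"missing spectrum file: {path}")
    xs, ys = [], []
    in_data = False
    for line in path.read_text().splitlines():
        line = line.strip()
        if line.startswith("##XYDATA"):
            in_data = True
            continue
        if line.startswith("##END"):
            break
        if in_data and line:
            x, y = line.split(",")
            xs.append(float(x))
            ys.append(float(y))
    if not xs:
        raise ValueError(f"no XYDATA table found in {path}")
    return np.array(xs), np.array(ys)


def write_dataset(ds: SpectralDataset, directory, format: str = "csv_matrix",
                  overwrite: bool = False) -> DatasetManifest:
    """Write a dataset and its manifest under ``directory``.

    Refuses to clobber an existing manifest unless ``overwrite`` is set.
    """
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if not ds.images:
        raise ValueError("cannot write an empty dataset")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / MANIFEST_NAME
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(
            f"{manifest_path} already exists; pass overwrite=True to replace"
        )

    records = []
    for img in ds:
        if format == "csv_matrix":
            rel = f"{img.sample_id}.csv"
            _write_csv_image(img, directory / rel)
        else:
            rel = img.sample_id
            img_dir = directory / rel
            img_dir.mkdir(exist_ok=True)
            for s in img.spectra:
                name = f"r{s.meta['row']:02d}_c{s.meta['col']:02d}.jdx"
                _write_jcamp_spectrum(
                    s, img_dir / name,
                    title=f"{img.sample_id} pixel ({s.meta['row']},{s.meta['col']})",
                )
        records.append(
            {"sample_id": img.sample_id, "group": img.group, "path": rel,
             "n_rows": img.n_rows, "n_cols": img.n_cols, "format": format}
        )
    records = pd.DataFrame(records)
    records.to_csv(manifest_path, index=False)
    return DatasetManifest(records, manifest_path)


def read_dataset(manifest_path) -> SpectralDataset:
    """Reconstruct a dataset from a manifest written by :func:`write_dataset`."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    records = pd.read_csv(manifest_path)
    base = manifest_path.parent
    images = []
    axis_ref: WavenumberAxis | None = None
    for rec in records.itertuples():
        if rec.group not in GROUPS:
            raise ValueError(
                f"unknown group label {rec.group!r} for sample {rec.sample_id!r}; "
                f"expected one of {GROUPS}"
            )
        if rec.format == "csv_matrix":
            img = _read_csv_image(base / rec.path, rec.sample_id, rec.group,
                                  int(rec.n_rows), int(rec.n_cols))
        elif rec.format == "jcampdx":
            img_dir = base / rec.path
            spectra = []
            axis: WavenumberAxis | None = None
            for r in range(int(rec.n_rows)):
                for c in range(int(rec.n_cols)):
                    x, y = _read_jcamp_spectrum(img_dir / f"r{r:02d}_c{c:02d}.jdx")
                    if axis is None:
                        axis = WavenumberAxis(x)
                    spectra.append(
                        Spectrum(axis, y, {"sample_id": rec.sample_id,
                                           "group": rec.group,
                                           "row": r, "col": c})
                    )
            img = SpectralImage(rec.sample_id, rec.group,
                                int(rec.n_rows), int(rec.n_cols), spectra)
        else:
            raise ValueError(f"unknown format {rec.format!r} in manifest")
        if axis_ref is None:
            axis_ref = img.axis
        elif not np.array_equal(axis_ref.values, img.axis.values):
            raise ValueError(
                f"axis mismatch: image {rec.sample_id!r} differs from the "
                "first image's wavenumber axis"
            )
        images.append(img)
    return SpectralDataset(images, {"manifest": str(manifest_path)})
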