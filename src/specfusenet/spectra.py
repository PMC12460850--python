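"""Spectral dataset containers and CSV I/O.

A dataset is a samples-by-wavelengths absorbance matrix with a physical
wavelength grid (nm) and an integer class label per row.  The on-disk
dialect is a plain CSV whose header holds the wavelengths in nm plus one
label column (default ``label``); an optional JSON sidecar can pin the
class-name vocabulary explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_GRID_POINTS = 331
DEFAULT_GRID_RANGE = (740.0, 1070.0)


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths in nm; >= 5 points."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1 or vals.size < 5:
            raise ValueError("wavelength grid must be 1-D with at least 5 points")
        if not np.all(np.diff(vals) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size

    @property
    def step(self) -> float:
        """Mean grid spacing in nm (grids are validated near-uniform downstream)."""
        return float(np.mean(np.diff(self.values)))

    @staticmethod
    def default() -> "WavelengthGrid":
        lo, hi = DEFAULT_GRID_RANGE
        return WavelengthGrid(np.linspace(lo, hi, DEFAULT_GRID_POINTS))


@dataclass(frozen=True)
class LabelVocabulary:
    """Ordered unique class names with a contiguous name -> index map."""

    names: tuple[str, ...]

    def __post_init__(self):
        names = tuple(str(n) for n in self.names)
        if len(set(names)) != len(names):
            raise ValueError("class names must be unique")
        if any(n == "" for n in names):
            raise ValueError("class names must be non-empty")
        object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.names)

    @property
    def index_of(self) -> dict[str, int]:
        return {n: i for i, n in enumerate(self.names)}


@dataclass(frozen=True)
class SpectralDataset:
    """n x m absorbance matrix + wavelength grid + per-row class labels."""

    spectra: np.ndarray
    grid: WavelengthGrid
    labels: np.ndarray
    class_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "spectra", spectra)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "class_names", LabelVocabulary(self.class_names).names)
        if spectra.shape[1] != len(self.grid):
            raise ValueError(
                f"spectra have {spectra.shape[1]} columns but grid has {len(self.grid)}")
        if labels.shape != (spectra.shape[0],):
            raise ValueError("labels must be one integer per spectrum row")
        if not np.all(np.isfinite(spectra)):
            raise ValueError("spectra contain non-finite values")
        k = len(self.class_names)
        if labels.size and (labels.min() < 0 or labels.max() >= k):
            raise ValueError(f"labels must lie in [0, {k})")

    @property
    def n_samples(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_features(self) -> int:
        return self.spectra.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, row_indices) -> "SpectralDataset":
        """Select rows in the given order; grid and vocabulary unchanged."""
        idx = np.asarray(row_indices, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_samples):
            raise IndexError("row index out of range")
        return SpectralDataset(self.spectra[idx].reshape(idx.size, self.n_features),
                               self.grid, self.labels[idx], self.class_names)


def subset(ds: SpectralDataset, row_indices) -> SpectralDataset:
    return ds.subset(row_indices)


def read_spectra_csv(path, label_column: str = "label") -> SpectralDataset:
    """Read the CSV dialect: numeric wavelength columns + a label column.

    Wavelength columns are sorted ascending (spectra permuted to match);
    labels are factorized in first-appearance order unless a JSON sidecar
    ``<path>.names.json`` with ``{"class_names": [...]}`` is present.
    """
    path = Path(path)
    with open(path) as fh:
        raw_header = fh.readline().strip().split(",")
    raw_wl = [c for c in raw_header if c != label_column]
    if len(set(raw_wl)) != len(raw_wl):
        raise ValueError("duplicate wavelength columns in header")
    df = pd.read_csv(path, dtype=str)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} missing from {path}")
    if len(df) < 1:
        raise ValueError(f"{path} holds no data rows")
    wl_cols = [c for c in df.columns if c != label_column]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength column in header: {exc}") from exc
    if np.unique(wavelengths).size != wavelengths.size:
        raise ValueError("duplicate wavelength columns in header")
    order = np.argsort(wavelengths)
    wl_cols = [wl_cols[i] for i in order]
    wavelengths = wavelengths[order]

    spectra = np.empty((len(df), len(wl_cols)))
    for j, col in enumerate(wl_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy())[0]
        if bad.size:
            raise ValueError(
                f"non-numeric absorbance at row {bad[0]}, column {col!r} in {path}")
        spectra[:, j] = vals.to_numpy(dtype=float)

    raw_labels = df[label_column].astype(str).to_numpy()
    sidecar = path.with_suffix(path.suffix + ".names.json")
    if sidecar.exists():
        names = tuple(json.loads(sidecar.read_text())["class_names"])
        index = {n: i for i, n in enumerate(names)}
        try:
            labels = np.array([index[v] for v in raw_labels])
        except KeyError as exc:
            raise ValueError(f"label {exc} absent from sidecar vocabulary") from exc
    else:
        names_list: list[str] = []
        index = {}
        labels = np.empty(len(raw_labels), dtype=int)
        for i, v in enumerate(raw_labels):
            if v not in index:
                index[v] = len(names_list)
                names_list.append(v)
            labels[i] = index[v]
        names = tuple(names_list)
    return SpectralDataset(spectra, WavelengthGrid(wavelengths), labels, names)


def write_spectra_csv(ds: SpectralDataset, path, label_column: str = "label"):
    """Write the CSV dialect; round-trips through :func:`read_spectra_csv`."""
    path = Path(path)
    header = [format(w, ".10g") for w in ds.grid.values] + [label_column]
    df = pd.DataFrame(ds.spectra, columns=header[:-1])
    df[label_column] = [ds.class_names[i] for i in ds.labels]
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = path.with_suffix(path.suffix + ".names.json")
    sidecar.write_text(json.dumps({"class_names": list(ds.class_names)}))
    return path
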