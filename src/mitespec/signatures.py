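"""Spectral signatures: extraction, smoothing, averaging and SNV.

Terminology follows the common chemometric workflow for leaf-level
hyperspectral classification:

* RSS  - raw spectral signature, the reflectance vector of one pixel;
* MRSS - mean raw spectral signature, the average of all (smoothed)
  ROI pixel spectra, one per leaf snapshot;
* MNSS - mean normalized spectral signature, the MRSS after the
  standard normal variate (SNV) transform, which subtracts the
  spectrum's own mean and divides by its standard deviation and thereby
  removes multiplicative scatter/illumination effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .cube_io import HyperCube, WavelengthGrid
from .segmentation import ROI

__all__ = [
    "SpectralSignature",
    "LabeledDataset",
    "extract_rss",
    "smooth_spectrum",
    "mean_signature",
    "snv",
    "build_dataset",
]

SignatureKind = Literal["RSS", "MRSS", "MNSS"]


@dataclass(frozen=True)
class SpectralSignature:
    """One spectrum over a wavelength grid, tagged by processing stage."""

    grid: WavelengthGrid
    values: np.ndarray
    kind: SignatureKind

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", values)
        if values.shape != (self.grid.n_bands,):
            raise ValueError("signature length must match the grid")
        if not np.all(np.isfinite(values)):
            raise ValueError("signature values must be finite")


def extract_rss(cube: HyperCube, roi: ROI) -> np.ndarray:
    """Per-pixel raw signatures of the ROI as an (n_pixels, n_bands) array.

    Rows follow raster (row-major) order of the ROI pixels, so the
    extraction is deterministic for a given cube and mask.
    """
    if roi.pixel_count == 0:
        raise ValueError("cannot extract signatures from an empty ROI")
    if roi.mask.shape != cube.values.shape[:2]:
        raise ValueError("ROI shape does not match the cube")
    return cube.values[roi.mask].astype(np.float64)


def smooth_spectrum(values: np.ndarray, window: int = 7, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing along the band axis.

    A polynomial of the given order is least-squares fitted in a moving
    window; spectrum ends are handled by evaluating the polynomial
    fitted to the terminal window, so the output keeps all bands.
    Accepts a single spectrum or a stack with bands on the last axis.
    """
    values = np.asarray(values, dtype=np.float64)
    n_bands = values.shape[-1]
    if window % 2 == 0 or window <= polyorder or window > n_bands:
        raise ValueError(
            f"invalid smoothing window: need odd window, window > polyorder and "
            f"window <= n_bands, got window={window}, polyorder={polyorder}, "
            f"n_bands={n_bands}"
        )
    return savgol_filter(values, window, polyorder, axis=-1, mode="interp")


def mean_signature(
    rss: np.ndarray | Sequence[SpectralSignature],
    grid: WavelengthGrid | None = None,
) -> SpectralSignature:
    """Elementwise mean of a signature collection -> MRSS.

    ``rss`` is either the matrix returned by :func:`extract_rss`
    (``grid`` required) or a sequence of :class:`SpectralSignature`
    objects, which must all share one grid.
    """
    if isinstance(rss, np.ndarray):
        if grid is None:
            raise ValueError("grid is required when passing a raw matrix")
        matrix = np.atleast_2d(np.asarray(rss, dtype=np.float64))
    else:
        sigs = list(rss)
        if not sigs:
            raise ValueError("cannot average an empty signature collection")
        grid = sigs[0].grid
        if any(s.grid != grid for s in sigs):
            raise ValueError("signatures lie on different wavelength grids")
        matrix = np.vstack([s.values for s in sigs])
    if matrix.shape[0] == 0:
        raise ValueError("cannot average an empty signature collection")
    return SpectralSignature(grid, matrix.mean(axis=0), "MRSS")


def snv(signature: SpectralSignature | np.ndarray) -> SpectralSignature | np.ndarray:
    """Standard normal variate transform of one spectrum.

    Subtracts the spectrum mean and divides by its sample standard
    deviation (n-1 divisor), giving output with mean 0 and SD 1; a
    spectrum with zero spread is rejected.  Passing a bare array returns
    a bare array; passing a signature returns an MNSS signature.
    """
    values = signature.values if isinstance(signature, SpectralSignature) else signature
    values = np.asarray(values, dtype=np.float64)
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a constant spectrum (zero spread)")
    out = (values - values.mean()) / sd
    if isinstance(signature, SpectralSignature):
        return SpectralSignature(signature.grid, out, "MNSS")
    return out


@dataclass
class LabeledDataset:
    """n_samples x n_bands signature matrix with healthy/infested labels."""

    X: np.ndarray
    y: np.ndarray
    grid: WavelengthGrid
    kind: SignatureKind = "MNSS"
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=object)
        if self.X.ndim != 2 or self.X.shape[1] != self.grid.n_bands:
            raise ValueError("matrix shape inconsistent with the grid")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("row count must equal label count")
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(self.X.shape[0])]
        if len(self.sample_ids) != self.X.shape[0]:
            raise ValueError("sample_ids length must equal row count")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_bands(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.y.astype(str), return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def subset_rows(self, indices: np.ndarray | Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return LabeledDataset(
            self.X[idx], self.y[idx], self.grid, self.kind,
            [self.sample_ids[i] for i in idx],
        )

    def subset_bands(self, band_indices: Sequence[int]) -> np.ndarray:
        return self.X[:, np.asarray(band_indices, dtype=int)]

    # -- CSV round trip ----------------------------------------------------
    def to_csv(self, path: str | Path) -> Path:
        """Write sample_id, label and one ``w<nm>`` column per band.

        The signature kind goes into a JSON sidecar next to the CSV.
        """
        path = Path(path)
        cols = [f"w{int(round(c))}" for c in self.grid.centers]
        df = pd.DataFrame(self.X, columns=cols)
        df.insert(0, "label", self.y.astype(str))
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, index=False, float_format="%.10g")
        meta = {
            "kind": self.kind,
            "start_nm": self.grid.start_nm,
            "step_nm": self.grid.step_nm,
            "n_bands": self.grid.n_bands,
        }
        path.with_suffix(".meta.json").write_text(json.dumps(meta, sort_keys=True))
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledDataset":
        path = Path(path)
        df = pd.read_csv(path)
        band_cols = [c for c in df.columns if c.startswith("w")]
        centers = np.array([float(c[1:]) for c in band_cols])
        meta_path = path.with_suffix(".meta.json")
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            grid = WavelengthGrid(meta["start_nm"], meta["step_nm"], meta["n_bands"])
            kind = meta["kind"]
        else:
            step = float(centers[1] - centers[0]) if centers.size > 1 else 1.0
            grid = WavelengthGrid(float(centers[0]), step, centers.size)
            kind = "MNSS"
        return cls(
            df[band_cols].to_numpy(dtype=np.float64),
            df["label"].to_numpy(dtype=object),
            grid,
            kind,
            df["sample_id"].astype(str).tolist(),
        )


def build_dataset(
    signatures: Iterable[SpectralSignature] | np.ndarray,
    labels: Sequence[str],
    *,
    grid: WavelengthGrid | None = None,
    balance: bool = False,
    n_per_class: int | None = None,
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> LabeledDataset:
    """Assemble (and optionally class-balance) a labeled dataset.

    With ``balance=True`` each class is subsampled without replacement,
    using a generator seeded by ``seed``, down to ``n_per_class``
    (default: the minority class count).  Retained rows keep their
    original relative order, so resampling is stable and reproducible.
    """
    if isinstance(signatures, np.ndarray):
        if grid is None:
            raise ValueError("grid is required when passing a raw matrix")
        X = np.asarray(signatures, dtype=np.float64)
        kind: SignatureKind = "MNSS"
    else:
        sigs = list(signatures)
        if not sigs:
            raise ValueError("no signatures given")
        grid = sigs[0].grid
        kind = sigs[0].kind
        if any(s.grid != grid for s in sigs):
            raise ValueError("signatures lie on different wavelength grids")
        X = np.vstack([s.values for s in sigs])

    y = np.asarray(list(labels), dtype=object)
    if X.shape[0] != y.shape[0]:
        raise ValueError("label count must equal signature count")
    classes, counts = np.unique(y.astype(str), return_counts=True)
    if (counts == 0).any() or len(classes) == 0:
        raise ValueError("every class needs at least one sample")

    ids = list(sample_ids) if sample_ids is not None else [f"s{i:04d}" for i in range(len(y))]
    ds = LabeledDataset(X, y, grid, kind, ids)
    if not balance:
        return ds

    target = int(n_per_class) if n_per_class is not None else int(counts.min())
    if target > counts.min():
        raise ValueError(
            f"cannot draw {target} samples per class: minority class has {counts.min()}"
        )
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for cls_label in classes:
        cls_idx = np.flatnonzero(y.astype(str) == cls_label)
        chosen = rng.choice(cls_idx, size=target, replace=False)
        keep.extend(sorted(chosen.tolist()))
    keep.sort()
    return ds.subset_rows(np.array(keep))
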