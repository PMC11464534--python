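"""Effective-wavelength selection and redundancy diagnostics.

Three selectors reduce the 113-band spectrum to a handful of effective
wavelengths:

* FI  - ensemble feature importance: mean impurity decrease of a random
  forest fitted on the labeled signatures;
* SKB - "select k best": top-k bands by a univariate score (one-way
  ANOVA F between the two classes by default);
* SP  - "select percentile": the top ``floor(p * n_bands / 100)`` bands
  by the same univariate score.

Selected wavelengths are attributed to named spectral regions (green,
red, red edge, NIR ...) and their pairwise Pearson correlations can be
inspected for redundancy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif

from .cube_io import WavelengthGrid
from .signatures import LabeledDataset

__all__ = [
    "RegionScheme",
    "SelectionResult",
    "fi_scores",
    "anova_f_scores",
    "select_k_best",
    "select_percentile",
    "region_of",
    "correlation_matrix",
]

# Table-style random-forest configuration shared with the classifier module.
FOREST_CONFIG = dict(
    n_estimators=100,
    max_depth=None,
    min_samples_split=5,
    min_samples_leaf=1,
    class_weight="balanced",
)


@dataclass(frozen=True)
class RegionScheme:
    """Named half-open wavelength intervals [lo, hi) covering the grid.

    The conventional visible subdivision puts red at 600-700 nm, but the
    red edge (the steep reflectance rise at the visible/NIR boundary)
    spans 690-740 nm; treating it as its own region, red ends at 690 nm,
    which on a 502-950 nm / 4 nm grid leaves exactly 22 red band
    centers.  The final interval is closed at its upper end.
    """

    intervals: tuple[tuple[str, float, float], ...] = (
        ("blue", 400.0, 500.0),
        ("green", 500.0, 600.0),
        ("red", 600.0, 690.0),
        ("red_edge", 690.0, 740.0),
        ("nir", 740.0, 1000.0),
    )

    def __post_init__(self) -> None:
        for (_, lo, hi), (_, lo2, _) in zip(self.intervals, self.intervals[1:]):
            if hi != lo2 or lo >= hi:
                raise ValueError("intervals must be ordered, disjoint and contiguous")

    def bands_in(self, grid: WavelengthGrid, region: str) -> np.ndarray:
        """Indices of grid centers falling in the named region."""
        names = {name for name, _, _ in self.intervals}
        if region not in names:
            raise ValueError(f"unknown region {region!r}")
        return np.array(
            [i for i, c in enumerate(grid.centers) if region_of(c, self) == region],
            dtype=int,
        )


def region_of(wavelength_nm: float, scheme: RegionScheme = RegionScheme()) -> str:
    """Region label of a wavelength under the half-open interval scheme."""
    last = len(scheme.intervals) - 1
    for i, (name, lo, hi) in enumerate(scheme.intervals):
        if lo <= wavelength_nm < hi or (i == last and wavelength_nm == hi):
            return name
    lo0 = scheme.intervals[0][1]
    hi_last = scheme.intervals[-1][2]
    raise ValueError(
        f"wavelength {wavelength_nm} nm outside scheme coverage [{lo0}, {hi_last}]"
    )


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one selector run: scores plus the chosen bands."""

    method: str
    k: int
    band_indices: tuple[int, ...]
    wavelengths_nm: tuple[float, ...]
    scores: np.ndarray = field(repr=False)
    regions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.band_indices) != self.k:
            raise ValueError("band_indices length must equal k")
        if any(b <= a for a, b in zip(self.band_indices, self.band_indices[1:])):
            raise ValueError("band_indices must be strictly increasing")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "method": self.method,
                "k": self.k,
                "band_indices": list(self.band_indices),
                "wavelengths_nm": list(self.wavelengths_nm),
                "regions": list(self.regions),
                "scores": [None if not np.isfinite(s) else float(s) for s in self.scores],
            },
            sort_keys=True,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def _require_two_classes(dataset: LabeledDataset) -> None:
    if len(dataset.class_counts()) < 2:
        raise ValueError("selection needs samples from both classes")


def fi_scores(dataset: LabeledDataset, seed: int = 0, **forest_kwargs) -> np.ndarray:
    """Per-band mean impurity-decrease importances of a random forest.

    Importances are non-negative and sum to 1 (provided at least one
    split was made).  The forest uses the classification configuration
    shared with the evaluation module unless overridden.
    """
    _require_two_classes(dataset)
    config = {**FOREST_CONFIG, **forest_kwargs}
    forest = RandomForestClassifier(random_state=seed, **config)
    forest.fit(dataset.X, dataset.y.astype(str))
    return forest.feature_importances_


def anova_f_scores(dataset: LabeledDataset) -> np.ndarray:
    """One-way ANOVA F statistic per band (MS_between / MS_within).

    Bands whose within-class variance is zero while class means differ
    get ``inf`` so they rank above every finite score; bands constant
    across all samples score 0.
    """
    _require_two_classes(dataset)
    counts = dataset.class_counts()
    if min(counts.values()) < 2:
        raise ValueError("ANOVA needs at least 2 samples per class")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores, _ = f_classif(dataset.X, dataset.y.astype(str))
    return np.nan_to_num(scores, nan=0.0, posinf=np.inf)


def _ranked_order(scores: np.ndarray) -> np.ndarray:
    # stable sort on negated scores: ties resolve to the lower band index
    return np.argsort(-np.asarray(scores, dtype=np.float64), kind="stable")


def select_k_best(
    scores: np.ndarray,
    k: int,
    *,
    method: str = "SKB",
    grid: WavelengthGrid | None = None,
    scheme: RegionScheme = RegionScheme(),
) -> SelectionResult:
    """Indices of the ``k`` largest scores; ties favour lower band index."""
    scores = np.asarray(scores, dtype=np.float64)
    n = scores.size
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    chosen = tuple(sorted(_ranked_order(scores)[:k].tolist()))
    if grid is not None:
        wavelengths = tuple(float(grid.centers[i]) for i in chosen)
        regions = tuple(region_of(w, scheme) for w in wavelengths)
    else:
        wavelengths = tuple(float(i) for i in chosen)
        regions = ()
    return SelectionResult(method, k, chosen, wavelengths, scores, regions)


def select_percentile(
    scores: np.ndarray,
    p: float,
    *,
    method: str = "SP",
    grid: WavelengthGrid | None = None,
    scheme: RegionScheme = RegionScheme(),
) -> SelectionResult:
    """Top ``floor(p * n / 100)`` scores (at least one band)."""
    if not 0 < p <= 100:
        raise ValueError("percentile must lie in (0, 100]")
    n = np.asarray(scores).size
    k = max(1, int(np.floor(p * n / 100.0)))
    return select_k_best(scores, k, method=method, grid=grid, scheme=scheme)


def correlation_matrix(
    dataset: LabeledDataset, band_indices: Sequence[int]
) -> np.ndarray:
    """Pearson correlations across samples between the selected bands.

    Zero-variance bands yield NaN rows/columns (flagged missing); valid
    diagonal entries are exactly 1.
    """
    idx = np.asarray(band_indices, dtype=int)
    if dataset.n_samples < 2 or idx.size < 1:
        raise ValueError("need >= 2 samples and >= 1 band")
    X = dataset.X[:, idx]
    sd = X.std(axis=0, ddof=1)
    centered = X - X.mean(axis=0)
    cov = centered.T @ centered / (X.shape[0] - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = cov / np.outer(sd, sd)
    corr[np.outer(sd == 0, np.ones(idx.size, bool))] = np.nan
    corr[np.outer(np.ones(idx.size, bool), sd == 0)] = np.nan
    good = sd > 0
    corr[np.ix_(good, good)] = np.clip(corr[np.ix_(good, good)], -1.0, 1.0)
    corr[np.diag_indices_from(corr)] = np.where(good, 1.0, np.nan)
    return corr
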