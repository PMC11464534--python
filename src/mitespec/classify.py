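"""Classifier training and paired evaluation of band subsets.

The evaluation design mirrors a standard leaf-level benchmark: a
stratified 70:30 split, optional five-fold grid tuning, and three
selector->classifier pairings -- forest feature importance feeds a
random forest (FI->RF), top-k ANOVA feeds an RBF support vector machine
(SKB->SVM), and the percentile selector feeds k-nearest neighbours
(SP->KNN).  Each pairing is scored with the full spectrum and with its
ten and five best wavelengths, reporting confusion counts (infested =
positive class) and accuracy / precision / recall / F1 as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .selection import (
    FOREST_CONFIG,
    RegionScheme,
    SelectionResult,
    anova_f_scores,
    fi_scores,
    select_k_best,
    select_percentile,
)
from .signatures import LabeledDataset

__all__ = [
    "ClassifierSpec",
    "SplitSpec",
    "EvaluationReport",
    "default_spec",
    "split_dataset",
    "tune_hyperparameters",
    "train_classifier",
    "evaluate",
    "run_pairings",
    "reports_to_frame",
    "ablation_drop_band",
    "red_region_experiment",
]

POSITIVE_LABEL = "infested"

#: selector -> classifier pairing plan
PAIRINGS = (("FI", "RF"), ("SKB", "SVM"), ("SP", "KNN"))

_DEFAULT_PARAMS = {
    "RF": dict(FOREST_CONFIG),
    "SVM": dict(C=10.0, gamma=1.0, kernel="rbf"),
    "KNN": dict(n_neighbors=5, weights="uniform"),
}


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier family plus its hyperparameters."""

    family: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in _DEFAULT_PARAMS:
            raise ValueError(f"unknown classifier family {self.family!r}")


def default_spec(family: str) -> ClassifierSpec:
    """The default configuration for a family (RF / SVM / KNN)."""
    return ClassifierSpec(family, dict(_DEFAULT_PARAMS[family]))


@dataclass(frozen=True)
class SplitSpec:
    """Train fraction, stratification flag and seed for one split."""

    train_fraction: float = 0.7
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(
    dataset: LabeledDataset, spec: SplitSpec = SplitSpec()
) -> tuple[LabeledDataset, LabeledDataset]:
    """Seeded (stratified) partition into train and test subsets.

    Stratified mode draws round(train_fraction * class size) training
    samples per class (round half up), so a balanced 220 + 220 dataset
    splits 70:30 into 154 + 154 training and 66 + 66 test samples.
    """
    y = dataset.y.astype(str)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("both classes must be present to split")
    rng = np.random.default_rng(spec.seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    if spec.stratified:
        for cls in classes:
            cls_idx = np.flatnonzero(y == cls)
            n_train = _round_half_up(spec.train_fraction * cls_idx.size)
            if n_train == 0 or n_train == cls_idx.size:
                raise ValueError(
                    f"class {cls!r} too small to stratify at "
                    f"train_fraction={spec.train_fraction}"
                )
            perm = rng.permutation(cls_idx)
            train_idx.extend(perm[:n_train].tolist())
            test_idx.extend(perm[n_train:].tolist())
    else:
        perm = rng.permutation(dataset.n_samples)
        n_train = _round_half_up(spec.train_fraction * dataset.n_samples)
        train_idx = perm[:n_train].tolist()
        test_idx = perm[n_train:].tolist()
    train_idx.sort()
    test_idx.sort()
    return dataset.subset_rows(train_idx), dataset.subset_rows(test_idx)


def _make_estimator(spec: ClassifierSpec, seed: int = 0):
    params = {**_DEFAULT_PARAMS[spec.family], **spec.params}
    if spec.family == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if spec.family == "SVM":
        return SVC(**params)
    return KNeighborsClassifier(**params)


def tune_hyperparameters(
    train: LabeledDataset,
    family: str,
    grid: Sequence[dict],
    folds: int = 5,
    seed: int = 0,
) -> ClassifierSpec:
    """Grid search maximizing mean stratified-CV accuracy.

    Ties resolve to the first grid point in declared order, so a grid
    containing a single configuration simply returns it.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if min(train.class_counts().values()) < folds:
        raise ValueError("fold count exceeds the minority class size")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_spec: ClassifierSpec | None = None
    best_score = -np.inf
    for params in grid:
        spec = ClassifierSpec(family, dict(params))
        score = cross_val_score(
            _make_estimator(spec, seed), train.X, train.y.astype(str),
            cv=cv, scoring="accuracy",
        ).mean()
        if score > best_score:  # strict: first grid point wins ties
            best_score = score
            best_spec = spec
    assert best_spec is not None
    return best_spec


def train_classifier(train: LabeledDataset, spec: ClassifierSpec, seed: int = 0):
    """Fit the classifier described by ``spec`` on the training matrix."""
    if len(train.class_counts()) < 2:
        raise ValueError("training set must contain both classes")
    model = _make_estimator(spec, seed)
    model.fit(train.X, train.y.astype(str))
    return model


@dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts and percentage metrics for one evaluation."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    band_subset: tuple[int, ...] = ()
    pairing: str = ""
    undefined: tuple[str, ...] = ()

    @property
    def n_test(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> dict:
    """Accuracy / precision / recall / F1 (percent) from confusion counts.

    Ratios with a zero denominator are reported as 0 and flagged.
    """
    undefined: list[str] = []
    total = tp + fp + fn + tn
    accuracy = 100.0 * (tp + tn) / total if total else 0.0
    if tp + fp:
        precision = 100.0 * tp / (tp + fp)
    else:
        precision, undefined = 0.0, undefined + ["precision"]
    if tp + fn:
        recall = 100.0 * tp / (tp + fn)
    else:
        recall, undefined = 0.0, undefined + ["recall"]
    if recall + precision:
        f1 = 2.0 * recall * precision / (recall + precision)
    else:
        f1, undefined = 0.0, undefined + ["f1"]
    return dict(accuracy=accuracy, precision=precision, recall=recall, f1=f1,
                undefined=tuple(undefined))


def evaluate(
    model,
    test: LabeledDataset,
    *,
    band_subset: Sequence[int] = (),
    pairing: str = "",
    X_test: np.ndarray | None = None,
) -> EvaluationReport:
    """Confusion counts and metrics of ``model`` on the test set.

    ``X_test`` lets callers pass an already band-subset feature matrix;
    by default the full test matrix is used.
    """
    if test.n_samples == 0:
        raise ValueError("empty test set")
    X = test.X if X_test is None else X_test
    pred = np.asarray(model.predict(X)).astype(str)
    truth = test.y.astype(str)
    pos = POSITIVE_LABEL
    tp = int(np.sum((pred == pos) & (truth == pos)))
    fp = int(np.sum((pred == pos) & (truth != pos)))
    fn = int(np.sum((pred != pos) & (truth == pos)))
    tn = int(np.sum((pred != pos) & (truth != pos)))
    m = metrics_from_counts(tp, fp, fn, tn)
    return EvaluationReport(
        tp, fp, fn, tn, m["accuracy"], m["precision"], m["recall"], m["f1"],
        tuple(int(b) for b in band_subset), pairing, m["undefined"],
    )


def _select_bands(
    method: str,
    train: LabeledDataset,
    k: int,
    seed: int,
    scheme: RegionScheme,
) -> SelectionResult:
    if method == "FI":
        scores = fi_scores(train, seed=seed)
        return select_k_best(scores, k, method="FI", grid=train.grid, scheme=scheme)
    if method == "SKB":
        scores = anova_f_scores(train)
        return select_k_best(scores, k, method="SKB", grid=train.grid, scheme=scheme)
    if method == "SP":
        scores = anova_f_scores(train)
        p = 100.0 * k / train.n_bands  # percentile whose floor yields exactly k bands
        return select_percentile(scores, p, method="SP", grid=train.grid, scheme=scheme)
    raise ValueError(f"unknown selection method {method!r}")


def _fit_eval(
    train: LabeledDataset,
    test: LabeledDataset,
    family: str,
    bands: Sequence[int],
    seed: int,
    pairing: str,
) -> EvaluationReport:
    bands = list(bands)
    spec = default_spec(family)
    sub_train = LabeledDataset(
        train.subset_bands(bands), train.y,
        _subgrid(train, bands), train.kind, list(train.sample_ids),
    )
    model = train_classifier(sub_train, spec, seed=seed)
    return evaluate(
        model, test, band_subset=bands, pairing=pairing,
        X_test=test.subset_bands(bands),
    )


def _subgrid(dataset: LabeledDataset, bands: Sequence[int]):
    # classifiers ignore the grid; keep a placeholder grid of matching length
    from .cube_io import WavelengthGrid

    return WavelengthGrid(0.0, 1.0, len(list(bands)))


def run_pairings(
    dataset: LabeledDataset,
    subset_plan: Sequence[int | str] = ("all", 10, 5),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    *,
    train_fraction: float = 0.7,
    scheme: RegionScheme = RegionScheme(),
    select_on_train: bool = True,
) -> list[dict]:
    """Evaluate every pairing x band-subset size x seed combination.

    For each seed the dataset is stratified-split 70:30; band selection
    runs on the training split only (avoiding selection leakage) unless
    ``select_on_train`` is False, in which case scores are computed on
    the full dataset before splitting.  Returns one record per run with
    the selection and the evaluation report.
    """
    if dataset.kind != "MNSS":
        raise ValueError("run_pairings expects SNV-normalized (MNSS) signatures")
    records: list[dict] = []
    for seed in seeds:
        train, test = split_dataset(dataset, SplitSpec(train_fraction, True, seed))
        sel_source = train if select_on_train else dataset
        for method, family in PAIRINGS:
            for size in subset_plan:
                if size == "all":
                    bands = list(range(dataset.n_bands))
                    selection = None
                else:
                    selection = _select_bands(method, sel_source, int(size), seed, scheme)
                    bands = list(selection.band_indices)
                report = _fit_eval(train, test, family, bands, seed,
                                   pairing=f"{method}->{family}")
                records.append(
                    dict(seed=seed, method=method, family=family,
                         subset="all" if size == "all" else int(size),
                         selection=selection, report=report)
                )
    return records


def reports_to_frame(records: Sequence[dict]) -> pd.DataFrame:
    """Flatten pairing records into a tidy one-row-per-run DataFrame."""
    rows = []
    for r in records:
        rep: EvaluationReport = r["report"]
        sel: SelectionResult | None = r.get("selection")
        rows.append(
            dict(
                seed=r["seed"], method=r["method"], family=r["family"],
                subset=r["subset"], n_bands=len(rep.band_subset),
                wavelengths="|".join(f"{w:g}" for w in sel.wavelengths_nm) if sel else "all",
                tp=rep.tp, fp=rep.fp, fn=rep.fn, tn=rep.tn,
                accuracy=rep.accuracy, precision=rep.precision,
                recall=rep.recall, f1=rep.f1,
            )
        )
    return pd.DataFrame(rows)


def ablation_drop_band(
    dataset: LabeledDataset,
    selection: SelectionResult,
    band_index: int,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    *,
    family: str = "RF",
    train_fraction: float = 0.7,
) -> list[tuple[EvaluationReport, EvaluationReport]]:
    """Paired before/after reports when one selected band is deleted.

    Both members of each pair share the same split seed, so any metric
    difference is attributable to the dropped band.
    """
    if band_index not in selection.band_indices:
        raise ValueError(f"band {band_index} is not part of the selection")
    reduced = [b for b in selection.band_indices if b != band_index]
    pairs = []
    for seed in seeds:
        train, test = split_dataset(dataset, SplitSpec(train_fraction, True, seed))
        before = _fit_eval(train, test, family, list(selection.band_indices), seed,
                           pairing=f"{selection.method}->{family}")
        after = _fit_eval(train, test, family, reduced, seed,
                          pairing=f"{selection.method}->{family} (-band {band_index})")
        pairs.append((before, after))
    return pairs


def red_region_experiment(
    dataset: LabeledDataset,
    scheme: RegionScheme = RegionScheme(),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    *,
    family: str = "RF",
    train_fraction: float = 0.7,
) -> dict:
    """Classify using exactly the red-region bands.

    Returns the red band count, the band list and one report per seed;
    used to contrast against few-band selections drawn from the
    informative (green/NIR) regions.
    """
    red_bands = scheme.bands_in(dataset.grid, "red")
    if red_bands.size == 0:
        raise ValueError("the region scheme yields no red bands on this grid")
    reports = []
    for seed in seeds:
        train, test = split_dataset(dataset, SplitSpec(train_fraction, True, seed))
        reports.append(
            _fit_eval(train, test, family, red_bands.tolist(), seed,
                      pairing=f"red-only->{family}")
        )
    return dict(n_red_bands=int(red_bands.size), band_indices=red_bands.tolist(),
                reports=reports)
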