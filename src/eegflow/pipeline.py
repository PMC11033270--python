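"""Hold-out split, sevenfold cross-validated evaluation, and orchestration.

Protocol: one-seventh of the window samples is held out (stratified); AUC
ranking, top-k pooling, second-layer selection and the reported k-fold
cross-validation all run on the remaining six-sevenths, so no fitted artifact
ever sees test labels. Headline numbers are the cross-validation means; the
held-out test metrics are reported alongside as a confirmation.

Classifiers: RBF-kernel SVM (C = 1, gamma = 'scale'), linear discriminant
analysis, random forest (100 trees), decision tree — all behind a per-fold
standardisation step. Metrics (accuracy, precision, recall, F1; positive
class = high workload) are on the percent scale, mean +/- std over folds,
recomputable exactly from the stored per-fold confusion matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .ddtf import ConnectivityConfig, connectivity_for_recording
from .preprocess import PreprocessConfig, preprocess_pipeline
from .ranking import (DEFAULT_K_FOLDS, DEFAULT_TOP_K, FeatureTable, RankedFeature,
                      feature_table, rank_features, region_summary, top_k_per_band)
from .selection import SelectionResult, forward_select, mrmr_select, relieff_select
from .synthetic import HIGH, LabeledDataset

POSITIVE_LABEL = HIGH
UNDEFINED = float("nan")


@dataclass(frozen=True)
class ModelSpec:
    kind: str = "svm"
    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    n_trees: int = 100
    max_depth: int | None = None
    seed: int = 0

    def build(self):
        if self.kind == "svm":
            clf = SVC(kernel=self.kernel, C=self.C, gamma=self.gamma, random_state=self.seed)
        elif self.kind == "lda":
            clf = LinearDiscriminantAnalysis()
        elif self.kind == "rf":
            clf = RandomForestClassifier(n_estimators=self.n_trees, random_state=self.seed)
        elif self.kind == "dt":
            clf = DecisionTreeClassifier(max_depth=self.max_depth, random_state=self.seed)
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")
        return make_pipeline(StandardScaler(), clf)


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float, float, float]:
    """(accuracy, precision, recall, F1) in percent; 0/0 reported as NaN."""
    if min(tp, fp, fn, tn) < 0 or tp + fp + fn + tn == 0:
        raise ValueError("confusion counts must be non-negative and sum > 0")
    n = tp + fp + fn + tn
    acc = 100.0 * (tp + tn) / n
    prec = 100.0 * tp / (tp + fp) if tp + fp > 0 else UNDEFINED
    rec = 100.0 * tp / (tp + fn) if tp + fn > 0 else UNDEFINED
    if np.isnan(prec) or np.isnan(rec) or prec + rec == 0:
        f1 = UNDEFINED
    else:
        f1 = 2 * prec * rec / (prec + rec)
    return acc, prec, rec, f1


@dataclass
class EvalReport:
    model: ModelSpec
    confusions: list[tuple[int, int, int, int]]     # (tp, fp, fn, tn) per fold
    fold_assignment: list[np.ndarray] = field(default_factory=list)

    def fold_metrics(self) -> pd.DataFrame:
        rows = [metrics_from_confusion(*c) for c in self.confusions]
        return pd.DataFrame(rows, columns=["accuracy", "precision", "recall", "f1"])

    def mean(self, metric: str = "accuracy") -> float:
        return float(self.fold_metrics()[metric].mean())

    def std(self, metric: str = "accuracy") -> float:
        return float(self.fold_metrics()[metric].std(ddof=1))

    def summary(self) -> dict[str, str]:
        fm = self.fold_metrics()
        return {m: f"{fm[m].mean():.2f}% (+/- {fm[m].std(ddof=1):.2f})" for m in fm.columns}


def crossval_evaluate(table: FeatureTable, model: ModelSpec | None = None,
                      k_folds: int = DEFAULT_K_FOLDS, seed: int = 0) -> EvalReport:
    """Stratified k-fold evaluation with per-fold standardisation."""
    spec = model or ModelSpec("svm", seed=seed)
    y = (table.y == POSITIVE_LABEL).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    confusions, folds = [], []
    for tr, te in skf.split(table.X, y):
        clf = spec.build()
        clf.fit(table.X[tr], y[tr])
        pred = clf.predict(table.X[te])
        yt = y[te]
        tp = int(np.sum((pred == 1) & (yt == 1)))
        fp = int(np.sum((pred == 1) & (yt == 0)))
        fn = int(np.sum((pred == 0) & (yt == 1)))
        tn = int(np.sum((pred == 0) & (yt == 0)))
        confusions.append((tp, fp, fn, tn))
        folds.append(te)
    return EvalReport(spec, confusions, folds)


def crossval_evaluate_ranked(table: FeatureTable, model: ModelSpec | None = None,
                             k_folds: int = DEFAULT_K_FOLDS, seed: int = 0,
                             top_k: int = DEFAULT_TOP_K,
                             band: str | None = None) -> EvalReport:
    """Stratified k-fold CV with the AUC ranking nested inside each fold.

    Per fold, features are ranked by LDA AUC on the training folds only and
    the top-k per band (optionally restricted to one band) are used to fit
    the classifier — so the held-out fold never influences feature selection
    and the reported accuracy carries no selection optimism. Under a null
    dataset this evaluator sits at chance where naive post-selection CV does
    not.
    """
    spec = model or ModelSpec("svm", seed=seed)
    y = (table.y == POSITIVE_LABEL).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    confusions, folds = [], []
    for tr, te in skf.split(table.X, y):
        train = table.subset(rows=tr)
        ranked = rank_features(train, k_folds=k_folds, seed=seed)
        if band is not None:
            ranked = [r for r in ranked if r.band == band]
        pooled = top_k_per_band(ranked, top_k)
        feats = [(r.band, r.source, r.target) for r in pooled]
        cols = [table.feature_index.get_loc(f) for f in feats]
        clf = spec.build()
        clf.fit(table.X[np.ix_(tr, cols)], y[tr])
        pred = clf.predict(table.X[np.ix_(te, cols)])
        yt = y[te]
        tp = int(np.sum((pred == 1) & (yt == 1)))
        fp = int(np.sum((pred == 1) & (yt == 0)))
        fn = int(np.sum((pred == 0) & (yt == 1)))
        tn = int(np.sum((pred == 0) & (yt == 0)))
        confusions.append((tp, fp, fn, tn))
        folds.append(te)
    return EvalReport(spec, confusions, folds)


def holdout_split(table: FeatureTable, fraction: float = 1 / 7,
                  seed: int = 0) -> tuple[FeatureTable, FeatureTable]:
    """Stratified hold-out: returns (train, test), disjoint and exhaustive."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    idx = np.arange(table.n_samples)
    tr, te = train_test_split(idx, test_size=fraction, stratify=table.y,
                              random_state=seed)
    if len(np.unique(table.y[tr])) < 2 or len(np.unique(table.y[te])) < 2:
        raise ValueError("fraction leaves a single-class partition")
    return table.subset(rows=np.sort(tr)), table.subset(rows=np.sort(te))


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: PreprocessConfig | None = None      # None skips cleaning
    connectivity: ConnectivityConfig = ConnectivityConfig(order=2)
    holdout_fraction: float = 1 / 7
    k_folds: int = DEFAULT_K_FOLDS
    top_k: int = DEFAULT_TOP_K
    ranking_k_folds: int = DEFAULT_K_FOLDS
    selectors: tuple[str, ...] = ("forward", "mrmr", "relieff")
    forward_max_features: int = 20
    models: tuple[str, ...] = ("svm", "lda", "rf", "dt")
    seed: int = 0


@dataclass
class PipelineReport:
    config: PipelineConfig
    ranked: list[RankedFeature]
    pooled: list[RankedFeature]
    region_counts: object
    band_reports: dict[str, dict[str, EvalReport]]      # band -> model kind -> report
    pooled_reports: dict[str, EvalReport]               # model kind -> report
    selection_results: dict[str, SelectionResult]
    selector_reports: dict[str, dict[str, EvalReport]]  # selector -> model -> report
    test_accuracy: dict[str, float]                     # selector -> held-out accuracy %
    seed: int = 0

    def best(self) -> tuple[str, str, float]:
        """(selector, model, accuracy) of the best selector/model combination."""
        best = ("", "", -np.inf)
        for sel, reps in self.selector_reports.items():
            for kind, rep in reps.items():
                acc = rep.mean("accuracy")
                if acc > best[2]:
                    best = (sel, kind, acc)
        return best


def _table_from_dataset(dataset: LabeledDataset, cfg: PipelineConfig) -> FeatureTable:
    tensors = []
    for rec in dataset.recordings:
        if cfg.preprocess is not None:
            rec = preprocess_pipeline(rec, cfg.preprocess)
        t = connectivity_for_recording(rec, cfg.connectivity)
        t.recording_id = f"{rec.subject_id}"
        t.condition = rec.condition
        tensors.append(t)
    return feature_table(tensors)


def run_full_pipeline(dataset: LabeledDataset, config: PipelineConfig | None = None) -> PipelineReport:
    """Execute the whole analysis on a labelled dataset.

    preprocess -> connectivity -> feature table -> 1/7 hold-out -> LDA-AUC
    ranking (train only) -> per-band and pooled CV evaluation -> second-layer
    selectors -> CV evaluation per selector -> held-out confirmation.
    """
    cfg = config or PipelineConfig()
    table = _table_from_dataset(dataset, cfg)
    train, test = holdout_split(table, cfg.holdout_fraction, seed=cfg.seed)

    ranked = rank_features(train, k_folds=cfg.ranking_k_folds, seed=cfg.seed)
    pooled = top_k_per_band(ranked, cfg.top_k)
    regions = region_summary(pooled)

    def _spec(kind: str) -> ModelSpec:
        return ModelSpec(kind, seed=cfg.seed)

    # per-band and pooled CV with the ranking nested in each fold, so the
    # reported accuracies carry no feature-selection optimism
    band_reports: dict[str, dict[str, EvalReport]] = {}
    for band in {r.band for r in pooled}:
        band_reports[band] = {
            k: crossval_evaluate_ranked(train, _spec(k), cfg.k_folds, cfg.seed,
                                        top_k=cfg.top_k, band=band)
            for k in cfg.models}
    pooled_reports = {
        k: crossval_evaluate_ranked(train, _spec(k), cfg.k_folds, cfg.seed,
                                    top_k=cfg.top_k)
        for k in cfg.models}
    pooled_feats = [(r.band, r.source, r.target) for r in pooled]
    pooled_table = train.subset(features=pooled_feats)

    selection_results: dict[str, SelectionResult] = {}
    selector_reports: dict[str, dict[str, EvalReport]] = {}
    test_accuracy: dict[str, float] = {}
    for sel in cfg.selectors:
        if sel == "forward":
            res = forward_select(pooled_table, _spec("svm"), k_folds=cfg.k_folds,
                                 max_features=cfg.forward_max_features, seed=cfg.seed)
        elif sel in ("mrmr", "relieff"):
            # filters default to the forward-selection count for an equal-footing comparison
            n_sel = (len(selection_results["forward"].selected)
                     if "forward" in selection_results else cfg.forward_max_features)
            if sel == "mrmr":
                res = mrmr_select(pooled_table, n_select=n_sel)
            else:
                res = relieff_select(pooled_table, n_select=n_sel, seed=cfg.seed)
        else:
            raise ValueError(f"unknown selector {sel!r}")
        if not res.selected:
            continue
        selection_results[sel] = res
        sel_table = train.subset(features=res.selected)
        selector_reports[sel] = {k: crossval_evaluate(sel_table, _spec(k), cfg.k_folds, cfg.seed)
                                 for k in cfg.models}
        # held-out confirmation with the best in-CV model for this selector
        best_kind = max(selector_reports[sel], key=lambda k: selector_reports[sel][k].mean())
        clf = _spec(best_kind).build()
        clf.fit(sel_table.X, (sel_table.y == POSITIVE_LABEL).astype(int))
        te = test.subset(features=res.selected)
        pred = clf.predict(te.X)
        test_accuracy[sel] = float(100.0 * np.mean(pred == (te.y == POSITIVE_LABEL).astype(int)))

    return PipelineReport(cfg, ranked, pooled, regions, band_reports, pooled_reports,
                          selection_results, selector_reports, test_accuracy, seed=cfg.seed)
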