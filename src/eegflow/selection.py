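"""Second feature-selection layer on the pooled candidate set.

Three methods operating on equal footing:

* forward selection — a greedy wrapper that at each step adds the candidate
  maximising mean k-fold cross-validated accuracy of the chosen classifier,
  stopping when the best improvement falls below ``epsilon`` or a cap is hit;
  the per-step accuracy trace is recorded;
* mRMR (MID variant) — discretize into equal-frequency bins, then greedily
  maximise MI(feature; class) minus the mean MI with already-selected features;
* Relief-F — instance-based weights from k nearest hits and misses on
  min-max-scaled features, supervised by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .ranking import FeatureTable

DEFAULT_EPSILON = 1e-4
DEFAULT_MAX_FEATURES = 50
DEFAULT_N_BINS = 10
DEFAULT_K_NEIGHBORS = 10


@dataclass
class SelectionResult:
    method: str
    selected: list[tuple[str, str, str]]     # (band, source, target)
    accuracy_trace: list[float] = field(default_factory=list)
    scores: dict[tuple[str, str, str], float] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, feat in enumerate(self.selected):
            band, s, t = feat
            rows.append({
                "step": i + 1,
                "feature": f"{s}=>{t}",
                "band": band,
                "cv_accuracy": self.accuracy_trace[i] if i < len(self.accuracy_trace) else np.nan,
                "score": self.scores.get(feat, np.nan),
            })
        return pd.DataFrame(rows)


def forward_select(table: FeatureTable, model_spec=None, k_folds: int = 7,
                   epsilon: float = DEFAULT_EPSILON,
                   max_features: int = DEFAULT_MAX_FEATURES,
                   seed: int = 0) -> SelectionResult:
    """Greedy wrapper selection driven by cross-validated accuracy.

    ``model_spec`` is a ModelSpec (see pipeline module) or None for the
    default SVM. Standardisation is fitted inside each training fold.
    """
    from .pipeline import ModelSpec, crossval_evaluate

    spec = model_spec or ModelSpec("svm", seed=seed)
    if table.n_features < 1:
        raise ValueError("need at least one feature")
    features = list(table.feature_index)
    selected: list[tuple[str, str, str]] = []
    trace: list[float] = []
    best_acc = -np.inf
    while len(selected) < min(max_features, len(features)):
        remaining = [f for f in features if f not in selected]
        step_best, step_feat = -np.inf, None
        for f in remaining:
            sub = table.subset(features=selected + [f])
            try:
                rep = crossval_evaluate(sub, spec, k_folds=k_folds, seed=seed)
            except Exception:
                continue  # degenerate candidate (e.g. constant column)
            acc = rep.mean("accuracy")
            if acc > step_best:
                step_best, step_feat = acc, f
        if step_feat is None or (trace and step_best - best_acc < epsilon * 100):
            break
        selected.append(step_feat)
        trace.append(step_best)
        best_acc = step_best
    return SelectionResult("forward", selected, accuracy_trace=trace,
                           config={"k_folds": k_folds, "epsilon": epsilon,
                                   "max_features": max_features, "model": spec.kind},
                           seed=seed)


def _discretize(X: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning per column; constant columns map to one bin."""
    out = np.zeros_like(X, dtype=int)
    for j in range(X.shape[1]):
        col = X[:, j]
        qs = np.unique(np.quantile(col, np.linspace(0, 1, n_bins + 1)[1:-1]))
        out[:, j] = np.searchsorted(qs, col, side="right")
    return out


def mrmr_select(table: FeatureTable, labels: np.ndarray | None = None,
                n_select: int = DEFAULT_MAX_FEATURES,
                n_bins: int = DEFAULT_N_BINS) -> SelectionResult:
    """Greedy max-relevance min-redundancy (MID: relevance minus mean redundancy)."""
    y = labels if labels is not None else table.y
    n_select = min(n_select, table.n_features)
    Xd = _discretize(table.X, n_bins)
    n_f = table.n_features
    relevance = np.array([mutual_info_score(y, Xd[:, j]) for j in range(n_f)])
    features = list(table.feature_index)
    selected_idx: list[int] = []
    scores: dict[tuple[str, str, str], float] = {}
    mi_cache = np.full((n_f, n_f), np.nan)
    while len(selected_idx) < n_select:
        best_j, best_score = None, -np.inf
        for j in range(n_f):
            if j in selected_idx:
                continue
            if selected_idx:
                reds = []
                for s in selected_idx:
                    if np.isnan(mi_cache[j, s]):
                        mi_cache[j, s] = mi_cache[s, j] = mutual_info_score(Xd[:, j], Xd[:, s])
                    reds.append(mi_cache[j, s])
                score = relevance[j] - float(np.mean(reds))
            else:
                score = relevance[j]
            if score > best_score:
                best_score, best_j = score, j
        selected_idx.append(best_j)
        scores[features[best_j]] = float(best_score)
    return SelectionResult("mrmr", [features[j] for j in selected_idx], scores=scores,
                           config={"n_bins": n_bins, "n_select": n_select})


def relieff_weights(X: np.ndarray, y: np.ndarray, k_neighbors: int = DEFAULT_K_NEIGHBORS,
                    seed: int = 0) -> np.ndarray:
    """Relief-F feature weights using k nearest hits and misses per instance.

    Features are min-max scaled for the distance computation; all instances
    are used (deterministic up to the seed used for tie ordering).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n, n_f = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts <= k_neighbors):
        raise ValueError(
            f"every class needs > {k_neighbors} members; lower k_neighbors")
    rng = np.random.default_rng(seed)
    span = X.max(axis=0) - X.min(axis=0)
    span = np.where(span > 0, span, 1.0)
    Xs = (X - X.min(axis=0)) / span
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    W = np.zeros(n_f)
    # tiny deterministic perturbation of distances breaks ties stably per seed
    jitter = rng.uniform(0, 1e-12, size=n)
    for i in range(n):
        d = np.abs(Xs - Xs[i]).sum(axis=1) + jitter
        d[i] = np.inf
        for c in classes:
            mask = y == c
            idx = np.flatnonzero(mask)
            order = idx[np.argsort(d[idx])][:k_neighbors]
            diff = np.abs(Xs[order] - Xs[i]).mean(axis=0)
            if c == y[i]:
                W -= diff / n
            else:
                W += (priors[c] / (1 - priors[y[i]])) * diff / n
    return W


def relieff_select(table: FeatureTable, labels: np.ndarray | None = None,
                   n_select: int = DEFAULT_MAX_FEATURES,
                   k_neighbors: int = DEFAULT_K_NEIGHBORS,
                   seed: int = 0) -> SelectionResult:
    y = labels if labels is not None else table.y
    W = relieff_weights(table.X, y, k_neighbors=k_neighbors, seed=seed)
    n_select = min(n_select, table.n_features)
    features = list(table.feature_index)
    order = np.argsort(-W, kind="stable")[:n_select]
    return SelectionResult("relieff", [features[j] for j in order],
                           scores={features[j]: float(W[j]) for j in order},
                           config={"k_neighbors": k_neighbors, "n_select": n_select},
                           seed=seed)
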