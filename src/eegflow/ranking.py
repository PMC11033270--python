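"""First feature-selection layer: per-connection discriminability by LDA AUC.

Every directed connection (band, source, target) is scored with the
cross-validated ROC-AUC of a single-feature linear discriminant, the top-k
connections per band are pooled (k = 30 -> 150 pooled candidates over the
five bands), and the ranked lists are summarised per electrode and per scalp
region — frontal, occipital, parietal, temporal — in both directions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .ddtf import BAND_NAMES, ConnectivityTensor

# 10-20 electrode -> scalp lobe map for the 14-channel montage
ELECTRODE_REGIONS: dict[str, str] = {
    "AF3": "frontal", "F7": "frontal", "F3": "frontal", "FC5": "frontal",
    "FC6": "frontal", "F4": "frontal", "F8": "frontal", "AF4": "frontal",
    "O1": "occipital", "O2": "occipital",
    "P7": "parietal", "P8": "parietal",
    "T7": "temporal", "T8": "temporal",
}
REGIONS = ("frontal", "occipital", "parietal", "temporal")

DEFAULT_TOP_K = 30
DEFAULT_K_FOLDS = 7


@dataclass(frozen=True)
class RankedFeature:
    band: str
    source: str
    target: str
    auc: float

    @property
    def name(self) -> str:
        return f"{self.band}:{self.source}=>{self.target}"


@dataclass
class FeatureTable:
    """Window-samples x directed-connection features.

    One row per valid window per recording; columns are (band, source, target)
    triples with self-edges excluded: 5 x M x (M-1) columns for M channels.
    """

    X: np.ndarray
    feature_index: pd.MultiIndex           # levels: band, source, target
    y: np.ndarray                          # class labels (strings)
    subjects: np.ndarray
    window_index: np.ndarray

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_index)
        df.insert(0, ("meta", "label", ""), self.y)
        df.insert(1, ("meta", "subject", ""), self.subjects)
        df.insert(2, ("meta", "window", ""), self.window_index)
        return df

    def subset(self, rows: np.ndarray | None = None,
               features: list[tuple[str, str, str]] | None = None) -> "FeatureTable":
        X, y, subj, win = self.X, self.y, self.subjects, self.window_index
        idx = self.feature_index
        if rows is not None:
            X, y, subj, win = X[rows], y[rows], subj[rows], win[rows]
        if features is not None:
            cols = [idx.get_loc(f) for f in features]
            X = X[:, cols]
            idx = pd.MultiIndex.from_tuples(features, names=idx.names)
        return FeatureTable(X, idx, y, subj, win)

    def write_csv(self, path) -> None:
        df = pd.DataFrame(self.X, columns=[f"{b}:{s}=>{t}" for b, s, t in self.feature_index])
        df.insert(0, "label", self.y)
        df.insert(1, "subject", self.subjects)
        df.insert(2, "window", self.window_index)
        # default float formatting is the shortest round-tripping repr: the
        # written table reads back bit-exactly
        df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path, float_precision="round_trip")
        meta = df[["label", "subject", "window"]]
        feat = df.drop(columns=["label", "subject", "window"])
        tuples = []
        for c in feat.columns:
            band, edge = c.split(":")
            s, t = edge.split("=>")
            tuples.append((band, s, t))
        return cls(feat.to_numpy(), pd.MultiIndex.from_tuples(tuples, names=["band", "source", "target"]),
                   meta["label"].to_numpy(), meta["subject"].to_numpy(), meta["window"].to_numpy())


def feature_table(tensors: list[ConnectivityTensor]) -> FeatureTable:
    """Flatten connectivity tensors into one sample per (recording, window).

    Self-edges are excluded; invalid windows are dropped. All tensors must
    share channel and band structure.
    """
    if not tensors:
        raise ValueError("no tensors given")
    ch = tensors[0].channel_names
    bands = tensors[0].band_names
    for t in tensors:
        if t.channel_names != ch or t.band_names != bands:
            raise ValueError("tensors have mismatched channel or band structure")
    m = len(ch)
    cols = [(band, ch[j], ch[i])
            for band in bands for j in range(m) for i in range(m) if i != j]
    col_pos = [(bands.index(b), ch.index(t_), ch.index(s))  # values[b, target, source]
               for b, s, t_ in cols]
    rows, ys, subjects, windows = [], [], [], []
    for t in tensors:
        ok = t.valid if t.valid is not None else np.ones(t.n_windows, bool)
        for wi in range(t.n_windows):
            if not ok[wi]:
                continue
            rows.append([t.values[wi, bi, ti, si] for bi, ti, si in col_pos])
            ys.append(t.condition)
            subjects.append(t.recording_id)
            windows.append(wi)
    index = pd.MultiIndex.from_tuples(cols, names=["band", "source", "target"])
    return FeatureTable(np.asarray(rows, float), index, np.asarray(ys),
                        np.asarray(subjects), np.asarray(windows))


def feature_auc_lda(column: np.ndarray, labels: np.ndarray,
                    k_folds: int = DEFAULT_K_FOLDS, seed: int = 0,
                    positive_label: str = "high") -> float:
    """Mean held-out ROC-AUC of a single-feature LDA score over stratified folds."""
    column = np.asarray(column, float).reshape(-1, 1)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    y = (labels == positive_label).astype(int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(column, y):
        x_tr = column[tr, 0]
        within_var = (x_tr[y[tr] == 1].var() + x_tr[y[tr] == 0].var())
        if within_var == 0.0:
            # degenerate (e.g. perfectly separated constants): 1-D LDA reduces
            # to orienting the feature by the training-fold mean difference
            sign = np.sign(x_tr[y[tr] == 1].mean() - x_tr[y[tr] == 0].mean())
            scores = sign * column[te, 0]
        else:
            lda = LinearDiscriminantAnalysis()
            lda.fit(column[tr], y[tr])
            scores = lda.decision_function(column[te])
        aucs.append(roc_auc_score(y[te], scores))
    return float(np.mean(aucs))


def _fold_auc_oriented(x_test: np.ndarray, y_test: np.ndarray,
                       orientation: np.ndarray) -> np.ndarray:
    """Held-out ROC-AUC of oriented single-feature scores, all columns at once.

    For one feature, the LDA score is a positive multiple of
    sign(mean_pos - mean_neg) times the feature value, so its held-out ROC-AUC
    equals the tie-corrected Mann-Whitney AUC of the feature oriented by the
    training-fold mean difference; a zero mean difference gives constant
    scores, hence AUC 1/2.
    """
    from scipy.stats import rankdata

    scores = x_test * orientation[None, :]
    n1 = int(y_test.sum())
    n0 = len(y_test) - n1
    ranks = rankdata(scores, axis=0)
    u = ranks[y_test == 1].sum(axis=0) - n1 * (n1 + 1) / 2
    auc = u / (n1 * n0)
    return np.where(orientation == 0, 0.5, auc)


def rank_features(table: FeatureTable, k_folds: int = DEFAULT_K_FOLDS,
                  seed: int = 0, positive_label: str = "high") -> list[RankedFeature]:
    """Score every connection column with its cross-validated LDA AUC.

    Vectorised over columns via the rank-statistic identity (see
    ``_fold_auc_oriented``); ``feature_auc_lda`` is the per-column reference
    implementation and agrees to machine precision.
    """
    y = (table.y == positive_label).astype(int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_aucs = []
    for tr, te in skf.split(table.X, y):
        mu1 = table.X[tr][y[tr] == 1].mean(axis=0)
        mu0 = table.X[tr][y[tr] == 0].mean(axis=0)
        orientation = np.sign(mu1 - mu0)
        fold_aucs.append(_fold_auc_oriented(table.X[te], y[te], orientation))
    mean_auc = np.mean(fold_aucs, axis=0)
    return [RankedFeature(band, src, tgt, float(mean_auc[col]))
            for col, (band, src, tgt) in enumerate(table.feature_index)]


def top_k_per_band(ranked: list[RankedFeature], k: int = DEFAULT_TOP_K) -> list[RankedFeature]:
    """Per band, the k highest-AUC connections; pooled sorted by band then AUC.

    Ties at the cut are broken by lexicographic (band, source, target) order,
    so the result is a deterministic function of the input.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    pooled: list[RankedFeature] = []
    bands = [b for b in BAND_NAMES if any(r.band == b for r in ranked)]
    for band in bands:
        cand = [r for r in ranked if r.band == band]
        cand.sort(key=lambda r: (-r.auc, r.band, r.source, r.target))
        pooled.extend(cand[:k])
    return pooled


@dataclass
class RegionCounts:
    """Connection counts per region x band x direction, plus per-electrode tallies."""

    from_counts: pd.DataFrame   # regions x bands
    to_counts: pd.DataFrame
    electrode_from: pd.Series
    electrode_to: pd.Series

    def total(self, region: str, direction: str = "from") -> int:
        df = self.from_counts if direction == "from" else self.to_counts
        return int(df.loc[region].sum())


def region_summary(ranked: list[RankedFeature],
                   electrode_regions: dict[str, str] | None = None) -> RegionCounts:
    """Count connections originating from / terminating in each scalp region."""
    regions = electrode_regions or ELECTRODE_REGIONS
    bands = [b for b in BAND_NAMES if any(r.band == b for r in ranked)]
    region_names = sorted(set(regions.values()), key=lambda r: REGIONS.index(r) if r in REGIONS else 99)
    frm = pd.DataFrame(0, index=region_names, columns=bands)
    to = pd.DataFrame(0, index=region_names, columns=bands)
    e_from: dict[str, int] = {}
    e_to: dict[str, int] = {}
    for r in ranked:
        for e in (r.source, r.target):
            if e not in regions:
                raise KeyError(f"electrode {e!r} has no region mapping")
        frm.loc[regions[r.source], r.band] += 1
        to.loc[regions[r.target], r.band] += 1
        e_from[r.source] = e_from.get(r.source, 0) + 1
        e_to[r.target] = e_to.get(r.target, 0) + 1
    return RegionCounts(frm, to,
                        pd.Series(e_from).sort_values(ascending=False),
                        pd.Series(e_to).sort_values(ascending=False))


def ranked_to_frame(ranked: list[RankedFeature]) -> pd.DataFrame:
    return pd.DataFrame(
        {"band": [r.band for r in ranked],
         "connection": [f"{r.source}=>{r.target}" for r in ranked],
         "auc": [round(r.auc, 3) for r in ranked]})


def load_stew_reference_flows() -> list[RankedFeature]:
    """Published top-30 ranked directed flows per band for the STEW corpus.

    A fixed reference table (150 rows: band, source, target, AUC) used to
    exercise the region bookkeeping on known data; includes one literal
    self-edge ('O1=>O1') present in the published listing.
    """
    ref = importlib.resources.files("eegflow.data") / "stew_top30_flows.csv"
    df = pd.read_csv(ref)
    return [RankedFeature(r.band, r.source, r.target, float(r.auc))
            for r in df.itertuples()]
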