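"""Landscape-metric machine-learning pipeline.

Assembles per-case landscape metrics into feature tables, filters and
normalises them (near-zero-variance removal, rank-based inverse-normal
transform, greedy |r| > 0.75 correlation filter — all fitted on the training
split only), trains a bagged random-forest diagnostic classifier with full
per-tree structure retention for variable-importance introspection, and runs
k-means case clustering.

The forest is a hand-rolled bagging loop over sklearn decision trees
(sqrt(p) features per split) because variable importance here requires the
per-tree bootstrap/out-of-bag indices, root features, node counts and
minimal depths, which sklearn's packaged forest does not expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "split_cases",
    "FeatureFilter",
    "filter_features",
    "RandomForestModel",
    "train_forest",
    "evaluate",
    "variable_importance",
    "pairwise_interactions",
    "kmeans_cases",
]


def split_cases(table: pd.DataFrame, train_fraction: float = 0.8,
                rng_seed: int | None = None, case_col: str = "case_id",
                label_col: str = "label") -> tuple:
    """Split by case id: paired regions of one case never straddle the split.

    For unpaired designs (one label per case) the split is stratified by the
    case label; for paired designs (a case contributes rows of both labels)
    a random case split automatically preserves both classes on each side.
    Raises if either side would lack a class.
    """
    rng = np.random.default_rng(rng_seed)
    cases = table[case_col].unique()
    labels_per_case = table.groupby(case_col)[label_col].nunique()
    paired = (labels_per_case > 1).any()

    if paired:
        cases = rng.permutation(np.sort(cases))
        n_train = int(round(train_fraction * len(cases)))
        train_cases = set(cases[:n_train])
    else:
        case_label = table.groupby(case_col)[label_col].first()
        train_cases = set()
        for lab in np.unique(case_label):
            ids = rng.permutation(np.sort(case_label.index[case_label == lab]))
            n_train = int(round(train_fraction * len(ids)))
            train_cases.update(ids[:n_train])

    in_train = table[case_col].isin(train_cases)
    train, test = table[in_train].copy(), table[~in_train].copy()
    for name, part in (("train", train), ("test", test)):
        present = set(part[label_col].unique())
        if present != set(table[label_col].unique()):
            raise ValueError(f"class missing from {name} split at "
                             f"fraction {train_fraction}")
    return train, test


@dataclass
class FeatureFilter:
    """Fitted feature filter + normaliser; applied (never refit) to test data.

    Steps, fitted on training data only:

    1. drop zero-variance and near-zero-variance features (most-common /
       second-most-common frequency ratio > ``freq_cut`` AND unique-value
       fraction < ``unique_cut``); undefined (NaN) metric values also drop a
       feature here;
    2. per-feature rank-based inverse-normal transform
       (Phi^{-1}((midrank + 0.5) / (n + 1)), test values ranked against the
       stored training sample);
    3. greedy correlation filter: while any |pairwise r| > ``corr_cut``,
       drop the member of the worst pair with the larger mean absolute
       correlation (ties: the later column).
    """

    freq_cut: float = 19.0
    unique_cut: float = 0.10
    corr_cut: float = 0.75
    kept_features: list = field(default_factory=list)
    dropped: dict = field(default_factory=dict)
    _train_sorted: dict = field(default_factory=dict)

    def fit(self, train: pd.DataFrame, feature_cols: list) -> pd.DataFrame:
        n = len(train)
        survivors = []
        for col in feature_cols:
            x = train[col].to_numpy(float)
            if np.isnan(x).any():
                self.dropped[col] = "undefined values"
                continue
            _, counts = np.unique(x, return_counts=True)
            if len(counts) == 1:
                self.dropped[col] = "zero variance"
                continue
            counts = np.sort(counts)[::-1]
            freq_ratio = counts[0] / counts[1]
            unique_frac = len(counts) / n
            if freq_ratio > self.freq_cut and unique_frac < self.unique_cut:
                self.dropped[col] = "near-zero variance"
                continue
            survivors.append(col)
            self._train_sorted[col] = np.sort(x)
        if not survivors:
            raise ValueError("all features removed by the variance filter")

        z = pd.DataFrame({c: self._int_transform(train[c].to_numpy(float), c)
                          for c in survivors}, index=train.index)

        # greedy correlation filter on the normalised training features
        cols = list(z.columns)
        corr = z.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        corr = np.nan_to_num(corr)
        while corr.size and corr.max() > self.corr_cut:
            i, j = np.unravel_index(np.argmax(corr), corr.shape)
            mean_i, mean_j = corr[i].mean(), corr[j].mean()
            drop = (j if mean_j >= mean_i else i) if mean_i != mean_j else max(i, j)
            self.dropped[cols[drop]] = "correlated > %.2f" % self.corr_cut
            cols.pop(drop)
            corr = np.delete(np.delete(corr, drop, 0), drop, 1)
        self.kept_features = cols
        return z[cols]

    def _int_transform(self, x: np.ndarray, col: str) -> np.ndarray:
        ref = self._train_sorted[col]
        n = len(ref)
        midrank = 0.5 * (np.searchsorted(ref, x, side="left")
                         + np.searchsorted(ref, x, side="right"))
        u = (midrank + 0.5) / (n + 1.0)
        return stats.norm.ppf(u)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if not self.kept_features:
            raise RuntimeError("filter has not been fitted")
        return pd.DataFrame(
            {c: self._int_transform(table[c].to_numpy(float), c)
             for c in self.kept_features}, index=table.index)


def filter_features(train: pd.DataFrame, feature_cols: list,
                    **kwargs) -> tuple:
    """Fit the feature filter on training data; returns (filtered, filter)."""
    filt = FeatureFilter(**kwargs)
    filtered = filt.fit(train, feature_cols)
    return filtered, filt


@dataclass
class RandomForestModel:
    """Bagged decision-tree ensemble with retained per-tree structures."""

    trees: list
    bootstrap_idx: list
    feature_names: list
    classes_: np.ndarray
    oob_error: float
    n_train: int

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def _tree_proba(self, tree, X: np.ndarray) -> np.ndarray:
        """Per-tree class probabilities aligned to the model's class order."""
        p = tree.predict_proba(X)
        out = np.zeros((len(X), len(self.classes_)))
        for k, cls in enumerate(tree.classes_):
            out[:, np.searchsorted(self.classes_, cls)] = p[:, k]
        return out

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, float)
        acc = np.zeros((len(X), len(self.classes_)))
        for tree in self.trees:
            acc += self._tree_proba(tree, X)
        return acc / self.n_trees

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def train_forest(train: pd.DataFrame, label: pd.Series | np.ndarray,
                 n_trees: int = 10000, rng_seed: int | None = None) -> RandomForestModel:
    """Train a bagged random forest (sqrt(p) features per split).

    Each tree is fit on a bootstrap resample of the training cases; per-tree
    bootstrap indices are retained so out-of-bag accuracy and permutation
    importance can be computed exactly.
    """
    X = np.asarray(train, float)
    y = np.asarray(label)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    n = len(X)
    rng = np.random.default_rng(rng_seed)
    trees, boots = [], []
    votes = np.zeros((n, len(classes)))
    for _ in range(n_trees):
        idx = rng.integers(0, n, n)
        tree = DecisionTreeClassifier(
            max_features="sqrt", random_state=int(rng.integers(2 ** 31)))
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        boots.append(idx)
        oob = np.setdiff1d(np.arange(n), idx, assume_unique=False)
        if len(oob):
            pred = tree.predict(X[oob])
            for i, p in zip(oob, pred):
                votes[i, np.searchsorted(classes, p)] += 1
    covered = votes.sum(axis=1) > 0
    oob_pred = classes[np.argmax(votes[covered], axis=1)]
    oob_error = float(np.mean(oob_pred != y[covered])) if covered.any() else np.nan
    return RandomForestModel(
        trees=trees, bootstrap_idx=boots,
        feature_names=list(getattr(train, "columns", range(X.shape[1]))),
        classes_=classes, oob_error=oob_error, n_train=n)


def evaluate(model: RandomForestModel, test: pd.DataFrame,
             label: pd.Series | np.ndarray,
             thresholds: np.ndarray | None = None) -> dict:
    """ROC / AUC / F1-by-threshold evaluation on a held-out test set."""
    y = np.asarray(label)
    pos = model.classes_[1]
    prob = model.predict_proba(np.asarray(test, float))[:, 1]
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    y_bin = (y == pos).astype(int)
    if len(np.unique(y_bin)) < 2:
        auc_val, roc = np.nan, None
    else:
        fpr, tpr, thr = roc_curve(y_bin, prob)
        auc_val = float(sk_auc(fpr, tpr))
        roc = pd.DataFrame({"threshold": thr, "tpr": tpr, "fpr": fpr})

    f1s = []
    for t in thresholds:
        pred = (prob >= t).astype(int)
        tp = int(((pred == 1) & (y_bin == 1)).sum())
        fp = int(((pred == 1) & (y_bin == 0)).sum())
        fn = int(((pred == 0) & (y_bin == 1)).sum())
        f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
        f1s.append(f1)
    f1s = np.array(f1s)
    best = int(np.argmax(f1s))
    return {
        "auc": auc_val,
        "roc": roc,
        "f1_by_threshold": pd.DataFrame({"threshold": thresholds, "f1": f1s}),
        "best_threshold": float(thresholds[best]),
        "max_f1": float(f1s[best]),
    }


def _minimal_depths(tree) -> dict:
    """Depth of the shallowest node splitting on each feature (root = 0)."""
    t = tree.tree_
    depths: dict[int, int] = {}
    stack = [(0, 0)]
    max_depth = 0
    while stack:
        node, depth = stack.pop()
        max_depth = max(max_depth, depth)
        f = t.feature[node]
        if f >= 0:
            depths[f] = min(depths.get(f, np.inf), depth)
            stack.append((t.children_left[node], depth + 1))
            stack.append((t.children_right[node], depth + 1))
    return {"depths": depths, "max_depth": max_depth}


def variable_importance(model: RandomForestModel, train: pd.DataFrame,
                        label: pd.Series | np.ndarray,
                        rng_seed: int | None = None) -> pd.DataFrame:
    """Per-feature importance from the retained tree structures.

    Columns: permutation accuracy decrease (out-of-bag), total impurity
    (Gini) decrease, mean minimal depth (trees without the feature
    contribute their max depth + 1), node count, root count, and a one-sided
    binomial p-value for the node count against uniform-random split-variable
    choice.
    """
    X = np.asarray(train, float)
    y = np.asarray(label)
    n, p = X.shape
    rng = np.random.default_rng(rng_seed)

    acc_dec = np.zeros(p)
    gini_dec = np.zeros(p)
    min_depth_sum = np.zeros(p)
    n_nodes = np.zeros(p, int)
    n_root = np.zeros(p, int)
    n_trees_perm = 0
    total_split_nodes = 0

    for tree, idx in zip(model.trees, model.bootstrap_idx):
        t = tree.tree_
        feats = t.feature[t.feature >= 0]
        total_split_nodes += len(feats)
        counts = np.bincount(feats, minlength=p)
        n_nodes += counts
        if t.feature[0] >= 0:
            n_root[t.feature[0]] += 1
        gini_dec += tree.tree_.compute_feature_importances(normalize=False)

        md = _minimal_depths(tree)
        fill = md["max_depth"] + 1
        for f in range(p):
            min_depth_sum[f] += md["depths"].get(f, fill)

        oob = np.setdiff1d(np.arange(n), idx)
        if len(oob) < 2:
            continue
        n_trees_perm += 1
        Xo, yo = X[oob], y[oob]
        base = np.mean(tree.predict(Xo) == yo)
        for f in range(p):
            Xp = Xo.copy()
            Xp[:, f] = Xp[rng.permutation(len(oob)), f]
            acc_dec[f] += base - np.mean(tree.predict(Xp) == yo)

    acc_dec /= max(n_trees_perm, 1)
    p_nodes = stats.binom.sf(n_nodes - 1, total_split_nodes, 1.0 / p)
    return pd.DataFrame({
        "feature": model.feature_names,
        "permutation_accuracy_decrease": acc_dec,
        "impurity_decrease": gini_dec,
        "mean_minimal_depth": min_depth_sum / model.n_trees,
        "n_nodes": n_nodes,
        "n_root": n_root,
        "p_value_nodes": p_nodes,
    }).set_index("feature")


def pairwise_interactions(model: RandomForestModel) -> pd.DataFrame:
    """Simplified pairwise variable-interaction importance.

    Counts, over all trees, how often a split on one feature is the direct
    parent of a split on another (parent-child co-occurrence), as a cheap
    proxy for conditional interaction importance.
    """
    p = len(model.feature_names)
    counts = np.zeros((p, p), int)
    for tree in model.trees:
        t = tree.tree_
        for node in range(t.node_count):
            f = t.feature[node]
            if f < 0:
                continue
            for child in (t.children_left[node], t.children_right[node]):
                cf = t.feature[child]
                if cf >= 0:
                    counts[f, cf] += 1
    rows = [{"parent": model.feature_names[i], "child": model.feature_names[j],
             "count": int(counts[i, j])}
            for i in range(p) for j in range(p) if counts[i, j] > 0]
    return (pd.DataFrame(rows, columns=["parent", "child", "count"])
            .sort_values("count", ascending=False, ignore_index=True))


def kmeans_cases(features: pd.DataFrame, k: int,
                 rng_seed: int | None = None, n_restarts: int = 10) -> dict:
    """Standardised k-means clustering of cases.

    Returns cluster assignments (aligned with the table's row order) and the
    within-cluster sum of squares.
    """
    X = np.asarray(features, float)
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of cases {len(X)}")
    Xs = StandardScaler().fit_transform(X)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=rng_seed)
    labels = km.fit_predict(Xs)
    return {"assignments": labels, "wcss": float(km.inertia_),
            "centers": km.cluster_centers_}
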