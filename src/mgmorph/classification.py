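"""Morphotype classification: gain-ratio decision tree, focus gating,
evaluation and cross-validation.

The classifier is an open reimplementation of the C4.5/C5.0 family:
binary numeric splits chosen by information gain ratio (among candidate
splits whose gain is at least the mean candidate gain), with
pessimistic-error pruning at a configurable confidence (default 0.25,
using the Clopper-Pearson upper binomial bound on the leaf error rate).
Predictions are deterministic; ties break in the fixed class order
R < H < B < A < RD < HR.

Six morphotypes are recognised: ramified (R, green), hypertrophic
(H, yellow), bushy (B, orange), ameboid (A, red), rod-shaped (RD, cyan)
and hypertrophic rod-shaped (HR, blue). Cells failing the Brenner focus
gate are tagged UF (gray) and excluded from classification and
quantification but retained for display.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import beta

from mgmorph.evaluation import cohens_kappa
from mgmorph.imaging_io import CellRecord
from mgmorph.morphometrics import CLASSIFIER_FEATURES

MORPHOTYPES = ["R", "H", "B", "A", "RD", "HR"]
UNFOCUSED = "UF"
MORPHOTYPE_COLORS = {
    "R": (0, 200, 0),       # green
    "H": (255, 215, 0),     # yellow
    "B": (255, 140, 0),     # orange
    "A": (220, 0, 0),       # red
    "RD": (0, 200, 200),    # cyan
    "HR": (0, 0, 230),      # blue
    UNFOCUSED: (128, 128, 128),  # gray
}
_CLASS_RANK = {c: i for i, c in enumerate(MORPHOTYPES)}


def _registry_hash(features: list[str]) -> str:
    return hashlib.sha256("|".join(features).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# gain-ratio decision tree


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _pessimistic_errors(n: int, e: int, cf: float) -> float:
    """C4.5-style predicted error count: n times the upper ``1-cf``
    confidence bound (Clopper-Pearson) of the leaf error rate."""
    if n == 0:
        return 0.0
    if e >= n:
        return float(n)
    ub = float(beta.ppf(1.0 - cf, e + 1, n - e))
    return n * ub


@dataclass
class TreeConfig:
    min_leaf: int = 2
    cf: float = 0.25            # pruning confidence
    max_depth: int | None = None
    criterion: str = "gain_ratio"
    seed: int = 0


class GainRatioTree:
    """C4.5-style decision tree over a fixed feature registry.

    fit() consumes an (n, p) float matrix and string class labels;
    predict() returns labels. The fitted tree serialises to JSON together
    with its configuration and a hash of the feature registry.
    """

    def __init__(self, feature_names: list[str] | None = None,
                 config: TreeConfig | None = None):
        self.feature_names = list(feature_names or CLASSIFIER_FEATURES)
        self.config = config or TreeConfig()
        self.root: dict | None = None
        self.classes_: list[str] = []

    # -- training -----------------------------------------------------

    def fit(self, X: np.ndarray, y) -> "GainRatioTree":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"X must be (n, {len(self.feature_names)}), got {X.shape}")
        keep = ~np.isnan(X).any(axis=1)
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} rows with undefined features")
            X, y = X[keep], y[keep]
        if len(X) == 0:
            raise ValueError("no training rows left")
        self.classes_ = sorted(set(y),
                               key=lambda c: (_CLASS_RANK.get(c, 999), str(c)))
        codes = np.array([self.classes_.index(c) for c in y])
        self.root = self._grow(X, codes, depth=0)
        self._prune(self.root)
        return self

    def _class_counts(self, codes: np.ndarray) -> np.ndarray:
        return np.bincount(codes, minlength=len(self.classes_))

    def _leaf(self, codes: np.ndarray) -> dict:
        counts = self._class_counts(codes)
        best = int(np.argmax(counts))  # argmax takes the first = class-order tie-break
        return {"leaf": True, "class": best, "dist": counts.tolist(),
                "n": int(counts.sum()), "errors": int(counts.sum() - counts[best])}

    def _grow(self, X: np.ndarray, codes: np.ndarray, depth: int) -> dict:
        cfg = self.config
        n = len(codes)
        counts = self._class_counts(codes)
        if (n < 2 * cfg.min_leaf or (counts > 0).sum() <= 1
                or (cfg.max_depth is not None and depth >= cfg.max_depth)):
            return self._leaf(codes)
        base = _entropy(counts)
        k = len(self.classes_)

        def _prefix_entropy(cum: np.ndarray, totals: np.ndarray) -> np.ndarray:
            with np.errstate(divide="ignore", invalid="ignore"):
                p = cum / totals[:, None]
                h = np.where(p > 0, -p * np.log2(p), 0.0)
            return h.sum(axis=1)

        gains, ratios, feats, thrs = [], [], [], []
        for j in range(X.shape[1]):
            xs = X[:, j]
            order = np.argsort(xs, kind="stable")
            xs_s, cs = xs[order], codes[order]
            onehot = np.zeros((n, k))
            onehot[np.arange(n), cs] = 1.0
            left_counts = np.cumsum(onehot, axis=0)
            nl = np.arange(1, n + 1, dtype=float)
            valid = (np.diff(xs_s) > 0)
            valid &= (nl[:-1] >= cfg.min_leaf) & (n - nl[:-1] >= cfg.min_leaf)
            idx = np.nonzero(valid)[0]
            if idx.size == 0:
                continue
            nl_v = nl[idx]
            nr_v = n - nl_v
            h_l = _prefix_entropy(left_counts[idx], nl_v)
            h_r = _prefix_entropy(counts[None, :] - left_counts[idx], nr_v)
            gain = base - (nl_v / n) * h_l - (nr_v / n) * h_r
            pl = nl_v / n
            split_info = -(pl * np.log2(pl) + (1 - pl) * np.log2(1 - pl))
            ok = (gain > 1e-12) & (split_info > 1e-12)
            gains.append(gain[ok])
            ratios.append(gain[ok] / split_info[ok])
            feats.append(np.full(int(ok.sum()), j))
            thrs.append(0.5 * (xs_s[idx[ok]] + xs_s[idx[ok] + 1]))
        if not gains or all(g.size == 0 for g in gains):
            return self._leaf(codes)
        gains = np.concatenate(gains)
        ratios = np.concatenate(ratios)
        feats = np.concatenate(feats)
        thrs = np.concatenate(thrs)
        mean_gain = gains.mean()
        elig = gains >= mean_gain - 1e-12
        # best gain ratio; ties: lower feature index, then lower threshold
        order = np.lexsort((thrs[elig], feats[elig], -ratios[elig]))[0]
        j = int(feats[elig][order])
        thr = float(thrs[elig][order])
        left = X[:, j] <= thr
        node = {"leaf": False, "feature": int(j), "threshold": float(thr),
                "n": n, "dist": counts.tolist(),
                "left": self._grow(X[left], codes[left], depth + 1),
                "right": self._grow(X[~left], codes[~left], depth + 1)}
        return node

    def _prune(self, node: dict) -> float:
        """Bottom-up pessimistic pruning; returns predicted subtree errors."""
        cf = self.config.cf
        counts = np.asarray(node["dist"])
        n = int(counts.sum())
        leaf_pred = _pessimistic_errors(n, n - int(counts.max()), cf)
        if node["leaf"]:
            return leaf_pred
        subtree_pred = self._prune(node["left"]) + self._prune(node["right"])
        if leaf_pred <= subtree_pred + 1e-9:
            best = int(np.argmax(counts))
            node.clear()
            node.update({"leaf": True, "class": best, "dist": counts.tolist(),
                         "n": n, "errors": n - int(counts[best])})
            return leaf_pred
        return subtree_pred

    # -- inference ----------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.root is None:
            raise ValueError("tree is not fitted")
        X = np.asarray(X, dtype=np.float64)
        out = []
        for row in X:
            node = self.root
            while not node["leaf"]:
                node = node["left"] if row[node["feature"]] <= node["threshold"] \
                    else node["right"]
            out.append(self.classes_[node["class"]])
        return np.asarray(out, dtype=object)

    @property
    def depth(self) -> int:
        def d(node):
            return 0 if node["leaf"] else 1 + max(d(node["left"]), d(node["right"]))
        return d(self.root) if self.root else 0

    def n_leaves(self) -> int:
        def c(node):
            return 1 if node["leaf"] else c(node["left"]) + c(node["right"])
        return c(self.root) if self.root else 0

    # -- serialisation ------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {"feature_names": self.feature_names,
                   "registry_hash": _registry_hash(self.feature_names),
                   "config": vars(self.config),
                   "classes": self.classes_,
                   "tree": self.root}
        text = json.dumps(payload, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GainRatioTree":
        p = Path(str(source))
        payload = json.loads(p.read_text() if p.exists() else str(source))
        tree = cls(payload["feature_names"], TreeConfig(**payload["config"]))
        tree.classes_ = payload["classes"]
        tree.root = payload["tree"]
        return tree


def train_tree(features: np.ndarray, labels, config: TreeConfig | None = None,
               feature_names: list[str] | None = None) -> GainRatioTree:
    """Train the morphotype decision tree on an (n, 25) feature matrix."""
    return GainRatioTree(feature_names, config).fit(features, labels)


def make_baseline(kind: str, seed: int = 0):
    """Comparison learners behind the same fit/predict interface."""
    if kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if kind == "lda":
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        return LinearDiscriminantAnalysis()
    raise ValueError(f"unknown baseline: {kind}")


# ---------------------------------------------------------------------------
# focus gate


def apply_focus_gate(cells: list[CellRecord], fm_threshold: float = 600.0,
                     ) -> tuple[list[CellRecord], list[CellRecord]]:
    """Split cells into (kept, unfocused) at FM strictly above threshold.

    Unfocused cells are tagged UF in place; they stay out of
    classification and quantification but remain renderable.
    """
    kept, unfocused = [], []
    for c in cells:
        fm = c.focus if c.focus is not None else c.features.get("FM", np.nan)
        if fm is not None and not np.isnan(fm) and fm > fm_threshold:
            c.unfocused = False
            kept.append(c)
        else:
            c.unfocused = True
            c.morphotype = None
            unfocused.append(c)
    return kept, unfocused


def predict_cells(model: GainRatioTree, cells: list[CellRecord]) -> list[CellRecord]:
    """Assign a morphotype to every (focus-gated) cell in place."""
    if not cells:
        return cells
    rows = []
    for c in cells:
        row = []
        for name in model.feature_names:
            if name not in c.features:
                raise KeyError(f"cell {c.id}: feature '{name}' missing from registry values")
            row.append(c.features[name])
        rows.append(row)
    preds = model.predict(np.asarray(rows, dtype=np.float64))
    for c, p in zip(cells, preds):
        c.morphotype = str(p)
    return cells


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class EvalReport:
    """Six-way classification report with kappa and weighted averages."""

    classes: list[str]
    confusion: np.ndarray               # rows = truth, cols = prediction
    per_class: dict = field(default_factory=dict)
    weighted: dict = field(default_factory=dict)
    kappa: float = np.nan
    accuracy: float = np.nan
    n_excluded_unfocused: int = 0

    def to_dict(self) -> dict:
        return {"classes": self.classes,
                "confusion": self.confusion.tolist(),
                "per_class": self.per_class,
                "weighted": self.weighted,
                "kappa": self.kappa,
                "accuracy": self.accuracy,
                "n_excluded_unfocused": self.n_excluded_unfocused}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_frame(self):
        import pandas as pd

        rows = [dict(cls=c, **self.per_class[c]) for c in self.classes]
        rows.append(dict(cls="weighted_avg", **self.weighted))
        return pd.DataFrame(rows)


def evaluate_classifier(pred, truth, classes: list[str] | None = None,
                        n_excluded_unfocused: int = 0) -> EvalReport:
    """Confusion matrix, per-class and weighted metrics, Cohen's kappa.

    Per-class accuracy is one-vs-rest accuracy; weighted averages are
    weighted by truth-class support (so weighted recall equals overall
    accuracy).
    """
    pred = np.asarray(pred, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(pred) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    if len(pred) == 0:
        raise ValueError("empty label vectors")
    if classes is None:
        present = set(truth) | set(pred)
        classes = [c for c in MORPHOTYPES if c in present]
        classes += sorted(present - set(classes))
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, pred):
        confusion[index[t], index[p]] += 1
    n = confusion.sum()
    per_class = {}
    for i, c in enumerate(classes):
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        tn = n - tp - fp - fn
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[c] = {"precision": float(prec), "recall": float(rec),
                        "f1": float(f1), "accuracy": float((tp + tn) / n),
                        "support": int(tp + fn)}
    support = np.array([per_class[c]["support"] for c in classes], dtype=float)
    wsum = support.sum()
    weighted = {m: float(sum(per_class[c][m] * per_class[c]["support"]
                             for c in classes) / wsum)
                for m in ("precision", "recall", "f1", "accuracy")}
    weighted["support"] = int(wsum)
    report = EvalReport(classes, confusion, per_class, weighted,
                        kappa=cohens_kappa(confusion),
                        accuracy=float(np.trace(confusion) / n),
                        n_excluded_unfocused=n_excluded_unfocused)
    return report


# ---------------------------------------------------------------------------
# cross-validation


def stratified_folds(labels, k: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Classes with at least k members are spread round-robin over the k
    folds after a seeded shuffle; a class with fewer than k members is
    kept whole in a single (seeded) fold, with a warning.
    """
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    folds = np.full(len(labels), -1, dtype=int)
    for c in sorted(set(labels), key=str):
        idx = np.nonzero(labels == c)[0]
        rng.shuffle(idx)
        if len(idx) < k:
            fold = int(rng.integers(k))
            warnings.warn(f"class {c!r} has {len(idx)} < {k} members; "
                          f"kept whole in fold {fold}")
            folds[idx] = fold
        else:
            folds[idx] = np.arange(len(idx)) % k
    return folds


def cross_validate(features: np.ndarray, labels, k: int = 5, seed: int = 0,
                   config: TreeConfig | None = None,
                   feature_names: list[str] | None = None) -> list[EvalReport]:
    """Stratified k-fold cross-validation of the gain-ratio tree."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=object)
    if len(X) < k:
        raise ValueError(f"need at least k={k} rows, got {len(X)}")
    folds = stratified_folds(y, k, seed)
    reports = []
    for f in range(k):
        test = folds == f
        model = GainRatioTree(feature_names, config).fit(X[~test], y[~test])
        pred = model.predict(X[test])
        reports.append(evaluate_classifier(pred, y[test]))
    return reports
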