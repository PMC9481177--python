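"""Group statistics and interpretable classification of subject features.

Two layers sit on top of the cohort feature table:

* rank-based group comparisons (Mann-Whitney rank-sum by default, optional
  signed-rank for paired designs) with a Bonferroni-corrected threshold;
* leave-one-out cross-validated classification with per-fold feature
  selection and two interpretable learners — a RIPPER-style sequential rule
  inducer and a reduced-error-pruned decision tree — reported with the full
  confusion-matrix metric suite (TP/FP rates, precision, recall, F-measure,
  MCC, ROC and PRC areas) per class and class-size weighted.

Feature selection is repeated inside every fold on the training split only,
so the held-out subject never influences which features the learner sees;
the per-feature selection frequency (%f, percent of folds) doubles as a
relevance score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc, precision_recall_curve, roc_auc_score
from sklearn.tree import DecisionTreeClassifier

LABELS_VOCAB = ("HC", "MCS", "UWS", "DOC")


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected per-test significance threshold ``alpha / m``."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def group_compare(
    table: pd.DataFrame,
    labels,
    groups: tuple,
    features=None,
    method: str = "ranksum",
) -> pd.Series:
    """Two-sided rank-test p-value per feature between two groups.

    ``method='ranksum'`` is the Mann-Whitney U test for independent groups
    (exact for small samples without ties, normal approximation with tie
    correction otherwise).  ``method='signedrank'`` applies the paired
    Wilcoxon signed-rank test and requires equal group sizes with a
    meaningful pairing by row order.
    """
    labels = np.asarray(labels)
    a_name, b_name = groups
    mask_a = labels == a_name
    mask_b = labels == b_name
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least two subjects")
    if features is None:
        features = [c for c in table.columns if np.issubdtype(table[c].dtype, np.number)]
    pvals = {}
    for feat in features:
        x = table.loc[mask_a, feat].to_numpy(dtype=float)
        y = table.loc[mask_b, feat].to_numpy(dtype=float)
        if method == "ranksum":
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
        elif method == "signedrank":
            if x.size != y.size:
                raise ValueError("signed-rank test requires equal group sizes")
            if np.allclose(x, y):
                pvals[feat] = 1.0
                continue
            res = stats.wilcoxon(x, y, alternative="two-sided")
        else:
            raise ValueError(f"unknown method {method!r}")
        pvals[feat] = float(res.pvalue)
    return pd.Series(pvals, name=f"p_{a_name}_vs_{b_name}")


# ---------------------------------------------------------------------------
# feature selection


def select_features(
    X: np.ndarray, y: np.ndarray, method: str = "correlation", k: int = 5, seed: int = 0
) -> np.ndarray:
    """Indices of the ``k`` top-ranked features on the training split.

    ``correlation`` ranks by absolute point-biserial correlation with the
    binary label; ``infogain`` ranks by estimated mutual information.
    """
    X = np.asarray(X, dtype=float)
    y01 = (np.asarray(y) == np.asarray(y)[0]).astype(float)
    k = min(k, X.shape[1])
    if method == "correlation":
        xc = X - X.mean(axis=0)
        yc = y01 - y01.mean()
        denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            score = np.abs(xc.T @ yc) / denom
        score = np.nan_to_num(score)
    elif method == "infogain":
        from sklearn.feature_selection import mutual_info_classif

        score = mutual_info_classif(X, y, random_state=seed)
    else:
        raise ValueError(f"unknown selector {method!r}")
    order = np.argsort(-score, kind="stable")
    return np.sort(order[:k])


# ---------------------------------------------------------------------------
# learners


@dataclass
class _Rule:
    conditions: list  # (feature index, '<=' or '>=', threshold)
    target: object
    p: int = 0  # training positives covered (Laplace-smoothed score basis)
    n: int = 0

    def covers(self, X: np.ndarray) -> np.ndarray:
        mask = np.ones(X.shape[0], dtype=bool)
        for j, op, thr in self.conditions:
            mask &= (X[:, j] <= thr) if op == "<=" else (X[:, j] >= thr)
        return mask


class RuleLearner:
    """Sequential-covering rule inducer with grow/prune splits (RIPPER style).

    Rules for the minority class are grown greedily by FOIL information
    gain on two thirds of the training data and pruned on the remaining
    third using the ``(p - n) / (p + n)`` rule-value metric; induction stops
    once a pruned rule is no better than chance on the prune split.  The
    default rule predicts the majority class.
    """

    def __init__(self, seed: int = 0, max_rules: int = 8, max_conditions: int = 4):
        self.seed = seed
        self.max_rules = max_rules
        self.max_conditions = max_conditions

    # -- internal helpers --------------------------------------------------
    @staticmethod
    def _foil_gain(p0, n0, p1, n1):
        if p1 == 0:
            return -np.inf
        eps = 1e-12
        return p1 * (
            np.log2(p1 / (p1 + n1 + eps) + eps) - np.log2(p0 / (p0 + n0 + eps) + eps)
        )

    def _candidate_thresholds(self, col: np.ndarray) -> np.ndarray:
        vals = np.unique(col)
        if vals.size > 24:
            vals = np.quantile(col, np.linspace(0.02, 0.98, 24))
            vals = np.unique(vals)
        if vals.size < 2:
            return np.zeros(0)
        return (vals[:-1] + vals[1:]) / 2.0

    def _grow_rule(self, X, pos):
        covered = np.ones(X.shape[0], dtype=bool)
        conds = []
        while len(conds) < self.max_conditions:
            p0 = int(np.sum(pos & covered))
            n0 = int(np.sum(~pos & covered))
            if n0 == 0 or p0 == 0:
                break
            best = None
            for j in range(X.shape[1]):
                for thr in self._candidate_thresholds(X[covered, j]):
                    for op in ("<=", ">="):
                        sel = (X[:, j] <= thr) if op == "<=" else (X[:, j] >= thr)
                        sel &= covered
                        p1 = int(np.sum(pos & sel))
                        n1 = int(np.sum(~pos & sel))
                        gain = self._foil_gain(p0, n0, p1, n1)
                        if gain > 0 and (best is None or gain > best[0]):
                            best = (gain, j, op, thr, sel)
            if best is None:
                break
            _, j, op, thr, sel = best
            conds.append((j, op, thr))
            covered = sel
        return conds

    def _prune_rule(self, conds, X, pos):
        def value(cs):
            if not cs:
                return -np.inf
            rule = _Rule(cs, None)
            sel = rule.covers(X)
            p = int(np.sum(pos & sel))
            n = int(np.sum(~pos & sel))
            if p + n == 0:
                return -np.inf
            return (p - n) / (p + n)

        best = list(conds)
        best_val = value(best)
        trial = list(conds)
        while len(trial) > 1:
            trial = trial[:-1]
            v = value(trial)
            if v >= best_val:
                best, best_val = list(trial), v
        return best, best_val

    # -- sklearn-ish surface ----------------------------------------------
    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("RuleLearner is a binary classifier")
        counts = [np.sum(y == c) for c in self.classes_]
        self.pos_class_ = self.classes_[int(np.argmin(counts))]
        self.neg_class_ = self.classes_[int(np.argmax(counts))]
        if self.pos_class_ == self.neg_class_:  # balanced: fixed order
            self.pos_class_, self.neg_class_ = self.classes_[0], self.classes_[1]
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(X.shape[0])
        n_grow = max(2, int(round(X.shape[0] * 2 / 3)))
        grow_idx, prune_idx = order[:n_grow], order[n_grow:]
        if prune_idx.size < 2:
            grow_idx = prune_idx = order
        self.rules_: list[_Rule] = []
        active = np.ones(X.shape[0], dtype=bool)
        pos_all = y == self.pos_class_
        for _ in range(self.max_rules):
            g = np.intersect1d(grow_idx, np.flatnonzero(active))
            pr = np.intersect1d(prune_idx, np.flatnonzero(active))
            if np.sum(pos_all[g]) == 0:
                break
            conds = self._grow_rule(X[g], pos_all[g])
            if not conds:
                break
            conds, val = self._prune_rule(conds, X[pr], pos_all[pr]) if pr.size else (conds, 1.0)
            if val < 0:  # worse than chance on the prune split
                break
            rule = _Rule(conds, self.pos_class_)
            sel = rule.covers(X) & active
            rule.p = int(np.sum(pos_all & sel))
            rule.n = int(np.sum(~pos_all & sel))
            if rule.p == 0:
                break
            self.rules_.append(rule)
            active &= ~rule.covers(X)
            if np.sum(pos_all & active) == 0:
                break
        # default-rule statistics on the uncovered remainder
        self.default_p_ = int(np.sum(pos_all & active))
        self.default_n_ = int(np.sum(~pos_all & active))
        return self

    def _positive_proba(self, X):
        X = np.asarray(X, dtype=float)
        proba = np.empty(X.shape[0])
        assigned = np.zeros(X.shape[0], dtype=bool)
        for rule in self.rules_:
            sel = rule.covers(X) & ~assigned
            proba[sel] = (rule.p + 1) / (rule.p + rule.n + 2)
            assigned |= sel
        proba[~assigned] = (self.default_p_ + 1) / (self.default_p_ + self.default_n_ + 2)
        return proba

    def predict_proba(self, X):
        p = self._positive_proba(X)
        out = np.zeros((p.shape[0], 2))
        for i, c in enumerate(self.classes_):
            out[:, i] = p if c == self.pos_class_ else 1 - p
        return out

    def predict(self, X):
        p = self._positive_proba(X)
        return np.where(p >= 0.5, self.pos_class_, self.neg_class_)


class REPTree:
    """Decision tree with reduced-error pruning on a held-out third.

    A full tree is grown on two thirds of the training data; the
    cost-complexity pruning path is evaluated on the remaining third and
    the smallest subtree with maximal held-out accuracy is kept.
    """

    def __init__(self, seed: int = 0, min_leaf: int = 2):
        self.seed = seed
        self.min_leaf = min_leaf

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.seed)
        order = rng.permutation(X.shape[0])
        n_grow = max(2, int(round(X.shape[0] * 2 / 3)))
        grow_idx, prune_idx = order[:n_grow], order[n_grow:]
        if prune_idx.size < 2 or np.unique(y[grow_idx]).size < 2:
            grow_idx = prune_idx = order
        base = DecisionTreeClassifier(
            random_state=self.seed, min_samples_leaf=self.min_leaf
        )
        base.fit(X[grow_idx], y[grow_idx])
        path = base.cost_complexity_pruning_path(X[grow_idx], y[grow_idx])
        best_alpha, best_acc = 0.0, -1.0
        for ccp in path.ccp_alphas:
            t = DecisionTreeClassifier(
                random_state=self.seed, min_samples_leaf=self.min_leaf, ccp_alpha=ccp
            )
            t.fit(X[grow_idx], y[grow_idx])
            acc = float(np.mean(t.predict(X[prune_idx]) == y[prune_idx]))
            if acc >= best_acc:  # ties resolve toward the smaller subtree
                best_alpha, best_acc = ccp, acc
        self.tree_ = DecisionTreeClassifier(
            random_state=self.seed, min_samples_leaf=self.min_leaf, ccp_alpha=best_alpha
        )
        self.tree_.fit(X, y)
        self.classes_ = self.tree_.classes_
        return self

    def predict(self, X):
        return self.tree_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return self.tree_.predict_proba(np.asarray(X, dtype=float))


_LEARNERS = {"rule": RuleLearner, "tree": REPTree}


# ---------------------------------------------------------------------------
# metrics


def confusion_from_rates(tp_rates, class_sizes) -> np.ndarray:
    """Integer binary confusion matrix implied by per-class TP rates and sizes."""
    cm = np.zeros((2, 2), dtype=int)
    for c, (rate, size) in enumerate(zip(tp_rates, class_sizes)):
        tp = int(round(rate * size))
        cm[c, c] = tp
        cm[c, 1 - c] = size - tp
    return cm


def metrics_from_confusion(
    cm: np.ndarray,
    class_names=None,
    scores: np.ndarray | None = None,
    y_true: np.ndarray | None = None,
) -> dict:
    """Per-class and weighted metrics from an integer confusion matrix.

    Rows are true classes, columns predictions.  ROC and PRC areas need the
    per-subject class scores (columns aligned with ``class_names``); without
    them those entries are NaN.  Cells with a zero denominator yield a 0
    metric with a ``zero_division`` flag, following common tool convention.
    """
    cm = np.asarray(cm, dtype=int)
    k = cm.shape[0]
    if class_names is None:
        class_names = [str(i) for i in range(k)]
    total = int(cm.sum())
    per_class: dict = {}
    flags = []
    for c in range(k):
        tp = int(cm[c, c])
        fn = int(cm[c].sum() - tp)
        fp = int(cm[:, c].sum() - tp)
        tn = total - tp - fn - fp

        def _safe(num, den, name):
            if den == 0:
                flags.append((class_names[c], name))
                return 0.0
            return num / den

        tpr = _safe(tp, tp + fn, "tp_rate")
        fpr = _safe(fp, fp + tn, "fp_rate")
        prec = _safe(tp, tp + fp, "precision")
        fmeas = _safe(2 * prec * tpr, prec + tpr, "f_measure")
        mcc_den = np.sqrt(
            float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
        )
        mcc = (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else 0.0
        row = {
            "tp_rate": tpr,
            "fp_rate": fpr,
            "precision": prec,
            "recall": tpr,
            "f_measure": fmeas,
            "mcc": mcc,
            "roc_area": np.nan,
            "prc_area": np.nan,
            "support": tp + fn,
        }
        if scores is not None and y_true is not None:
            truth = (np.asarray(y_true) == class_names[c]).astype(int)
            sc = np.asarray(scores, dtype=float)[:, c]
            if truth.min() == truth.max():
                flags.append((class_names[c], "roc_area"))
            else:
                row["roc_area"] = float(roc_auc_score(truth, sc))
                precision, recall, _ = precision_recall_curve(truth, sc)
                row["prc_area"] = float(auc(recall, precision))
        per_class[class_names[c]] = row
    weights = np.array([per_class[name]["support"] for name in class_names], float)
    weights = weights / weights.sum()
    weighted = {
        key: float(
            np.sum(weights * np.array([per_class[nm][key] for nm in class_names]))
        )
        for key in (
            "tp_rate",
            "fp_rate",
            "precision",
            "recall",
            "f_measure",
            "mcc",
            "roc_area",
            "prc_area",
        )
    }
    return {
        "per_class": per_class,
        "weighted": weighted,
        "accuracy": float(np.trace(cm) / total) if total else 0.0,
        "zero_division_flags": flags,
    }


# ---------------------------------------------------------------------------
# leave-one-out evaluation


@dataclass
class ClassifierReport:
    """Outcome of a leave-one-out evaluation."""

    class_names: list
    confusion: np.ndarray
    metrics: dict
    feature_frequency: pd.Series  # %f, percent of folds selecting each feature
    predictions: pd.DataFrame
    learner: str = ""

    def to_dict(self) -> dict:
        return {
            "learner": self.learner,
            "class_names": list(self.class_names),
            "confusion": self.confusion.tolist(),
            "metrics": _jsonable(self.metrics),
            "feature_frequency": {k: float(v) for k, v in self.feature_frequency.items()},
        }

    def text_table(self) -> str:
        """Human-readable metric table, one row per class plus weighted average."""
        cols = ("tp_rate", "fp_rate", "precision", "recall", "f_measure", "mcc", "roc_area", "prc_area")
        header = f"{'Class':<14}" + "".join(f"{c:>11}" for c in cols)
        lines = [header]
        rows = [(nm, self.metrics["per_class"][nm]) for nm in self.class_names]
        rows.append(("Weighted Avg.", self.metrics["weighted"]))
        for nm, row in rows:
            lines.append(
                f"{nm:<14}" + "".join(f"{row[c]:>11.3f}" for c in cols)
            )
        return "\n".join(lines)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def loo_classify(
    table: pd.DataFrame,
    label_col: str = "label",
    features=None,
    learner: str = "rule",
    selector: str = "correlation",
    n_features: int = 5,
    seed: int = 0,
) -> ClassifierReport:
    """Leave-one-out cross-validation with in-fold feature selection.

    One fold per subject: features are ranked on the training split alone,
    the learner is fit on the selected columns, and the held-out subject's
    prediction and class scores are recorded.  The report pools the folds
    into a confusion matrix, the metric suite, and %f selection frequencies.
    """
    if learner not in _LEARNERS:
        raise ValueError(f"unknown learner {learner!r}; choose from {sorted(_LEARNERS)}")
    if features is None:
        features = [
            c
            for c in table.columns
            if c != label_col and np.issubdtype(table[c].dtype, np.number)
        ]
    X = table[features].to_numpy(dtype=float)
    y = table[label_col].to_numpy()
    class_names = sorted(np.unique(y).tolist())
    if len(class_names) < 2:
        raise ValueError("need at least two classes")
    n = X.shape[0]
    sel_counts = np.zeros(len(features))
    preds = []
    scores = np.zeros((n, len(class_names)))
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        sel = select_features(
            X[train], y[train], method=selector, k=n_features, seed=seed
        )
        sel_counts[sel] += 1
        model = _LEARNERS[learner](seed=seed)
        model.fit(X[train][:, sel], y[train])
        x_test = X[i : i + 1, sel]
        pred = model.predict(x_test)[0]
        proba = model.predict_proba(x_test)[0]
        for cls, p in zip(model.classes_, proba):
            scores[i, class_names.index(cls)] = p
        preds.append((i, y[i], pred))
    cm = np.zeros((len(class_names), len(class_names)), dtype=int)
    for _, truth, pred in preds:
        cm[class_names.index(truth), class_names.index(pred)] += 1
    metrics = metrics_from_confusion(cm, class_names, scores=scores, y_true=y)
    freq = pd.Series(100.0 * sel_counts / n, index=features, name="%f")
    pred_frame = pd.DataFrame(preds, columns=["index", "true", "predicted"])
    return ClassifierReport(
        class_names=class_names,
        confusion=cm,
        metrics=metrics,
        feature_frequency=freq,
        predictions=pred_frame,
        learner=learner,
    )
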