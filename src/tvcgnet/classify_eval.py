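"""Class-weighted SVM contract and AAMI evaluation metrics.

The classifier is an RBF-kernel C-SVC (one-against-one multi-class) with
C = 1, gamma = 1/number_of_features, and per-class penalty weights
(w1, w2, w3) for the N, S and V superclasses to compensate the heavy class
imbalance of inter-patient ECG data.  The quadratic-programming solver is
delegated to scikit-learn (libsvm).

Metrics follow the AAMI recommendations: per-class sensitivity Se (recall),
positive predictivity +P (precision) and false positive rate FPR, plus
overall accuracy.  For 5-class input the de Chazal convention is applied:
fusion (F) beats predicted as V are excluded from V's false positives and
+P denominator.  The optimization fitness is the mean per-class F-score,
F = 2 Se (+P) / (Se + (+P)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

THREE_CLASSES = ("N", "S", "V")

#: Published benchmark confusion matrix for the common-filter configuration
#: of the TVCG method on the MIT-BIH inter-patient test set (rows = true
#: N, S, V; columns = predicted n, s, v).  Serves as direct input for
#: metric-arithmetic checks.
BENCHMARK_CONFUSION_COMMON = np.array([
    [41043, 792, 1834],
    [657, 1111, 25],
    [200, 195, 2724],
])


@dataclass(frozen=True)
class SVMConfig:
    """C-SVC configuration: hard-ish margin C = 1, RBF kernel with
    gamma = 1/number_of_features, per-class weights (N, S, V)."""

    C: float = 1.0
    class_weights: tuple[float, float, float] = (6.0, 100.0, 15.0)
    cache_size_mb: float = 200.0
    tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.C <= 0 or any(w <= 0 for w in self.class_weights):
            raise ValueError("C and class weights must be positive")


def train_classifier(X: np.ndarray, y: np.ndarray, cfg: SVMConfig) -> SVC:
    """Fit the weighted RBF C-SVC.  Deterministic for fixed inputs."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if np.isnan(X).any():
        raise ValueError("X contains NaN")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain at least 2 classes")
    weights = dict(zip(THREE_CLASSES, cfg.class_weights))
    clf = SVC(
        kernel="rbf",
        C=cfg.C,
        gamma=1.0 / X.shape[1],
        class_weight={c: w for c, w in weights.items() if c in set(y)},
        cache_size=cfg.cache_size_mb,
        tol=cfg.tol,
        decision_function_shape="ovo",
    )
    clf.fit(X, y)
    return clf


def predict(model: SVC, X: np.ndarray) -> np.ndarray:
    """Predict one superclass label per row."""
    X = np.asarray(X, float)
    if X.size == 0:
        return np.array([], dtype=object)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"X has {X.shape[1]} features, model expects {model.n_features_in_}"
        )
    return model.predict(X)


@dataclass
class ConfusionMatrix:
    """counts[true][predicted] over an ordered class tuple."""

    counts: np.ndarray
    classes: tuple[str, ...] = THREE_CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"matrix shape {self.counts.shape} does not match "
                f"{k} classes"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(true: np.ndarray, pred: np.ndarray,
              classes: tuple[str, ...] = THREE_CLASSES) -> ConfusionMatrix:
    """Count matrix counts[t][p] = #{i : true_i = t, pred_i = p}."""
    true = np.asarray(true)
    pred = np.asarray(pred)
    if len(true) != len(pred):
        raise ValueError("true and pred must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true, pred):
        counts[index[str(t)], index[str(p)]] += 1
    return ConfusionMatrix(counts, classes)


@dataclass
class AAMIMetrics:
    """Per-class Se/+P/FPR (proportions in [0, 1]) and overall accuracy."""

    se: dict[str, float]
    positive_predictivity: dict[str, float]
    fpr: dict[str, float]
    accuracy: float
    zero_denominator_flags: list[str] = field(default_factory=list)

    def rounded_percent(self, ndigits: int = 1) -> dict[str, float]:
        """Presentation form: percentages, half-up rounding."""
        def r(x: float) -> float:
            scale = 10 ** ndigits
            return float(np.floor(x * 100 * scale + 0.5) / scale)

        out = {"Acc": r(self.accuracy)}
        for c in self.se:
            out[f"Se_{c}"] = r(self.se[c])
            out[f"+P_{c}"] = r(self.positive_predictivity[c])
            out[f"FPR_{c}"] = r(self.fpr[c])
        return out


def aami_metrics(cm: ConfusionMatrix) -> AAMIMetrics:
    """AAMI per-class metrics from a 3-class (N, S, V) or 5-class
    (N, S, V, F, Q) confusion matrix.

    For 5-class input, F-class beats predicted as V are excluded from V's
    false positives and +P denominator; metrics are reported for N, S, V
    only.  Zero denominators yield 0 and are flagged.
    """
    counts = cm.counts.astype(float)
    classes = cm.classes
    total = counts.sum()
    flags: list[str] = []

    def safe(num: float, den: float, tag: str) -> float:
        if den == 0:
            flags.append(tag)
            return 0.0
        return num / den

    five_class = "F" in classes
    report = [c for c in classes if c in THREE_CLASSES]
    se, pp, fpr = {}, {}, {}
    for c in report:
        i = classes.index(c)
        tp = counts[i, i]
        row = counts[i].sum()
        col = counts[:, i].sum()
        fp = col - tp
        neg = total - row
        if five_class and c == "V":
            f_row = classes.index("F")
            excl = counts[f_row, i]  # fusion beats predicted as V
            col -= excl
            fp -= excl
            neg -= excl
        se[c] = safe(tp, row, f"Se_{c}")
        pp[c] = safe(tp, col, f"+P_{c}")
        fpr[c] = safe(fp, neg, f"FPR_{c}")
    acc = safe(np.trace(counts), total, "Acc")
    return AAMIMetrics(se, pp, fpr, acc, flags)


def f_score(se: float, pp: float) -> float:
    """Harmonic mean of sensitivity and positive predictivity; 0 at 0+0."""
    if not (0 <= se <= 1 and 0 <= pp <= 1):
        raise ValueError("se and pp must be proportions in [0, 1]")
    if se + pp == 0:
        return 0.0
    return 2.0 * se * pp / (se + pp)


@dataclass(frozen=True)
class FitnessValue:
    per_class: dict[str, float]
    mean: float


def fitness(cm: ConfusionMatrix,
            weights: dict[str, float] | None = None) -> FitnessValue:
    """Mean (or weighted mean) per-class F-score over N, S, V."""
    m = aami_metrics(cm)
    per_class = {c: f_score(m.se[c], m.positive_predictivity[c]) for c in m.se}
    if weights is None:
        mean = float(np.mean(list(per_class.values())))
    else:
        num = sum(weights[c] * per_class[c] for c in per_class)
        den = sum(weights[c] for c in per_class)
        mean = num / den if den else 0.0
    return FitnessValue(per_class, mean)
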