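"""Classifier ensembles for induction-vs-emergence discrimination.

For each individual, 250 classifiers (linear discriminant analysis, and
optionally support vector machines) are trained on balanced 260-per-class
training sets resampled from the 10-30 min windows of each 0.6% step: the
emergence class from the final step of the emergence recording, the
induction class split equally between the induction recording and the
induction arm of the emergence recording (130 + 130), so that recording-day
idiosyncrasies cannot masquerade as path dependence.  Matched null
ensembles are trained on label-shuffled copies of the same sets.  Accuracy
is the balanced accuracy (1/2)(I_C/I_T + E_C/E_T), whose chance level is
0.5 regardless of test-set imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.svm import SVC

__all__ = [
    "LABEL_INDUCTION",
    "LABEL_EMERGENCE",
    "TRAIN_WINDOW_S",
    "TrainingSet",
    "TrainedClassifier",
    "ClassifierEnsemble",
    "PredictionSummary",
    "assemble_training_set",
    "assemble_population_training_set",
    "shuffle_labels",
    "train_lda",
    "train_svm",
    "train_ensemble",
    "balanced_accuracy",
    "summarize_predictions",
]

LABEL_INDUCTION = 0
LABEL_EMERGENCE = 1
#: training windows come from minutes 10-30 of the relevant 0.6% step
TRAIN_WINDOW_S = (600.0, 1800.0)

_INDUCTION_SOURCES = ("induction", "emergence_induction_arm")


@dataclass
class TrainingSet:
    X: np.ndarray              # (n, k) PC scores
    y: np.ndarray              # int labels, 0 = induction, 1 = emergence
    meta: pd.DataFrame         # source / time bookkeeping per row
    seed: int

    def __post_init__(self):
        if len(self.X) != len(self.y) or len(self.X) != len(self.meta):
            raise ValueError("rows, labels and meta must align")

    @property
    def class_counts(self):
        return (int((self.y == LABEL_INDUCTION).sum()),
                int((self.y == LABEL_EMERGENCE).sum()))


def _training_pools(meta: pd.DataFrame, train_window_s=TRAIN_WINDOW_S):
    lo, hi = train_window_s
    in_window = (meta["step_time_s"] >= lo) & (meta["step_time_s"] < hi)
    pools = {}
    for source in _INDUCTION_SOURCES + ("emergence",):
        pools[source] = np.flatnonzero((meta["source"] == source) & in_window)
    return pools


def assemble_training_set(
    scores: np.ndarray,
    meta: pd.DataFrame,
    n_per_class: int = 260,
    seed: int = 0,
    train_window_s=TRAIN_WINDOW_S,
) -> TrainingSet:
    """Balanced training set sampled without replacement from one individual.

    ``meta`` must carry ``source`` (induction / emergence /
    emergence_induction_arm) and ``step_time_s`` (seconds since the source's
    0.6% step onset) columns aligned with ``scores``.  If any pool is too
    small the per-class count is reduced symmetrically with a warning.
    """
    meta = meta.reset_index(drop=True)
    pools = _training_pools(meta, train_window_s)
    half = n_per_class // 2
    avail = min(
        len(pools["emergence"]) ,
        2 * min(len(pools[s]) for s in _INDUCTION_SOURCES),
    )
    n_eff = min(n_per_class, avail)
    if n_eff < n_per_class:
        warnings.warn(
            f"insufficient training windows: using {n_eff} per class "
            f"instead of {n_per_class}"
        )
    if n_eff < 2:
        raise ValueError("not enough training windows in minutes 10-30")
    half = n_eff // 2
    rng = np.random.default_rng(seed)
    idx_em = rng.choice(pools["emergence"], size=2 * half, replace=False)
    idx_ind = np.concatenate([
        rng.choice(pools[s], size=half, replace=False) for s in _INDUCTION_SOURCES
    ])
    idx = np.concatenate([idx_ind, idx_em])
    y = np.concatenate([
        np.full(idx_ind.size, LABEL_INDUCTION),
        np.full(idx_em.size, LABEL_EMERGENCE),
    ])
    return TrainingSet(X=scores[idx], y=y, meta=meta.iloc[idx].reset_index(drop=True),
                       seed=seed)


def assemble_population_training_set(
    cohort_features: dict,
    held_out_id,
    n_per_individual: int = 260,
    seed: int = 0,
    train_window_s=TRAIN_WINDOW_S,
) -> TrainingSet:
    """Leave-one-out population training set.

    ``cohort_features`` maps individual id -> (scores, meta) in a shared
    feature space.  Windows are drawn equally (``n_per_individual`` per
    class) from every individual except ``held_out_id``; with a six-mouse
    cohort this yields the canonical 5 x 260 = 1300 windows per class.
    """
    if held_out_id not in cohort_features:
        raise KeyError(f"held-out individual {held_out_id!r} not in cohort")
    others = [i for i in cohort_features if i != held_out_id]
    if not others:
        raise ValueError("population training needs at least 2 individuals")
    rng = np.random.default_rng(seed)
    parts = []
    for ind in others:
        scores, meta = cohort_features[ind]
        ts = assemble_training_set(
            scores, meta, n_per_class=n_per_individual,
            seed=int(rng.integers(0, 2 ** 31)), train_window_s=train_window_s,
        )
        ts.meta["individual"] = ind
        parts.append(ts)
    X = np.concatenate([p.X for p in parts])
    y = np.concatenate([p.y for p in parts])
    meta = pd.concat([p.meta for p in parts], ignore_index=True)
    return TrainingSet(X=X, y=y, meta=meta, seed=seed)


def shuffle_labels(ts: TrainingSet, seed: int) -> TrainingSet:
    """Uniformly permute labels over rows (features untouched); the label
    multiset — hence class balance — is preserved."""
    rng = np.random.default_rng(seed)
    return replace(ts, y=ts.y[rng.permutation(len(ts.y))])


@dataclass
class TrainedClassifier:
    """One fitted classifier; linear methods expose (weights, bias)."""

    method: str                     # "lda" | "svm-rbf" | "svm-linear"
    model: object
    weights: np.ndarray = None      # (k,) for linear decision rules
    bias: float = None
    seed: int = 0

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        if self.weights is not None:
            return X @ self.weights + self.bias
        return self.model.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_values(X) > 0, LABEL_EMERGENCE, LABEL_INDUCTION)


def train_lda(ts: TrainingSet) -> TrainedClassifier:
    """Classical (Fisher/Gaussian) LDA with Ledoit-Wolf shrinkage of the
    pooled within-class covariance, so near-singular synthetic cases stay
    well-posed.  The decision rule is sign(w . x + b)."""
    _require_two_classes(ts)
    model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    model.fit(ts.X, ts.y)
    w = model.coef_[0].copy()
    b = float(model.intercept_[0])
    if model.classes_[1] != LABEL_EMERGENCE:  # keep a fixed sign convention
        w, b = -w, -b
    return TrainedClassifier(method="lda", model=model, weights=w, bias=b,
                             seed=ts.seed)


def train_svm(ts: TrainingSet, kernel: str = "rbf", c: float = 1.0) -> TrainedClassifier:
    """Support-vector classifier; Gaussian RBF by default
    (gamma = 1/(k * Var(X)), C = 1), linear kernel by request."""
    _require_two_classes(ts)
    model = SVC(kernel=kernel, C=c, gamma="scale")
    model.fit(ts.X, ts.y)
    if kernel == "linear":
        w = model.coef_[0].copy()
        b = float(model.intercept_[0])
        if model.classes_[1] != LABEL_EMERGENCE:
            w, b = -w, -b
        return TrainedClassifier(method="svm-linear", model=model,
                                 weights=w, bias=b, seed=ts.seed)
    return TrainedClassifier(method=f"svm-{kernel}", model=model, seed=ts.seed)


def _require_two_classes(ts: TrainingSet):
    counts = ts.class_counts
    if min(counts) < 2:
        raise ValueError(f"need >= 2 rows per class, got {counts}")


@dataclass
class ClassifierEnsemble:
    """A bag of classifiers sharing method and sampling protocol."""

    members: list
    method: str
    base_seed: int
    null: bool = False              # True = trained on shuffled labels
    provenance: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.members)

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        """(n_members, n_windows) predicted labels; linear members are
        evaluated as a single matrix product."""
        linear = all(m.weights is not None for m in self.members)
        if linear and self.members:
            W = np.stack([m.weights for m in self.members])
            b = np.array([m.bias for m in self.members])
            return np.where(X @ W.T + b > 0, LABEL_EMERGENCE, LABEL_INDUCTION).T
        return np.stack([m.predict(X) for m in self.members])


def train_ensemble(
    scores: np.ndarray,
    meta: pd.DataFrame,
    n_members: int = 250,
    method: str = "lda",
    base_seed: int = 0,
    null: bool = False,
    n_per_class: int = 260,
    train_window_s=TRAIN_WINDOW_S,
    svm_kernel: str = "rbf",
) -> ClassifierEnsemble:
    """Train ``n_members`` classifiers on independently resampled training
    sets (member i uses seed base_seed + i); with ``null=True`` each
    member's labels are independently shuffled first, giving the
    permutation-null ensemble."""
    members = []
    for i in range(n_members):
        ts = assemble_training_set(scores, meta, n_per_class=n_per_class,
                                   seed=base_seed + i,
                                   train_window_s=train_window_s)
        if null:
            ts = shuffle_labels(ts, seed=base_seed + 100_000 + i)
        if method == "lda":
            members.append(train_lda(ts))
        elif method == "svm":
            members.append(train_svm(ts, kernel=svm_kernel))
        else:
            raise ValueError(f"unknown method {method!r}")
    return ClassifierEnsemble(members=members, method=method,
                              base_seed=base_seed, null=null)


@dataclass(frozen=True)
class PredictionSummary:
    """Counts entering the balanced-accuracy formula."""

    i_correct: int
    i_total: int
    e_correct: int
    e_total: int

    def __post_init__(self):
        if not (0 <= self.i_correct <= self.i_total):
            raise ValueError("induction counts inconsistent")
        if not (0 <= self.e_correct <= self.e_total):
            raise ValueError("emergence counts inconsistent")


def balanced_accuracy(summary: PredictionSummary) -> float:
    """(1/2)(I_C/I_T + E_C/E_T); raises on empty classes."""
    if summary.i_total == 0 or summary.e_total == 0:
        raise ValueError("balanced accuracy undefined with an empty class")
    return 0.5 * (summary.i_correct / summary.i_total
                  + summary.e_correct / summary.e_total)


def summarize_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> PredictionSummary:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    is_ind = y_true == LABEL_INDUCTION
    is_em = y_true == LABEL_EMERGENCE
    return PredictionSummary(
        i_correct=int((is_ind & (y_pred == LABEL_INDUCTION)).sum()),
        i_total=int(is_ind.sum()),
        e_correct=int((is_em & (y_pred == LABEL_EMERGENCE)).sum()),
        e_total=int(is_em.sum()),
    )
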