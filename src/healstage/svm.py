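"""One-vs-one linear SVM voting weighted by hyperplane distance, and the
one-vs-all elimination cascade.

One binary linear-kernel SVM is trained per unordered pair of classes
(control plus the nine post-injury hours gives C(10,2) = 45 models).  A
test sample consults every model; each votes for the class on its side
of the decision boundary with weight

    R = |w . x + b| / ||w||,

the perpendicular distance of the sample from the separating hyperplane,
and the class with the largest summed weighted vote wins.

The one-vs-all cascade first separates control from injured; an injured
call then repeatedly trains each remaining hour against the rest,
eliminating the least-supported hour until one survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .errors import ConfigError, DimensionError
from .types import CONTROL, ClassificationResult, ClassLabel, best_class, class_order


@dataclass
class HyperplaneModel:
    """A trained linear decision boundary between two classes."""

    w: np.ndarray
    b: float
    class_neg: ClassLabel  # decision value < 0
    class_pos: ClassLabel  # decision value > 0

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float).ravel()
        if not np.linalg.norm(self.w) > 0:
            raise ConfigError("hyperplane normal vector must be nonzero")

    def decision(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float).ravel()
        if x.shape != self.w.shape:
            raise DimensionError(
                f"profile has {x.size} features, model expects {self.w.size}"
            )
        return float(self.w @ x + self.b)


@dataclass
class PairwiseSVM:
    """The full pairwise model set plus the shared feature standardization."""

    models: list[HyperplaneModel]
    classes: list[ClassLabel]
    feature_ids: list[str]
    mean: np.ndarray | None = None  # z-scoring parameters (None = raw)
    sd: np.ndarray | None = None

    def transform(self, x) -> np.ndarray:
        if isinstance(x, pd.Series):
            x = x.reindex(self.feature_ids).to_numpy()
        x = np.asarray(x, dtype=float).ravel()
        if x.size != len(self.feature_ids):
            raise DimensionError(
                f"profile has {x.size} features, model expects {len(self.feature_ids)}"
            )
        if self.mean is not None:
            x = (x - self.mean) / self.sd
        return x


@dataclass
class VoteTally:
    """Per-class accumulated weighted votes; one vote per pairwise model."""

    votes: dict[ClassLabel, float]
    n_models: int
    winner: ClassLabel = field(init=False)

    def __post_init__(self):
        self.winner, _, _ = best_class(self.votes, higher_is_better=True)

    def to_dict(self) -> dict:
        return {
            "votes": {str(c): float(v) for c, v in self.votes.items()},
            "n_models": self.n_models,
            "winner": str(self.winner),
        }


def hyperplane_distance(model: HyperplaneModel, x: np.ndarray) -> float:
    """Perpendicular distance R = |w.x + b| / ||w|| of x from the boundary."""
    return abs(model.decision(x)) / float(np.linalg.norm(model.w))


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0  # constant features carry no information either way
    return (X - mean) / sd, mean, sd


def _fit_linear(X: np.ndarray, y: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def train_pairwise(
    X: pd.DataFrame,
    labels: Sequence[ClassLabel],
    C: float = 1.0,
    standardize: bool = True,
) -> PairwiseSVM:
    """Train one linear SVM per unordered class pair.

    ``X`` is samples x features (replicate-level profiles); ``labels``
    the per-sample class (control or hour).  K classes yield C(K,2)
    models.  Features are z-scored once over the whole training set.
    """
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise ConfigError("one label per training sample required")
    if len(set(labels)) < 2:
        raise ConfigError("need at least two classes to train")
    classes = sorted(set(labels), key=class_order)
    counts = pd.Series(labels).value_counts()
    empty = [c for c in classes if counts.get(c, 0) == 0]
    if empty:
        raise ConfigError(f"class {empty[0]!r} has no training samples")

    mat = X.to_numpy(dtype=float)
    mean = sd = None
    if standardize:
        mat, mean, sd = _standardize(mat)
    y = np.array(labels, dtype=object)

    models = []
    for i, a in enumerate(classes):
        for bcls in classes[i + 1 :]:
            mask = (y == a) | (y == bcls)
            # map to {0, 1} so sklearn's class order (hence decision sign)
            # is ours: a -> negative side, b -> positive side
            yy = (y[mask] == bcls).astype(int)
            w, b0 = _fit_linear(mat[mask], yy, C)
            models.append(HyperplaneModel(w=w, b=b0, class_neg=a, class_pos=bcls))
    return PairwiseSVM(
        models=models,
        classes=classes,
        feature_ids=[str(f) for f in X.columns],
        mean=mean,
        sd=sd,
    )


def classify_one_vs_one(
    svm: PairwiseSVM, x
) -> tuple[VoteTally, ClassificationResult]:
    """Weighted one-vs-one vote: every pairwise model votes for its
    predicted side with the sample's hyperplane distance as weight."""
    z = svm.transform(x)
    votes: dict[ClassLabel, float] = {c: 0.0 for c in svm.classes}
    for model in svm.models:
        d = model.decision(z)
        cls = model.class_pos if d > 0 else model.class_neg
        votes[cls] += abs(d) / float(np.linalg.norm(model.w))
    tally = VoteTally(votes=dict(votes), n_models=len(svm.models))
    winner, margin, tie = best_class(votes, higher_is_better=True)
    result = ClassificationResult(
        scores=dict(votes), winner=winner, margin=margin, tie=tie, method="svm_ovo"
    )
    return tally, result


def classify_one_vs_all(
    X: pd.DataFrame,
    labels: Sequence[ClassLabel],
    x,
    C: float = 1.0,
    standardize: bool = True,
) -> ClassificationResult:
    """Control-vs-injured gate, then hour-by-hour elimination.

    Stage 1 trains control against all injured hours pooled; a control
    call stops there.  Otherwise each remaining hour is trained against
    the pooled rest and the hour with the weakest evidence of membership
    is eliminated, repeating until one hour survives.  The elimination
    order is recorded in ``scores`` as ranks (the survivor ranked
    highest).
    """
    labels = list(labels)
    mat = X.to_numpy(dtype=float)
    mean = sd = None
    if standardize:
        mat, mean, sd = _standardize(mat)
    if isinstance(x, pd.Series):
        x = x.reindex(X.columns).to_numpy()
    xv = np.asarray(x, dtype=float).ravel()
    if xv.size != mat.shape[1]:
        raise DimensionError(f"profile has {xv.size} features, expected {mat.shape[1]}")
    if standardize:
        xv = (xv - mean) / sd
    y = np.array(labels, dtype=object)
    hours = sorted({c for c in labels if c != CONTROL}, key=class_order)
    if CONTROL not in labels or not hours:
        raise ConfigError("one-vs-all needs control samples and >=1 injured hour")

    # stage 1: control vs pooled injured
    yy = (y != CONTROL).astype(int)  # 1 = injured side
    w, b0 = _fit_linear(mat, yy, C)
    stage1 = HyperplaneModel(w=w, b=b0, class_neg=CONTROL, class_pos="injured")
    if stage1.decision(xv) <= 0:
        scores = {CONTROL: 1.0, **{h: 0.0 for h in hours}}
        return ClassificationResult(
            scores=scores, winner=CONTROL, margin=1.0, method="svm_ova"
        )

    remaining = list(hours)
    eliminated: list[ClassLabel] = []
    while len(remaining) > 1:
        support: dict[ClassLabel, float] = {}
        for h in remaining:
            mask = np.isin(y, remaining)
            yy = (y[mask] == h).astype(int)  # 1 = this hour
            w, b0 = _fit_linear(mat[mask], yy, C)
            model = HyperplaneModel(w=w, b=b0, class_neg="rest", class_pos=h)
            support[h] = model.decision(xv)
        # drop the least-supported hour; on ties drop the later one so the
        # earlier hour survives, matching the package-wide tie rule
        weakest = sorted(remaining, key=lambda h: (support[h], -class_order(h)))[0]
        eliminated.append(weakest)
        remaining.remove(weakest)

    winner = remaining[0]
    ranks: dict[ClassLabel, float] = {CONTROL: 0.0}
    for rank, h in enumerate(eliminated, start=1):
        ranks[h] = float(rank)
    ranks[winner] = float(len(eliminated) + 1)
    result = ClassificationResult(
        scores=ranks, winner=winner, margin=1.0, method="svm_ova"
    )
    result.elimination_order = eliminated  # length <= K-1, recorded for audit
    return result
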