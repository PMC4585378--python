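"""The two time point signatures classifiers and their confidence tiers.

Both methods compare a test sample's per-gene up/down/no-change profile
(relative to uninjured controls) against the training profile of each
candidate class (the nine post-injury hours plus a control class that
expects no change anywhere), and call the class with the best match
score.

*Time point-specific* method: a gene's vote is weighted by one over the
number of time points at which it responded, computed separately for up-
and downregulated directions — a gene up at two hours carries 1/2 per
matching hour, a gene down at one hour carries 1.  A gene unchanged in
both profiles adds a fixed 0.5.

*Time point-weighted* method: a gene's vote at an hour is its fold-change
magnitude there normalized by its maximum fold-change magnitude across
hours (so weights lie in [0, 1], equal to 1 at the peak hour), with the
expected direction kept alongside; the unchanged/unchanged match again
adds 0.5.  A companion score-matrix variant restricts to genes
significant at exactly one training hour, encodes profiles as -1/0/+1
matrices, and calls the hour minimizing the element-wise L1 distance.

Confidence tiers: a winning margin above 100 weighted genes is a high
confidence call, 50-100 medium, below 50 low.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from os import PathLike
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .differential import CALL_DOWN, CALL_NONE, CALL_UP, FoldChangeMatrix
from .errors import DimensionError
from .types import CONTROL, ClassificationResult, ClassLabel, best_class

#: Score added when a gene shows no significant change in both the
#: training and the test profile (fitted once in the source analysis;
#: exposed as a parameter, not re-optimized here).
NO_CHANGE_INCREMENT = 0.5

#: Default confidence-tier thresholds (margin in weighted-gene units).
HIGH_CONFIDENCE_MARGIN = 100.0
MEDIUM_CONFIDENCE_MARGIN = 50.0


@dataclass
class SpecificSignatureModel:
    """Per-gene 1/k directional weights plus expected calls per hour."""

    calls: pd.DataFrame  # features x hours, expected {up, down, none}
    up_weight: pd.Series  # 1 / (#hours called up); NaN when none
    down_weight: pd.Series

    @property
    def features(self) -> pd.Index:
        return self.calls.index

    @property
    def time_points(self) -> list[int]:
        return [int(t) for t in self.calls.columns]

    def to_tsv(self, path: str | PathLike, header_comment: str | None = None) -> None:
        long = self.calls.stack().rename("expected_call").reset_index()
        long.columns = ["feature_id", "time_point_h", "expected_call"]
        long["up_weight"] = self.up_weight.reindex(long["feature_id"]).to_numpy()
        long["down_weight"] = self.down_weight.reindex(long["feature_id"]).to_numpy()
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            long.to_csv(fh, sep="\t", index=False)


@dataclass
class WeightedSignatureModel:
    """Normalized |fold change| weights per gene x hour, with signs."""

    weights: pd.DataFrame  # in [0, 1]; 1 at the max-|fold| hour(s)
    calls: pd.DataFrame  # expected {up, down, none}
    max_tp: pd.Series  # hour of the max |fold change| (earliest on ties)

    @property
    def features(self) -> pd.Index:
        return self.weights.index

    @property
    def time_points(self) -> list[int]:
        return [int(t) for t in self.weights.columns]

    def to_tsv(self, path: str | PathLike, header_comment: str | None = None) -> None:
        long = self.weights.stack().rename("weight").reset_index()
        long.columns = ["feature_id", "time_point_h", "weight"]
        long["expected_call"] = self.calls.stack().to_numpy()
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            long.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_specific(fc_train: FoldChangeMatrix) -> SpecificSignatureModel:
    """Fit 1/k directional weights from the training call matrix.

    Up and down responses are counted independently: a gene up at 3 h and
    10 h and down at 504 h gets up-weight 1/2 and down-weight 1.
    """
    calls = fc_train.calls
    n_up = (calls == CALL_UP).sum(axis=1).astype(float)
    n_down = (calls == CALL_DOWN).sum(axis=1).astype(float)
    with np.errstate(divide="ignore"):
        up_w = (1.0 / n_up).replace(np.inf, np.nan)
        down_w = (1.0 / n_down).replace(np.inf, np.nan)
    return SpecificSignatureModel(calls=calls.copy(), up_weight=up_w, down_weight=down_w)


def fit_weighted(fc_train: FoldChangeMatrix) -> WeightedSignatureModel:
    """Fit normalized fold-change-magnitude weights from training folds.

    Per gene, each hour's weight is |log2 fold| divided by the gene's
    maximum |log2 fold| across hours; an all-zero row stays all zero (an
    inert gene).  The expected direction is the training call.
    """
    absfc = fc_train.log2fc.abs()
    row_max = absfc.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        weights = absfc.div(row_max.where(row_max > 0), axis=0).fillna(0.0)
    max_tp = absfc.idxmax(axis=1)  # earliest hour on ties (column order)
    return WeightedSignatureModel(
        weights=weights, calls=fc_train.calls.copy(), max_tp=max_tp
    )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _expected_calls(model_calls: pd.DataFrame, candidate: ClassLabel) -> pd.Series:
    if candidate == CONTROL:
        return pd.Series(CALL_NONE, index=model_calls.index)
    return model_calls[int(candidate)]


def _common_features(model_features: pd.Index, test_index: pd.Index) -> pd.Index:
    common = model_features.intersection(test_index)
    if len(common) == 0:
        raise DimensionError("model and test profile share no features")
    return common


def score_specific(
    model: SpecificSignatureModel,
    test_calls: pd.Series,
    candidate: ClassLabel,
) -> float:
    """Match score of a test call profile against one candidate class.

    For every gene whose test call equals the model's expected call at
    the candidate hour, the score grows by the gene's directional 1/k
    weight (up or down), or by 0.5 when both calls are ``none``.  The
    control candidate expects ``none`` everywhere.
    """
    common = _common_features(model.features, test_calls.index)
    expected = _expected_calls(model.calls, candidate).loc[common]
    observed = test_calls.loc[common]
    match = expected.to_numpy() == observed.to_numpy()
    exp = expected.to_numpy()
    contrib = np.zeros(len(common))
    contrib[match & (exp == CALL_UP)] = model.up_weight.loc[common].to_numpy()[
        match & (exp == CALL_UP)
    ]
    contrib[match & (exp == CALL_DOWN)] = model.down_weight.loc[common].to_numpy()[
        match & (exp == CALL_DOWN)
    ]
    contrib[match & (exp == CALL_NONE)] = NO_CHANGE_INCREMENT
    return float(np.nansum(contrib))


def score_weighted(
    model: WeightedSignatureModel,
    test_calls: pd.Series,
    candidate: ClassLabel,
) -> float:
    """Match score under the normalized fold-change weighting.

    An up/down match at the candidate hour adds the gene's normalized
    weight there; an unchanged/unchanged match adds 0.5 (the same
    no-change increment as the specific method).
    """
    common = _common_features(model.features, test_calls.index)
    expected = _expected_calls(model.calls, candidate).loc[common]
    observed = test_calls.loc[common]
    match = expected.to_numpy() == observed.to_numpy()
    exp = expected.to_numpy()
    if candidate == CONTROL:
        weights = np.zeros(len(common))
    else:
        weights = model.weights[int(candidate)].loc[common].to_numpy()
    contrib = np.zeros(len(common))
    directional = match & (exp != CALL_NONE)
    contrib[directional] = weights[directional]
    contrib[match & (exp == CALL_NONE)] = NO_CHANGE_INCREMENT
    return float(contrib.sum())


def classify_signature(
    model: SpecificSignatureModel | WeightedSignatureModel,
    test_calls: pd.Series,
    candidates: Sequence[ClassLabel] | None = None,
    confidence_margins: tuple[float, float] = (
        HIGH_CONFIDENCE_MARGIN,
        MEDIUM_CONFIDENCE_MARGIN,
    ),
) -> ClassificationResult:
    """Score every candidate class and call the argmax, with confidence.

    Candidates default to the control class plus the model's hours.  Ties
    break toward the earlier class (control first), flagged on the result.
    """
    if candidates is None:
        candidates = [CONTROL, *model.time_points]
    scorer = score_specific if isinstance(model, SpecificSignatureModel) else score_weighted
    scores = {c: scorer(model, test_calls, c) for c in candidates}
    winner, margin, tie = best_class(scores, higher_is_better=True)
    method = "specific" if isinstance(model, SpecificSignatureModel) else "weighted"
    result = ClassificationResult(
        scores=scores, winner=winner, margin=margin, tie=tie, method=method
    )
    return assign_confidence(result, *confidence_margins)


# ---------------------------------------------------------------------------
# score-matrix (-1/0/+1) variant
# ---------------------------------------------------------------------------

def build_score_matrix(
    fc: FoldChangeMatrix, features: Iterable[str] | None = None
) -> pd.DataFrame:
    """Encode calls as a -1/0/+1 matrix (restrict to single-hour genes upstream)."""
    calls = fc.calls if features is None else fc.calls.loc[list(features)]
    mat = pd.DataFrame(0, index=calls.index, columns=calls.columns, dtype=int)
    mat[calls == CALL_UP] = 1
    mat[calls == CALL_DOWN] = -1
    return mat


def score_vector(test_calls: pd.Series) -> pd.Series:
    """Encode one test call profile as a -1/0/+1 vector."""
    vec = pd.Series(0, index=test_calls.index, dtype=int)
    vec[test_calls == CALL_UP] = 1
    vec[test_calls == CALL_DOWN] = -1
    return vec


def score_matrix_classify(
    train_matrix: pd.DataFrame,
    test_calls: pd.Series,
    include_control: bool = True,
) -> ClassificationResult:
    """Call the hour whose +-1/0 training column is L1-nearest the test.

    ``train_matrix`` should cover genes significant at exactly one
    training hour.  The test profile is thresholded to -1/0/+1 and, per
    candidate hour, the element-wise absolute difference against the
    training column is summed; the minimal total distance wins.  When
    ``include_control``, an all-zero expected column represents the
    uninjured class.
    """
    common = _common_features(train_matrix.index, test_calls.index)
    train = train_matrix.loc[common]
    vec = score_vector(test_calls.loc[common]).to_numpy()
    distances: dict[ClassLabel, float] = {}
    if include_control:
        distances[CONTROL] = float(np.abs(vec).sum())
    for tp in train.columns:
        distances[int(tp)] = float(np.abs(train[tp].to_numpy() - vec).sum())
    winner, margin, tie = best_class(distances, higher_is_better=False)
    return ClassificationResult(
        scores=distances,
        winner=winner,
        margin=margin,
        tie=tie,
        higher_is_better=False,
        method="score_matrix",
    )


def assign_confidence(
    result: ClassificationResult,
    high: float = HIGH_CONFIDENCE_MARGIN,
    medium: float = MEDIUM_CONFIDENCE_MARGIN,
) -> ClassificationResult:
    """Attach the confidence tier implied by the winning margin.

    Margin > ``high`` is a high-confidence call; ``medium`` <= margin <=
    ``high`` is medium; anything smaller (including ties) is low.
    """
    if len(result.scores) < 2:
        raise DimensionError("confidence needs at least two scored classes")
    if result.margin > high:
        tier = "high"
    elif medium <= result.margin <= high:
        tier = "medium"
    else:
        tier = "low"
    return replace(result, confidence=tier)
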