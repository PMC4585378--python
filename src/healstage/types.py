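"""Core in-memory containers shared by every stage of the pipeline.

An :class:`ExpressionStudy` holds a replicate-level (or aggregated) FPKM
matrix together with per-sample metadata.  Class labels used throughout the
classifiers are either the string ``"control"`` or an integer post-injury
hour; :func:`class_order` gives the canonical ordering (control first, then
hours ascending), which is also the tie-break order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import StudyError

#: Post-injury sampling times (hours) of the study design.
DEFAULT_TIME_POINTS: tuple[int, ...] = (3, 10, 24, 48, 72, 168, 336, 504, 672)

CONTROL = "control"
INJURED = "injured"
#: Condition of a blinded sample whose label is sealed.
BLINDED = "blinded"

#: Coarse healing periods: early inflammation, mid repair, late remodeling.
COARSE_PERIODS: Mapping[str, tuple[int, int]] = {
    "early": (3, 24),
    "middle": (48, 168),
    "late": (336, 672),
}

ClassLabel = str | int


def class_order(label: ClassLabel) -> float:
    """Sort key for class labels: control before any injured hour."""
    if label == CONTROL:
        return -1.0
    return float(label)


def coarse_period(label: ClassLabel) -> str:
    """Map a class label onto the early/middle/late healing period."""
    if label == CONTROL:
        return CONTROL
    hour = float(label)
    for name, (lo, hi) in COARSE_PERIODS.items():
        if lo <= hour <= hi:
            return name
    raise ValueError(f"hour {hour} outside every coarse period")


@dataclass(frozen=True)
class Sample:
    """Metadata for one profiled tissue sample."""

    sample_id: str
    condition: str  # control | injured | blinded
    time_point_h: int | None
    replicate: int | None = None

    def __post_init__(self):
        if self.condition not in (CONTROL, INJURED, BLINDED):
            raise StudyError(f"unknown condition {self.condition!r}")
        if self.condition == INJURED and self.time_point_h is None:
            raise StudyError(f"injured sample {self.sample_id} lacks a time point")


class ExpressionStudy:
    """FPKM matrix (features x samples) with per-sample metadata.

    Parameters
    ----------
    values
        Non-negative FPKM values, indexed by feature id, one column per
        sample id.
    samples
        Per-sample metadata with columns ``condition``, ``time_point_h``,
        ``replicate``; its index must equal the value columns.
    qvalues
        Optional per-feature, per-time-point q-values from an upstream
        differential test (columns are integer hours).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        samples: pd.DataFrame,
        qvalues: pd.DataFrame | None = None,
    ):
        self.values = values.astype(float)
        self.samples = samples
        self.qvalues = qvalues
        self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise StudyError(f"duplicate feature id {dup!r}")
        if list(self.values.columns) != list(self.samples.index):
            raise StudyError("sample metadata does not match value columns")
        if (self.values.to_numpy() < 0).any():
            raise StudyError("negative FPKM value in expression matrix")
        if self.values.isna().any().any():
            raise StudyError("missing FPKM value in expression matrix")
        for sid, row in self.samples.iterrows():
            tp = row["time_point_h"]
            Sample(
                sample_id=str(sid),
                condition=row["condition"],
                time_point_h=None if pd.isna(tp) else int(tp),
                replicate=None if pd.isna(row.get("replicate")) else int(row["replicate"]),
            )

    # -- conveniences ---------------------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def time_points(self, condition: str = INJURED) -> list[int]:
        mask = self.samples["condition"] == condition
        tps = self.samples.loc[mask, "time_point_h"].dropna().unique()
        return sorted(int(t) for t in tps)

    def groups(self) -> dict[tuple[str, int | None], list[str]]:
        """Sample ids grouped by (condition, time point)."""
        out: dict[tuple[str, int | None], list[str]] = {}
        for sid, row in self.samples.iterrows():
            tp = row["time_point_h"]
            key = (row["condition"], None if pd.isna(tp) else int(tp))
            out.setdefault(key, []).append(str(sid))
        return out

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionStudy":
        ids = list(sample_ids)
        return ExpressionStudy(self.values[ids], self.samples.loc[ids], self.qvalues)

    def subset_features(self, feature_ids: Iterable[str]) -> "ExpressionStudy":
        ids = list(feature_ids)
        q = self.qvalues.loc[ids] if self.qvalues is not None else None
        return ExpressionStudy(self.values.loc[ids], self.samples, q)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ExpressionStudy):
            return NotImplemented
        same = self.values.equals(other.values) and self.samples.equals(other.samples)
        if self.qvalues is None or other.qvalues is None:
            return same and (self.qvalues is None) == (other.qvalues is None)
        return same and self.qvalues.equals(other.qvalues)

    def __repr__(self) -> str:
        return f"ExpressionStudy({self.values.shape[0]} features x {self.n_samples} samples)"


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]


@dataclass
class GeneSetCollection:
    """Named pathways mapped to member feature identifiers (GMT-style)."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets.values())

    def add(self, name: str, description: str, members: Iterable[str]) -> None:
        if name in self.sets:
            raise StudyError(f"duplicate gene set name {name!r}")
        deduped = tuple(dict.fromkeys(members))
        if not deduped:
            raise StudyError(f"gene set {name!r} is empty")
        self.sets[name] = GeneSet(name, description, deduped)


@dataclass
class ClassificationResult:
    """Per-class scores of one classified sample and the resulting call.

    ``higher_is_better`` distinguishes vote/match scores from distance
    metrics; ``margin`` is always oriented so that larger means a more
    clear-cut call, and is 0 for an exact tie.
    """

    scores: dict[ClassLabel, float]
    winner: ClassLabel
    margin: float
    confidence: str | None = None
    tie: bool = False
    higher_is_better: bool = True
    method: str | None = None

    def __post_init__(self):
        if self.margin < 0:
            raise ValueError("margin must be non-negative")

    @property
    def runner_up(self) -> ClassLabel | None:
        others = {c: s for c, s in self.scores.items() if c != self.winner}
        if not others:
            return None
        sign = -1.0 if self.higher_is_better else 1.0
        return sorted(others, key=lambda c: (sign * others[c], class_order(c)))[0]

    def to_dict(self) -> dict:
        return {
            "scores": {str(c): float(s) for c, s in self.scores.items()},
            "winner": str(self.winner),
            "margin": float(self.margin),
            "confidence": self.confidence,
            "tie": self.tie,
            "higher_is_better": self.higher_is_better,
            "method": self.method,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def best_class(
    scores: Mapping[ClassLabel, float], higher_is_better: bool = True
) -> tuple[ClassLabel, float, bool]:
    """Pick the winning class, its margin over the runner-up, and a tie flag.

    Ties are broken toward the earlier class in :func:`class_order`
    (control first), deterministically.
    """
    if not scores:
        raise ValueError("no candidate classes scored")
    ordered = sorted(scores, key=class_order)
    vals = np.array([scores[c] for c in ordered], dtype=float)
    if not higher_is_better:
        vals = -vals
    best = vals.max()
    # near-equal scores (to float precision) tie; earliest class wins
    close = np.isclose(vals, best, rtol=1e-9, atol=0.0)
    best_idx = int(np.flatnonzero(close)[0])
    winner = ordered[best_idx]
    tie = bool(close.sum() > 1)
    if len(ordered) == 1:
        return winner, 0.0, tie
    rest = np.delete(vals, best_idx)
    margin = float(max(vals[best_idx] - rest.max(), 0.0))
    return winner, margin, tie
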