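"""Per-time-point fold-change profiles, significance calls, and the
feature filters that feed the classifiers.

Fold changes compare each injured time point's aggregate against its
matched (contralateral) control aggregate:
``log2fc = log2((injured + eps) / (control + eps))`` with a small
pseudocount so zero-FPKM cells stay defined.  A cell is called ``up``
when log2fc >= log2(min_fold) (``down`` symmetrically), the two-fold rule
by default, optionally gated by a per-cell q-value threshold.

Four filtering approaches select the features handed to the classifiers:
all significant genes, genes significant at exactly one time point, and
the same two applied to isoform tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from os import PathLike

import numpy as np
import pandas as pd

from .errors import ConfigError, PairingError
from .types import CONTROL, INJURED, ExpressionStudy

CALL_UP = "up"
CALL_DOWN = "down"
CALL_NONE = "none"

#: The four filtering approaches; isoform modes behave like the gene
#: modes on whatever feature table the caller designates as isoforms.
FILTER_MODES = (
    "all_significant_genes",
    "single_tp_genes",
    "all_significant_isoforms",
    "single_tp_isoforms",
)


@dataclass
class FilterSpec:
    """Thresholds for significance calls and feature selection.

    ``min_fpkm`` is 1.0 for the discovery-style filter and 0.5 for the
    classification filter; ``q_max=None`` disables q-value gating (used
    when no upstream differential q column exists, e.g. single blinded
    samples).
    """

    mode: str = "all_significant_genes"
    min_fpkm: float = 1.0
    q_max: float | None = 0.05
    min_fold: float = 2.0

    def validate(self) -> None:
        if self.mode not in FILTER_MODES:
            raise ConfigError(f"mode must be one of {FILTER_MODES}")
        if self.min_fpkm <= 0:
            raise ConfigError("min_fpkm must be > 0")
        if self.min_fold <= 1:
            raise ConfigError("min_fold must be > 1")
        if self.q_max is not None and not 0 < self.q_max <= 1:
            raise ConfigError("q_max must lie in (0, 1] or be None")

    @property
    def single_tp(self) -> bool:
        return self.mode.startswith("single_tp")


@dataclass
class FoldChangeMatrix:
    """log2 fold changes, calls, and per-feature max FPKM."""

    log2fc: pd.DataFrame  # features x time points
    calls: pd.DataFrame  # entries in {up, down, none}
    fpkm_max: pd.Series  # max aggregate FPKM over time points/conditions
    qvalues: pd.DataFrame | None = None

    @property
    def features(self) -> pd.Index:
        return self.log2fc.index

    @property
    def time_points(self) -> list[int]:
        return [int(t) for t in self.log2fc.columns]

    def subset(self, feature_ids) -> "FoldChangeMatrix":
        ids = list(feature_ids)
        return FoldChangeMatrix(
            self.log2fc.loc[ids],
            self.calls.loc[ids],
            self.fpkm_max.loc[ids],
            None if self.qvalues is None else self.qvalues.loc[ids],
        )

    def to_tsv(self, path: str | PathLike, header_comment: str | None = None) -> None:
        long = self.log2fc.stack().rename("log2fc").reset_index()
        long.columns = ["feature_id", "time_point_h", "log2fc"]
        long["call"] = self.calls.stack().to_numpy()
        long["fpkm_max"] = self.fpkm_max.reindex(long["feature_id"]).to_numpy()
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            long.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | PathLike) -> "FoldChangeMatrix":
        long = pd.read_csv(path, sep="\t", comment="#")
        log2fc = long.pivot(index="feature_id", columns="time_point_h", values="log2fc")
        calls = long.pivot(index="feature_id", columns="time_point_h", values="call")
        fpkm_max = long.groupby("feature_id")["fpkm_max"].first()
        log2fc.columns = [int(c) for c in log2fc.columns]
        calls.columns = [int(c) for c in calls.columns]
        return cls(log2fc, calls, fpkm_max.loc[log2fc.index])


def call_matrix(
    log2fc: pd.DataFrame,
    min_fold: float = 2.0,
    qvalues: pd.DataFrame | None = None,
    q_max: float | None = None,
) -> pd.DataFrame:
    """Assign up/down/none calls from fold-change (and optional q) thresholds."""
    thr = np.log2(min_fold)
    fc = log2fc.to_numpy()
    calls = np.full(fc.shape, CALL_NONE, dtype=object)
    calls[fc >= thr] = CALL_UP
    calls[fc <= -thr] = CALL_DOWN
    if qvalues is not None and q_max is not None:
        q = qvalues.reindex(index=log2fc.index, columns=log2fc.columns).to_numpy()
        calls[~(q < q_max)] = CALL_NONE
    return pd.DataFrame(calls, index=log2fc.index, columns=log2fc.columns)


def compute_fold_changes(
    injured: ExpressionStudy,
    control: ExpressionStudy,
    pseudocount: float = 0.5,
    spec: FilterSpec | None = None,
) -> FoldChangeMatrix:
    """Build the fold-change matrix from aggregated injured/control studies.

    Every injured time point must have a control aggregate at the same
    hour (the contralateral pairing); a missing counterpart raises
    :class:`PairingError`.  Calls follow ``spec`` (default
    :class:`FilterSpec`), with q gating applied only when the injured
    study carries q-values and ``spec.q_max`` is set.
    """
    spec = spec or FilterSpec()
    spec.validate()
    if not injured.features.equals(control.features):
        raise PairingError("injured and control studies list different features")
    inj_tps = injured.time_points(INJURED)
    ctl_tps = set(control.time_points(CONTROL))
    missing = [t for t in inj_tps if t not in ctl_tps]
    if missing:
        raise PairingError(f"no control aggregate for time point(s) {missing}")

    inj_groups = injured.groups()
    ctl_groups = control.groups()
    inj_cols = {t: inj_groups[(INJURED, t)][0] for t in inj_tps}
    ctl_cols = {t: ctl_groups[(CONTROL, t)][0] for t in inj_tps}

    inj_mat = injured.values[[inj_cols[t] for t in inj_tps]].to_numpy()
    ctl_mat = control.values[[ctl_cols[t] for t in inj_tps]].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(inj_mat + pseudocount) - np.log2(ctl_mat + pseudocount)
    log2fc = pd.DataFrame(log2fc, index=injured.features, columns=inj_tps)

    q = injured.qvalues
    calls = call_matrix(log2fc, spec.min_fold, q, spec.q_max)
    fpkm_max = pd.Series(
        np.maximum(inj_mat.max(axis=1), ctl_mat.max(axis=1)),
        index=injured.features,
        name="fpkm_max",
    )
    q_aligned = None if q is None else q.reindex(index=log2fc.index, columns=inj_tps)
    return FoldChangeMatrix(log2fc, calls, fpkm_max, q_aligned)


def test_fold_profiles(
    test: ExpressionStudy,
    control_aggregate: ExpressionStudy,
    pseudocount: float = 0.5,
    min_fold: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fold-change and call profiles for test samples of unknown stage.

    Each test sample is compared against the mean of the control
    aggregates across time points (the global uninjured reference, since
    a blinded sample has no matched hour).  Returns ``(log2fc, calls)``
    with one column per test sample; no q gating (single samples carry no
    differential q-values).
    """
    ctl_ids = [s for s, row in control_aggregate.samples.iterrows() if row["condition"] == CONTROL]
    if not ctl_ids:
        raise PairingError("control study contains no control samples")
    ref = control_aggregate.values[ctl_ids].mean(axis=1)
    ref = ref.reindex(test.features)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(test.values.add(pseudocount, axis=0)).sub(
            np.log2(ref + pseudocount), axis=0
        )
    calls = call_matrix(log2fc, min_fold)
    return log2fc, calls


def significant_cells(fc: FoldChangeMatrix, spec: FilterSpec) -> pd.DataFrame:
    """Boolean matrix of cells passing the fold (and optional q) rule."""
    thr = np.log2(spec.min_fold)
    sig = fc.log2fc.abs() >= thr
    if spec.q_max is not None:
        if fc.qvalues is None:
            raise ConfigError("q_max is set but the fold-change matrix has no q-values")
        sig &= fc.qvalues < spec.q_max
    return sig


def select_features(fc: FoldChangeMatrix, spec: FilterSpec) -> list[str]:
    """Apply one of the four filtering approaches and return feature ids.

    ``all_significant`` modes keep features with max FPKM >= ``min_fpkm``
    and at least one significant cell; ``single_tp`` modes additionally
    require the significant cell to be unique (up and down counted
    together).
    """
    spec.validate()
    sig = significant_cells(fc, spec)
    n_sig = sig.sum(axis=1)
    keep = (fc.fpkm_max >= spec.min_fpkm) & (n_sig >= 1)
    if spec.single_tp:
        keep &= n_sig == 1
    return fc.features[keep].tolist()
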