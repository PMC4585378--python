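"""Reading and writing expression tables and gene sets, and the
replicate-level quality control applied before any downstream analysis.

Two table dialects are supported: a plain TSV matrix (feature rows,
sample columns) with a companion sample-metadata TSV, and a Cufflinks
``fpkm_tracking``-style table where per-sample abundances live in
``<sample>_FPKM`` columns keyed by ``tracking_id``.

Quality control follows two rules applied to each (condition, time point)
replicate group:

* a replicate is excluded when its squared Pearson correlation against
  any other replicate of its group falls below a cutoff (default 0.95);
* replicates are merged into one aggregate profile per group: per
  feature, the aggregate is 0 when the replicate median is 0, otherwise
  the replicate mean.
"""

from __future__ import annotations

from os import PathLike
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GroupEmptiedError, ParseError, StudyError
from .types import ExpressionStudy, GeneSetCollection

_META_COLUMNS = ["condition", "time_point_h", "replicate"]


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def _read_metadata(path: str | PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    missing = {"sample_id", *_META_COLUMNS} - set(meta.columns)
    if missing:
        raise ParseError(f"metadata lacks columns {sorted(missing)}", line=1)
    meta = meta.set_index("sample_id")
    meta["time_point_h"] = meta["time_point_h"].astype("Int64")
    meta["replicate"] = meta["replicate"].astype("Int64")
    return meta[_META_COLUMNS]


def _infer_metadata(sample_ids: list[str]) -> pd.DataFrame:
    """Parse ``condition_<hour>h_r<rep>`` style sample ids."""
    rows = []
    for sid in sample_ids:
        parts = sid.split("_")
        if len(parts) != 3 or not parts[1].endswith("h") or not parts[2].startswith("r"):
            raise ParseError(
                f"cannot infer metadata from sample id {sid!r}; "
                "provide a metadata table"
            )
        rows.append((sid, parts[0], int(parts[1][:-1]), int(parts[2][1:])))
    meta = pd.DataFrame(rows, columns=["sample_id", *_META_COLUMNS]).set_index("sample_id")
    meta["time_point_h"] = meta["time_point_h"].astype("Int64")
    meta["replicate"] = meta["replicate"].astype("Int64")
    return meta


def read_expression(
    path: str | PathLike,
    dialect: str = "tsv",
    metadata: str | PathLike | None = None,
    qvalues: str | PathLike | None = None,
) -> ExpressionStudy:
    """Read an FPKM table into an :class:`ExpressionStudy`.

    ``dialect`` is ``"tsv"`` (matrix with a leading feature-id column) or
    ``"fpkm_tracking"`` (Cufflinks tracking table).  ``metadata`` points at
    a sample-metadata TSV; when omitted, metadata is inferred from sample
    ids of the form ``injured_72h_r1``.
    """
    if dialect not in ("tsv", "fpkm_tracking"):
        raise ParseError(f"unknown dialect {dialect!r}")
    raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if raw.shape[1] < 2:
        raise ParseError("expected a feature-id column plus sample columns", line=1)

    if dialect == "tsv":
        feature_col = raw.columns[0]
        sample_cols = list(raw.columns[1:])
        table = raw.set_index(feature_col)[sample_cols]
    else:
        if "tracking_id" not in raw.columns:
            raise ParseError("fpkm_tracking table lacks a tracking_id column", line=1)
        fpkm_cols = [c for c in raw.columns if c.endswith("_FPKM")]
        if not fpkm_cols:
            raise ParseError("fpkm_tracking table has no *_FPKM columns", line=1)
        table = raw.set_index("tracking_id")[fpkm_cols]
        table.columns = [c[: -len("_FPKM")] for c in fpkm_cols]
        sample_cols = list(table.columns)

    if table.index.has_duplicates:
        pos = int(np.flatnonzero(table.index.duplicated())[0])
        raise ParseError(f"duplicate feature id {table.index[pos]!r}", line=pos + 2)
    try:
        values = table.astype(float)
    except ValueError as exc:
        raise ParseError(f"non-numeric FPKM value ({exc})") from None
    if values.isna().any().any():
        pos = int(np.flatnonzero(values.isna().any(axis=1))[0])
        raise ParseError("missing FPKM value", line=pos + 2)
    if (values.to_numpy() < 0).any():
        pos = int(np.flatnonzero((values < 0).any(axis=1))[0])
        raise ParseError(f"negative FPKM for feature {values.index[pos]!r}", line=pos + 2)

    meta = _read_metadata(metadata) if metadata is not None else _infer_metadata(sample_cols)
    try:
        meta = meta.loc[sample_cols]
    except KeyError as exc:
        raise ParseError(f"metadata missing sample {exc}") from None
    q = None
    if qvalues is not None:
        q = pd.read_csv(qvalues, sep="\t", comment="#", index_col=0)
        q.columns = [int(c) for c in q.columns]
    return ExpressionStudy(values, meta, q)


def write_expression(
    study: ExpressionStudy,
    path: str | PathLike,
    metadata: str | PathLike | None = None,
    qvalues: str | PathLike | None = None,
    header_comment: str | None = None,
) -> None:
    """Write a study as a TSV matrix plus optional metadata/q-value TSVs."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out = study.values.copy()
        out.index.name = "feature_id"
        out.to_csv(fh, sep="\t")
    if metadata is not None:
        meta = study.samples.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata, sep="\t")
    if qvalues is not None and study.qvalues is not None:
        q = study.qvalues.copy()
        q.index.name = "feature_id"
        q.to_csv(qvalues, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | PathLike) -> GeneSetCollection:
    """Read an MSigDB-style GMT file (name, description, members...)."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError("GMT line needs name, description and >=1 member", line=lineno)
            try:
                collection.add(fields[0], fields[1], fields[2:])
            except StudyError as exc:
                raise ParseError(str(exc), line=lineno) from None
    return collection


def write_gmt(collection: GeneSetCollection, path: str | PathLike) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# replicate quality filter and aggregation
# ---------------------------------------------------------------------------

def filter_replicates(
    study: ExpressionStudy,
    r2_threshold: float = 0.95,
    log_space: bool = False,
) -> tuple[ExpressionStudy, list[str]]:
    """Drop replicates that fail pairwise correlation QC within their group.

    Within each (condition, time point) group the pairwise Pearson
    correlation over features is computed (on raw FPKM by default, on
    log2(FPKM+1) when ``log_space``); a replicate is excluded when its
    squared correlation falls below ``r2_threshold`` against a strict
    majority of the other group members — i.e. the replicate is the
    outlier, not the well-correlated members it drags down.  Exclusion is
    decided in a single simultaneous pass.  Singleton groups are kept
    untouched.
    """
    excluded: list[str] = []
    for (condition, tp), sids in study.groups().items():
        if len(sids) < 2:
            continue
        mat = study.values[sids].to_numpy()
        if log_space:
            mat = np.log2(mat + 1.0)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(mat, rowvar=False)
        r2 = np.nan_to_num(corr, nan=0.0) ** 2
        np.fill_diagonal(r2, 1.0)
        n_fail = (r2 < r2_threshold).sum(axis=0)
        bad = n_fail > (len(sids) - 1) / 2
        if bad.all():
            raise GroupEmptiedError(
                f"all replicates of group ({condition}, {tp}) failed the "
                f"R^2 >= {r2_threshold} filter"
            )
        excluded.extend(np.array(sids)[bad].tolist())
    if not excluded:
        return study, []
    keep = [s for s in study.samples.index if s not in set(excluded)]
    return study.subset_samples(keep), excluded


def aggregate_replicates(study: ExpressionStudy) -> ExpressionStudy:
    """Merge replicates into one profile per (condition, time point) group.

    Per feature: aggregate FPKM is 0 when the replicate median is 0,
    otherwise the replicate mean.  Aggregate sample ids are
    ``<condition>_<hour>h`` (or just the condition for untimed groups).
    """
    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    keys = sorted(
        study.groups().items(),
        key=lambda kv: (kv[0][0], -1 if kv[0][1] is None else kv[0][1]),
    )
    for (condition, tp), sids in keys:
        mat = study.values[sids].to_numpy()
        med = np.median(mat, axis=1)
        agg = np.where(med == 0, 0.0, mat.mean(axis=1))
        sid = condition if tp is None else f"{condition}_{tp}h"
        cols[sid] = agg
        meta_rows.append((sid, condition, tp, pd.NA))
    values = pd.DataFrame(cols, index=study.features)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "condition", "time_point_h", "replicate"]
    ).set_index("sample_id")
    meta["time_point_h"] = meta["time_point_h"].astype("Int64")
    meta["replicate"] = meta["replicate"].astype("Int64")
    return ExpressionStudy(values, meta, study.qvalues)
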