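"""Pathway-level activation scores, significance, and classification.

A pathway's activation in a sample is the arithmetic mean FPKM of its
member genes present in the study (absent members are dropped from the
mean, not treated as zero).  Activation dynamics are standardized within
each pathway across the nine post-injury hours,

    Z_t = (score_t - mean_t' score_t') / sd_t' score_t',

and |Z| > 2 marks a significant excursion (the two-sided normal 5%
level).  Significant pathways additionally require a two-fold
injured/control change at the same hour.  The gene-level classifiers are
re-applied at pathway resolution by substituting the pathway score
matrix for the gene matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from os import PathLike

import numpy as np
import pandas as pd

from .differential import FilterSpec, FoldChangeMatrix
from .errors import ConfigError
from .types import ExpressionStudy, GeneSetCollection, coarse_period

logger = logging.getLogger(__name__)

Z_THRESHOLD = 2.0


@dataclass
class PathwayScoreMatrix:
    """Mean member-gene FPKM per pathway per sample/time-point column."""

    scores: pd.DataFrame  # pathways x columns
    coverage: pd.Series  # member genes present in the study
    skipped: list[str]  # pathways with no member present

    @property
    def pathways(self) -> pd.Index:
        return self.scores.index

    def to_tsv(self, path: str | PathLike, header_comment: str | None = None) -> None:
        out = self.scores.copy()
        out.insert(0, "coverage", self.coverage)
        out.index.name = "pathway"
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            out.to_csv(fh, sep="\t")


@dataclass
class PathwayZScores:
    """Within-pathway standardized activation across the injured hours."""

    z: pd.DataFrame  # pathways x hours (NaN rows for inert pathways)
    significant: pd.DataFrame  # |Z| > threshold
    inert: list[str]  # zero-sd pathways (flat across hours)
    threshold: float = Z_THRESHOLD


def pathway_scores(
    study: ExpressionStudy, sets: GeneSetCollection
) -> PathwayScoreMatrix:
    """Mean member FPKM per pathway for every sample column of the study.

    Pathways with no member present in the study are skipped (and
    logged); members absent from the study are excluded from the mean.
    """
    rows = {}
    coverage = {}
    skipped = []
    feature_set = study.features
    for gs in sets:
        members = feature_set.intersection(gs.members)
        if len(members) == 0:
            skipped.append(gs.name)
            logger.warning("pathway %s has no member in the study; skipped", gs.name)
            continue
        rows[gs.name] = study.values.loc[members].mean(axis=0)
        coverage[gs.name] = len(members)
    scores = pd.DataFrame(rows).T
    if scores.empty:
        scores = pd.DataFrame(columns=study.values.columns)
    return PathwayScoreMatrix(
        scores=scores,
        coverage=pd.Series(coverage, dtype=int),
        skipped=skipped,
    )


def pathway_study(study: ExpressionStudy, sets: GeneSetCollection) -> ExpressionStudy:
    """Re-express a study at pathway resolution (pathways as features)."""
    mat = pathway_scores(study, sets)
    return ExpressionStudy(mat.scores, study.samples, None)


def pathway_zscores(scores: pd.DataFrame) -> PathwayZScores:
    """Standardize each pathway's activation across the injured hours.

    ``scores`` is pathways x hours (the injured aggregate columns).  A
    pathway with zero variance across hours is flagged inert and carries
    NaN Z-scores.  Needs >= 2 finite columns.
    """
    if scores.shape[1] < 2:
        raise ConfigError("Z-scores need at least 2 time points")
    vals = scores.to_numpy(dtype=float)
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (vals - mean) / sd
    inert_mask = (sd == 0).ravel()
    z[inert_mask] = np.nan
    zdf = pd.DataFrame(z, index=scores.index, columns=scores.columns)
    sig = zdf.abs() > Z_THRESHOLD
    return PathwayZScores(
        z=zdf,
        significant=sig.fillna(False),
        inert=scores.index[inert_mask].tolist(),
    )


def select_significant_pathways(
    z: PathwayZScores,
    fc: FoldChangeMatrix,
    min_fold: float = 2.0,
) -> list[str]:
    """Pathways with |Z| > 2 and a two-fold injured/control change at the
    same hour (at least one such hour)."""
    common = z.z.index.intersection(fc.features)
    thr = np.log2(min_fold)
    fold_ok = fc.log2fc.loc[common].abs() >= thr
    zsig = z.significant.loc[common]
    cols = [c for c in zsig.columns if c in fold_ok.columns]
    both = zsig[cols] & fold_ok[cols]
    keep = both.any(axis=1)
    return common[keep.to_numpy()].tolist()


def classify_at_pathway_level(
    train: ExpressionStudy,
    test: ExpressionStudy,
    sets: GeneSetCollection,
    method: str = "weighted",
    filter_spec: FilterSpec | None = None,
    pseudocount: float = 0.5,
) -> dict[str, dict]:
    """Run a gene-level classifier on pathway score matrices.

    ``train`` is the replicate-level (quality-filtered) training study
    and ``test`` the blinded study; both are collapsed to pathway
    resolution and handed to the chosen classifier (``specific``,
    ``weighted``, ``score_matrix``, ``pca`` or ``svm``).  Each call also
    carries the coarse healing period (early 3-24 h, middle 48-168 h,
    late 336-672 h) of the winning class, so an adjacent-hour confusion
    still lands in the right period.
    """
    from .pipeline import classify_samples  # deferred: pipeline imports us

    spec = filter_spec or FilterSpec(min_fpkm=0.5, q_max=None)
    train_pw = pathway_study(train, sets)
    test_pw = pathway_study(test, sets)
    report = classify_samples(
        train_pw, test_pw, methods=[method], filter_spec=spec, pseudocount=pseudocount
    )
    for sample_report in report.values():
        for res in sample_report.values():
            res["coarse_period"] = coarse_period(_parse_label(res["winner"]))
    return report


def _parse_label(label: str):
    try:
        return int(label)
    except (TypeError, ValueError):
        return label
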