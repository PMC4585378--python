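"""End-to-end orchestration: simulate or load, QC, profile, classify,
report.

:func:`classify_samples` is the shared classification engine: it
aggregates a (quality-filtered) training study, builds fold-change
profiles, selects features under a filter, and runs any of the five
classifiers (``specific``, ``weighted``, ``score_matrix``, ``pca``,
``svm``) on every test sample.  :func:`run_pipeline` wraps it with
configuration, artifact writing, and accuracy scoring against sealed
labels.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from os import PathLike
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import io as hio
from .differential import (
    FilterSpec,
    compute_fold_changes,
    select_features,
    test_fold_profiles,
)
from .errors import ConfigError
from .pca import classify_nearest, fit_pca
from .signatures import (
    HIGH_CONFIDENCE_MARGIN,
    MEDIUM_CONFIDENCE_MARGIN,
    build_score_matrix,
    classify_signature,
    fit_specific,
    fit_weighted,
    score_matrix_classify,
)
from .simulate import (
    DESIGN_TEST_LABELS,
    GeneratorConfig,
    generate_blinded_tests,
    generate_study,
    write_sealed_labels,
)
from .svm import classify_one_vs_all, classify_one_vs_one, train_pairwise
from .types import CONTROL, INJURED, ExpressionStudy, coarse_period

logger = logging.getLogger(__name__)

METHODS = ("specific", "weighted", "score_matrix", "pca", "svm", "svm_ova")


def _replicate_matrix(study: ExpressionStudy, features) -> tuple[pd.DataFrame, list]:
    """Samples x features matrix and per-sample class labels."""
    X = study.values.loc[list(features)].T
    labels = []
    for _, row in study.samples.iterrows():
        if row["condition"] == CONTROL:
            labels.append(CONTROL)
        else:
            labels.append(int(row["time_point_h"]))
    return X, labels


def classify_samples(
    train: ExpressionStudy,
    test: ExpressionStudy,
    methods: Sequence[str] = ("weighted",),
    filter_spec: FilterSpec | None = None,
    pseudocount: float = 0.5,
    confidence_margins: tuple[float, float] = (
        HIGH_CONFIDENCE_MARGIN,
        MEDIUM_CONFIDENCE_MARGIN,
    ),
    n_components: int | None = None,
    svm_C: float = 1.0,
) -> dict[str, dict[str, dict]]:
    """Classify every test sample with the requested methods.

    ``train`` is replicate-level (already quality-filtered); ``test``
    holds one column per blinded sample.  Returns
    ``{sample_id: {method: result dict}}``; each result dict is a
    serialized :class:`~healstage.types.ClassificationResult` plus the
    coarse healing period of its call.
    """
    bad = [m for m in methods if m not in METHODS]
    if bad:
        raise ConfigError(f"unknown method(s) {bad}; choose from {METHODS}")
    spec = filter_spec or FilterSpec()
    spec.validate()

    agg = hio.aggregate_replicates(train)
    fc = compute_fold_changes(agg, agg, pseudocount=pseudocount, spec=spec)
    selected = select_features(fc, spec)
    if not selected:
        raise ConfigError("feature filter selected nothing; relax the thresholds")
    fc_sel = fc.subset(selected)
    _, test_calls = test_fold_profiles(
        test.subset_features(selected), agg, pseudocount, spec.min_fold
    )

    report: dict[str, dict[str, dict]] = {s: {} for s in test.values.columns}

    if "specific" in methods or "weighted" in methods:
        models = {}
        if "specific" in methods:
            models["specific"] = fit_specific(fc_sel)
        if "weighted" in methods:
            models["weighted"] = fit_weighted(fc_sel)
        for sid in test.values.columns:
            for name, model in models.items():
                res = classify_signature(
                    model, test_calls[sid], confidence_margins=confidence_margins
                )
                report[sid][name] = res.to_dict()

    if "score_matrix" in methods:
        suffix = "isoforms" if spec.mode.endswith("isoforms") else "genes"
        single_spec = dataclasses.replace(spec, mode=f"single_tp_{suffix}")
        single = select_features(fc, single_spec)
        if not single:
            raise ConfigError("no single-time-point feature available for score_matrix")
        matrix = build_score_matrix(fc, single)
        _, single_calls = test_fold_profiles(
            test.subset_features(single), agg, pseudocount, spec.min_fold
        )
        for sid in test.values.columns:
            res = score_matrix_classify(matrix, single_calls[sid])
            report[sid]["score_matrix"] = res.to_dict()

    if "pca" in methods:
        X, labels = _replicate_matrix(train, selected)
        space = fit_pca(X, labels)
        for sid in test.values.columns:
            res, _ = classify_nearest(
                space, test.values.loc[selected, sid], n_components
            )
            report[sid]["pca"] = res.to_dict()

    if "svm" in methods:
        X, labels = _replicate_matrix(train, selected)
        svm = train_pairwise(X, labels, C=svm_C)
        for sid in test.values.columns:
            tally, res = classify_one_vs_one(svm, test.values.loc[selected, sid])
            d = res.to_dict()
            d["n_models"] = tally.n_models
            report[sid]["svm"] = d

    if "svm_ova" in methods:
        X, labels = _replicate_matrix(train, selected)
        for sid in test.values.columns:
            res = classify_one_vs_all(X, labels, test.values.loc[selected, sid], C=svm_C)
            report[sid]["svm_ova"] = res.to_dict()

    for sid, per_method in report.items():
        for res in per_method.values():
            winner = res["winner"]
            try:
                winner = int(winner)
            except (TypeError, ValueError):
                pass
            res["coarse_period"] = coarse_period(winner)
    return report


# ---------------------------------------------------------------------------
# run configuration and the end-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    When ``expression`` is unset the run simulates its own training and
    blinded studies from ``generator``; otherwise expression/metadata
    (and test study) paths are read.  ``gmt`` enables the pathway stage.
    """

    out_dir: str = "healstage_run"
    seed: int = 0
    methods: tuple[str, ...] = ("specific", "weighted", "pca", "svm")
    level: str = "gene"  # gene | isoform | pathway
    # input paths (optional; simulation used when expression is None)
    expression: str | None = None
    metadata: str | None = None
    qvalues: str | None = None
    test_expression: str | None = None
    test_metadata: str | None = None
    sealed_labels: str | None = None
    gmt: str | None = None
    # thresholds
    min_fpkm: float = 1.0
    q_max: float | None = 0.05
    min_fold: float = 2.0
    pseudocount: float = 0.5
    r2_threshold: float = 0.95
    confidence_high: float = HIGH_CONFIDENCE_MARGIN
    confidence_medium: float = MEDIUM_CONFIDENCE_MARGIN
    n_components: int | None = None
    svm_C: float = 1.0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def validate(self) -> None:
        if self.level not in ("gene", "isoform", "pathway"):
            raise ConfigError("level must be gene, isoform or pathway")
        if self.level == "pathway" and self.gmt is None:
            raise ConfigError("pathway level requires a gmt path")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ConfigError(f"unknown method(s) {bad}")
        if not 0 < self.r2_threshold <= 1:
            raise ConfigError("r2_threshold must lie in (0, 1]")
        self.filter_spec().validate()
        self.generator.validate()

    def filter_spec(self) -> FilterSpec:
        mode = "all_significant_isoforms" if self.level == "isoform" else "all_significant_genes"
        return FilterSpec(
            mode=mode, min_fpkm=self.min_fpkm, q_max=self.q_max, min_fold=self.min_fold
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in d["generator"].items()
        }
        d["methods"] = list(self.methods)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen_raw = raw.pop("generator", {})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s) {sorted(unknown)}")
        gen_known = {f.name for f in dataclasses.fields(GeneratorConfig)}
        unknown = set(gen_raw) - gen_known
        if unknown:
            raise ConfigError(f"unknown generator key(s) {sorted(unknown)}")
        for key in ("time_points", "effect_log2fc_range", "baseline_lognorm",
                    "multi_tp_span"):
            if key in gen_raw and isinstance(gen_raw[key], list):
                gen_raw[key] = tuple(gen_raw[key])
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(generator=GeneratorConfig(**gen_raw), **raw)


def _load_or_simulate(config: RunConfig):
    if config.expression is not None:
        train = hio.read_expression(
            config.expression, metadata=config.metadata, qvalues=config.qvalues
        )
        test = None
        if config.test_expression is not None:
            test = hio.read_expression(
                config.test_expression, metadata=config.test_metadata
            )
        sealed = None
        if config.sealed_labels is not None:
            with open(config.sealed_labels) as fh:
                sealed = {
                    sid: (rec["condition"], rec["time_point_h"])
                    for sid, rec in json.load(fh).items()
                }
        return train, test, sealed

    gen = dataclasses.replace(config.generator, seed=int(config.seed))
    train, _ = generate_study(gen)
    test, truth = generate_blinded_tests(gen, list(DESIGN_TEST_LABELS), seed=int(config.seed) + 1)
    sealed = {
        sid: (row["condition"], None if pd.isna(row["time_point_h"]) else int(row["time_point_h"]))
        for sid, row in truth.sample_labels.iterrows()
    }
    return train, test, sealed


def _accuracy(report: dict, sealed: dict) -> dict:
    """Per-method exact and coarse-period accuracy against sealed labels."""
    out: dict[str, dict] = {}
    for sid, per_method in report.items():
        condition, tp = sealed[sid]
        true_label = CONTROL if condition == CONTROL else int(tp)
        for method, res in per_method.items():
            entry = out.setdefault(method, {"n": 0, "correct": 0, "coarse_correct": 0})
            entry["n"] += 1
            called = res["winner"]
            called = int(called) if called != CONTROL else called
            if called == true_label:
                entry["correct"] += 1
            if coarse_period(called) == coarse_period(true_label):
                entry["coarse_correct"] += 1
    for entry in out.values():
        entry["accuracy"] = entry["correct"] / entry["n"]
        entry["coarse_accuracy"] = entry["coarse_correct"] / entry["n"]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate/load -> QC -> profile -> classify -> report.

    Writes per-stage artifacts (every one stamped with the config hash
    and seed) under ``config.out_dir`` and returns the consolidated
    report, including per-method accuracy when sealed labels exist.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = f"config_hash={config.config_hash()} seed={config.seed}"

    logger.info("stage: load/simulate")
    train, test, sealed = _load_or_simulate(config)
    hio.write_expression(
        train, out / "training_fpkm.tsv",
        metadata=out / "training_samples.tsv",
        qvalues=out / "training_qvalues.tsv" if train.qvalues is not None else None,
        header_comment=stamp,
    )
    if test is not None:
        hio.write_expression(test, out / "test_fpkm.tsv", header_comment=stamp)
    if sealed is not None:
        with open(out / "sealed_labels.json", "w") as fh:
            json.dump(
                {"config_hash": config.config_hash(), "seed": config.seed,
                 "labels": {s: {"condition": c, "time_point_h": t} for s, (c, t) in sealed.items()}},
                fh, indent=2,
            )

    logger.info("stage: replicate QC")
    filtered, excluded = hio.filter_replicates(train, config.r2_threshold)
    agg = hio.aggregate_replicates(filtered)
    hio.write_expression(
        agg, out / "aggregated_fpkm.tsv",
        metadata=out / "aggregated_samples.tsv", header_comment=stamp,
    )

    logger.info("stage: differential profile")
    spec = config.filter_spec()
    fc = compute_fold_changes(agg, agg, pseudocount=config.pseudocount, spec=spec)
    fc.to_tsv(out / "fold_changes.tsv", header_comment=stamp)

    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "excluded_replicates": excluded,
        "n_selected_features": len(select_features(fc, spec)),
    }

    if test is not None:
        logger.info("stage: classification (%s level)", config.level)
        if config.level == "pathway":
            from .pathways import classify_at_pathway_level

            sets = hio.read_gmt(config.gmt)
            calls = {}
            for method in config.methods:
                partial = classify_at_pathway_level(
                    filtered, test, sets, method=method,
                    filter_spec=FilterSpec(min_fpkm=spec.min_fpkm, q_max=None,
                                           min_fold=spec.min_fold),
                    pseudocount=config.pseudocount,
                )
                for sid, per_method in partial.items():
                    calls.setdefault(sid, {}).update(per_method)
        else:
            calls = classify_samples(
                filtered, test, methods=config.methods, filter_spec=spec,
                pseudocount=config.pseudocount,
                confidence_margins=(config.confidence_high, config.confidence_medium),
                n_components=config.n_components, svm_C=config.svm_C,
            )
        report["calls"] = calls
        if sealed is not None:
            report["accuracy"] = _accuracy(calls, sealed)

    if config.gmt is not None and config.level != "pathway":
        logger.info("stage: pathway activation")
        from .pathways import pathway_scores, pathway_zscores, select_significant_pathways

        sets = hio.read_gmt(config.gmt)
        inj_cols = [s for s, row in agg.samples.iterrows() if row["condition"] == INJURED]
        pw = pathway_scores(agg, sets)
        inj_scores = pw.scores[inj_cols]
        inj_scores.columns = [int(agg.samples.loc[c, "time_point_h"]) for c in inj_cols]
        z = pathway_zscores(inj_scores)
        pw_study = ExpressionStudy(pw.scores, agg.samples, None)
        pw_fc = compute_fold_changes(
            pw_study, pw_study, pseudocount=config.pseudocount,
            spec=FilterSpec(min_fpkm=spec.min_fpkm, q_max=None, min_fold=spec.min_fold),
        )
        significant = select_significant_pathways(z, pw_fc, min_fold=config.min_fold)
        pw.to_tsv(out / "pathway_scores.tsv", header_comment=stamp)
        z.z.to_csv(out / "pathway_zscores.tsv", sep="\t")
        report["pathways"] = {
            "n_scored": int(pw.scores.shape[0]),
            "n_skipped": len(pw.skipped),
            "n_inert": len(z.inert),
            "significant": significant,
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
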