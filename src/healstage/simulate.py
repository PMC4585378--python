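"""Synthetic time-course FPKM studies with known ground truth.

The generator emulates the design of a murine lower-limb muscle
freeze-injury time course: injured tibialis anterior tissue profiled at
nine post-injury times (3 h to 672 h) with 2-5 biological replicates per
time point, a contralateral uninjured control for every time point, and a
small blinded test set drawn from the same expression model.

Genes come in three classes: *single-time-point responders* active at
exactly one post-injury hour, *multi-time-point responders* active over a
contiguous window of hours (which makes adjacent time points share a
fraction of their active genes, the temporal smoothness the real data
show), and *null* genes that never respond.  Baseline abundance is
log-normal across genes; injured samples multiply the baseline by
``2**effect`` at active hours.  Replicate noise is multiplicative
log-normal with a fixed coefficient of variation, chosen so replicate
pairs typically correlate with R^2 >= 0.95; optionally one "transition"
hour (the study's 168 h) gets 3x noise variance on its injured
replicates, dropping their mutual correlation toward ~0.90.

Per-gene, per-hour q-values are emitted from a two-sample t-test on
log2(FPKM+0.5) between injured and control replicates, Benjamini-Hochberg
corrected across genes, standing in for an upstream differential engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from os import PathLike
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, LabelError
from .types import BLINDED, CONTROL, DEFAULT_TIME_POINTS, INJURED, ExpressionStudy

#: Injured replicate counts per hour of the emulated training design
#: (about 31 injured samples; several hours kept only 2-3 tissues after
#: RNA quality checks).
DESIGN_INJURED_REPS: Mapping[int, int] = {
    3: 2, 10: 5, 24: 4, 48: 3, 72: 4, 168: 2, 336: 3, 504: 3, 672: 4,
}
#: Contralateral control replicates per hour (about 37 controls total).
DESIGN_CONTROL_REPS = 4

#: Blinded test-set composition of the emulated design: six uninjured
#: controls plus paired injured samples at 3 h, 10 h and 168 h.
DESIGN_TEST_LABELS: tuple[tuple[str, int | None], ...] = (
    *(((CONTROL, None),) * 6),
    (INJURED, 3), (INJURED, 3),
    (INJURED, 10), (INJURED, 10),
    (INJURED, 168), (INJURED, 168),
)


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic study generator.

    Replicate counts accept either a single integer applied to every time
    point or a mapping hour -> count; ``n_injured_reps_per_tp=None`` uses
    the emulated study design counts when the default nine time points are
    in force, else 3.
    """

    n_features: int = 2000
    time_points: tuple[int, ...] = DEFAULT_TIME_POINTS
    n_control_reps_per_tp: int | Mapping[int, int] = DESIGN_CONTROL_REPS
    n_injured_reps_per_tp: int | Mapping[int, int] | None = None
    frac_single_tp_genes: float = 0.2
    frac_multi_tp_genes: float = 0.3
    effect_log2fc_range: tuple[float, float] = (1.0, 4.0)
    #: (mu, sigma) of ln FPKM baseline across genes.
    baseline_lognorm: tuple[float, float] = (1.5, 1.5)
    replicate_noise_cv: float = 0.12
    #: Hour whose injured replicates get the transition regime (inflated
    #: noise variance plus per-replicate state mixing toward a random
    #: adjacent hour); None disables the regime.
    transition_tp: int | None = None
    transition_var_factor: float = 3.0
    #: Upper bound of the per-replicate mixing coefficient toward an
    #: adjacent hour's expression program (drawn U(0, max) per replicate);
    #: emulates tissue whose cells straddle two healing states.
    transition_mix_max: float = 0.5
    #: Window lengths (inclusive range) for multi-time-point responders.
    multi_tp_span: tuple[int, int] = (2, 4)
    pseudocount: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 1:
            raise ConfigError("n_features must be >= 1")
        tps = tuple(self.time_points)
        if any(t <= 0 for t in tps) or list(tps) != sorted(set(tps)):
            raise ConfigError("time_points must be strictly increasing and > 0")
        for name in ("frac_single_tp_genes", "frac_multi_tp_genes"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.frac_single_tp_genes + self.frac_multi_tp_genes > 1.0 + 1e-12:
            raise ConfigError("frac_single_tp_genes + frac_multi_tp_genes must be <= 1")
        lo, hi = self.effect_log2fc_range
        if lo < 0 or hi < lo:
            raise ConfigError("effect_log2fc_range must satisfy 0 <= lo <= hi")
        if self.replicate_noise_cv < 0:
            raise ConfigError("replicate_noise_cv must be >= 0")
        if self.transition_tp is not None and self.transition_tp not in tps:
            raise ConfigError("transition_tp must be one of time_points")
        if self.transition_var_factor <= 0:
            raise ConfigError("transition_var_factor must be > 0")
        if not 0.0 <= self.transition_mix_max <= 1.0:
            raise ConfigError("transition_mix_max must lie in [0, 1]")
        lo, hi = self.multi_tp_span
        if not (1 <= lo <= hi):
            raise ConfigError("multi_tp_span must satisfy 1 <= lo <= hi")

    def injured_reps(self, tp: int) -> int:
        spec = self.n_injured_reps_per_tp
        if spec is None:
            if tuple(self.time_points) == DEFAULT_TIME_POINTS:
                return DESIGN_INJURED_REPS[tp]
            return 3
        if isinstance(spec, Mapping):
            return int(spec[tp])
        return int(spec)

    def control_reps(self, tp: int) -> int:
        spec = self.n_control_reps_per_tp
        if isinstance(spec, Mapping):
            return int(spec[tp])
        return int(spec)


@dataclass
class GroundTruth:
    """What the generator actually injected, for scoring downstream calls."""

    #: per-feature response class: "single" | "multi" | "null"
    feature_class: pd.Series
    #: signed log2 effects, features x hours; 0 where inactive
    effects: pd.DataFrame
    #: per-sample true (condition, time point); the sealed record for
    #: blinded studies
    sample_labels: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def active(self) -> pd.DataFrame:
        return self.effects != 0.0

    def n_active_tps(self) -> pd.Series:
        return self.active.sum(axis=1)

    def to_dict(self) -> dict:
        return {
            "feature_class": self.feature_class.to_dict(),
            "effects": {
                f: {str(t): float(v) for t, v in row.items() if v != 0.0}
                for f, row in self.effects.iterrows()
            },
            "sample_labels": {
                sid: {
                    "condition": row["condition"],
                    "time_point_h": None
                    if pd.isna(row["time_point_h"])
                    else int(row["time_point_h"]),
                }
                for sid, row in self.sample_labels.iterrows()
            },
        }

    def to_json(self, path: str | PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def write_sealed_labels(truth: GroundTruth, path: str | PathLike) -> None:
    """Write only the withheld sample labels (the sealed blinded record)."""
    with open(path, "w") as fh:
        json.dump(truth.to_dict()["sample_labels"], fh, indent=2)


# ---------------------------------------------------------------------------
# feature-effect model (shared between training and blinded studies)
# ---------------------------------------------------------------------------

def _feature_model(config: GeneratorConfig):
    """Draw baselines, response classes and signed effects from config.seed.

    Both :func:`generate_study` and :func:`generate_blinded_tests` derive
    this model identically, so a blinded study shares the training study's
    gene effects while its replicate noise stays independent.
    """
    rng = np.random.default_rng([int(config.seed), 7001])
    n = config.n_features
    tps = list(config.time_points)
    features = [f"g{i:05d}" for i in range(n)]

    n_single = int(round(config.frac_single_tp_genes * n))
    n_multi = int(round(config.frac_multi_tp_genes * n))
    classes = np.array(["null"] * n, dtype=object)
    classes[:n_single] = "single"
    classes[n_single : n_single + n_multi] = "multi"

    mu, sigma = config.baseline_lognorm
    baselines = rng.lognormal(mean=mu, sigma=sigma, size=n)

    lo, hi = config.effect_log2fc_range
    effects = np.zeros((n, len(tps)))
    signs = rng.choice([-1.0, 1.0], size=n)
    for i in range(n_single):
        j = rng.integers(len(tps))
        effects[i, j] = signs[i] * rng.uniform(lo, hi)
    span_lo, span_hi = config.multi_tp_span
    for i in range(n_single, n_single + n_multi):
        width = int(rng.integers(span_lo, span_hi + 1))
        width = min(width, len(tps))
        start = int(rng.integers(0, len(tps) - width + 1))
        effects[i, start : start + width] = signs[i] * rng.uniform(lo, hi, size=width)

    return (
        pd.Index(features, name="feature_id"),
        pd.Series(classes, index=features, name="feature_class"),
        pd.Series(baselines, index=features, name="baseline_fpkm"),
        pd.DataFrame(effects, index=features, columns=tps),
    )


def _noise_sigma(config: GeneratorConfig, condition: str, tp: int | None) -> float:
    """ln-scale noise s.d. for one sample; E[noise factor] = 1."""
    sigma2 = np.log1p(config.replicate_noise_cv**2)
    if (
        condition == INJURED
        and config.transition_tp is not None
        and tp == config.transition_tp
    ):
        sigma2 *= config.transition_var_factor
    return float(np.sqrt(sigma2))


def _draw_sample(rng, config, baselines, effects, condition, tp) -> np.ndarray:
    mean = baselines.to_numpy().copy()
    if condition == INJURED and tp is not None:
        eff = effects[tp].to_numpy()
        if config.transition_tp is not None and tp == config.transition_tp:
            # transition-state heterogeneity: this replicate's tissue is a
            # mixture of the transition hour's program and a neighbor's
            tps = list(effects.columns)
            i = tps.index(tp)
            neighbors = [tps[j] for j in (i - 1, i + 1) if 0 <= j < len(tps)]
            nb = neighbors[int(rng.integers(len(neighbors)))]
            lam = rng.uniform(0.0, config.transition_mix_max)
            eff = (1.0 - lam) * eff + lam * effects[nb].to_numpy()
        mean = mean * np.exp2(eff)
    sigma = _noise_sigma(config, condition, tp)
    noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=mean.size)
    return mean * noise


def _qvalues(values: pd.DataFrame, meta: pd.DataFrame, tps, pseudocount) -> pd.DataFrame:
    """Per-gene, per-hour BH-adjusted t-test q-values (injured vs control)."""
    logv = np.log2(values.to_numpy() + pseudocount)
    out = {}
    for tp in tps:
        inj = (meta["condition"] == INJURED) & (meta["time_point_h"] == tp)
        ctl = (meta["condition"] == CONTROL) & (meta["time_point_h"] == tp)
        with np.errstate(divide="ignore", invalid="ignore"):
            _, p = stats.ttest_ind(
                logv[:, inj.to_numpy()], logv[:, ctl.to_numpy()], axis=1
            )
        p = np.nan_to_num(p, nan=1.0)
        out[tp] = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(out, index=values.index)


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def generate_study(config: GeneratorConfig) -> tuple[ExpressionStudy, GroundTruth]:
    """Generate a replicate-level training study with ground truth.

    Deterministic for a fixed ``config.seed``.  Injured replicates at a
    gene's active hours have expected FPKM = baseline * 2**effect;
    controls are time-point-labelled draws from the same baseline.
    """
    config.validate()
    features, classes, baselines, effects = _feature_model(config)
    rng = np.random.default_rng([int(config.seed), 101])
    tps = list(config.time_points)

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for tp in tps:
        for condition, n_reps in (
            (CONTROL, config.control_reps(tp)),
            (INJURED, config.injured_reps(tp)),
        ):
            for rep in range(1, n_reps + 1):
                sid = f"{condition}_{tp}h_r{rep}"
                cols[sid] = _draw_sample(rng, config, baselines, effects, condition, tp)
                meta_rows.append((sid, condition, tp, rep))

    values = pd.DataFrame(cols, index=features)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "condition", "time_point_h", "replicate"]
    ).set_index("sample_id")
    meta["time_point_h"] = meta["time_point_h"].astype("Int64")
    meta["replicate"] = meta["replicate"].astype("Int64")
    q = _qvalues(values, meta, tps, config.pseudocount)
    study = ExpressionStudy(values, meta, q)

    labels = meta[["condition", "time_point_h"]].copy()
    truth = GroundTruth(feature_class=classes, effects=effects, sample_labels=labels)
    return study, truth


def generate_blinded_tests(
    config: GeneratorConfig,
    labels: Sequence[tuple[str, int | None]],
    seed: int,
) -> tuple[ExpressionStudy, GroundTruth]:
    """Generate blinded test samples from the same feature-effect model.

    One sample per requested ``(condition, time point)`` label, with
    replicate noise driven by ``seed`` (independent of the training
    study's noise).  The returned study's metadata carries only the
    ``blinded`` condition; true labels live in the ground truth's sealed
    ``sample_labels`` record.
    """
    config.validate()
    tps = set(config.time_points)
    for condition, tp in labels:
        if condition == INJURED:
            if tp not in tps:
                raise LabelError(f"injured hour {tp} not in the study design")
        elif condition == CONTROL:
            if tp is not None and tp not in tps:
                raise LabelError(f"control hour {tp} not in the study design")
        else:
            raise LabelError(f"unknown condition {condition!r}")

    features, classes, baselines, effects = _feature_model(config)
    rng = np.random.default_rng([int(config.seed), int(seed), 202])

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    truth_rows = []
    for i, (condition, tp) in enumerate(labels, start=1):
        sid = f"test_{i:02d}"
        cols[sid] = _draw_sample(rng, config, baselines, effects, condition, tp)
        meta_rows.append((sid, BLINDED, pd.NA, pd.NA))
        truth_rows.append((sid, condition, tp))

    values = pd.DataFrame(cols, index=features, dtype=float)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "condition", "time_point_h", "replicate"]
    ).set_index("sample_id")
    meta["time_point_h"] = meta["time_point_h"].astype("Int64")
    meta["replicate"] = meta["replicate"].astype("Int64")
    sealed = pd.DataFrame(
        truth_rows, columns=["sample_id", "condition", "time_point_h"]
    ).set_index("sample_id")
    sealed["time_point_h"] = sealed["time_point_h"].astype("Int64")
    study = ExpressionStudy(values, meta, None)
    truth = GroundTruth(feature_class=classes, effects=effects, sample_labels=sealed)
    return study, truth
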