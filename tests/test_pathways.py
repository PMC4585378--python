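"""Pathway activation scores, Z-score significance, and pathway-level
classification."""

import numpy as np
import pandas as pd
import pytest

import healstage as hs
from healstage.errors import ConfigError
from healstage.pathways import pathway_study, pathway_zscores
from healstage.types import GeneSetCollection

from conftest import TIME_POINTS, make_fc


def collection(sets: dict) -> GeneSetCollection:
    coll = GeneSetCollection()
    for name, members in sets.items():
        coll.add(name, "synthetic gene set", members)
    return coll


def study_of(values: pd.DataFrame, condition="injured") -> hs.ExpressionStudy:
    meta = pd.DataFrame(
        {
            "condition": condition,
            "time_point_h": pd.array([3] * values.shape[1], dtype="Int64"),
            "replicate": pd.array(range(1, values.shape[1] + 1), dtype="Int64"),
        },
        index=values.columns,
    )
    return hs.ExpressionStudy(values, meta)


class TestPathwayScores:
    def test_mean_of_member_fpkms(self):
        values = pd.DataFrame({"s1": [2.0, 4.0, 100.0]}, index=["g1", "g2", "g3"])
        pw = hs.pathway_scores(study_of(values), collection({"P1": ["g1", "g2"]}))
        assert pw.scores.loc["P1", "s1"] == pytest.approx(3.0)
        assert pw.coverage["P1"] == 2

    def test_pathway_without_members_skipped(self, caplog):
        values = pd.DataFrame({"s1": [1.0]}, index=["g1"])
        with caplog.at_level("WARNING"):
            pw = hs.pathway_scores(study_of(values), collection({"P1": ["absent"]}))
        assert pw.skipped == ["P1"]
        assert "P1" in caplog.text

    def test_absent_members_excluded_from_mean(self):
        values = pd.DataFrame({"s1": [2.0, 6.0]}, index=["g1", "g2"])
        pw = hs.pathway_scores(
            study_of(values), collection({"P1": ["g1", "g2", "missing"]})
        )
        assert pw.scores.loc["P1", "s1"] == pytest.approx(4.0)
        assert pw.coverage["P1"] == 2

    def test_matches_member_loop_oracle(self, rng):
        genes = [f"g{i}" for i in range(60)]
        values = pd.DataFrame(
            rng.lognormal(1, 1, (60, 4)), index=genes,
            columns=[f"s{j}" for j in range(4)],
        )
        sets = {
            f"P{k}": list(rng.choice(genes, rng.integers(2, 12), replace=False))
            for k in range(50)
        }
        pw = hs.pathway_scores(study_of(values), collection(sets))
        for name, members in sets.items():
            for col in values.columns:
                expect = np.mean([values.loc[g, col] for g in members])
                assert pw.scores.loc[name, col] == pytest.approx(expect)

    def test_duplicate_members_do_not_bias_the_mean(self):
        values = pd.DataFrame({"s1": [2.0, 10.0]}, index=["g1", "g2"])
        coll = collection({"P1": ["g1", "g1", "g2"]})  # deduped on ingest
        pw = hs.pathway_scores(study_of(values), coll)
        assert pw.scores.loc["P1", "s1"] == pytest.approx(6.0)


class TestPathwayZScores:
    def test_hand_computed_example(self):
        scores = pd.DataFrame([[10.0] + [1.0] * 8], index=["P1"], columns=TIME_POINTS)
        z = pathway_zscores(scores)
        assert z.z.loc["P1", 3] == pytest.approx(8 / 3)  # (10-2)/3

    def test_constant_pathway_flagged_inert(self):
        scores = pd.DataFrame([[5.0] * 9], index=["P1"], columns=TIME_POINTS)
        z = pathway_zscores(scores)
        assert z.inert == ["P1"]
        assert not z.significant.loc["P1"].any()

    def test_flags_match_brute_force_threshold(self, rng):
        scores = pd.DataFrame(
            rng.lognormal(2, 1, (40, 9)), columns=TIME_POINTS,
            index=[f"P{k}" for k in range(40)],
        )
        z = pathway_zscores(scores)
        for p in scores.index:
            row = scores.loc[p].to_numpy()
            mu, sd = row.mean(), row.std(ddof=1)
            for t in TIME_POINTS:
                expect = abs((scores.loc[p, t] - mu) / sd) > 2
                assert z.significant.loc[p, t] == expect

    def test_needs_two_time_points(self):
        with pytest.raises(ConfigError):
            pathway_zscores(pd.DataFrame({3: [1.0]}, index=["P1"]))


class TestSelectSignificantPathways:
    def build(self, zrow, fcrow):
        z = pathway_zscores(
            pd.DataFrame([zrow], index=["P1"], columns=TIME_POINTS)
        )
        fc = make_fc(pd.DataFrame([fcrow], index=["P1"], columns=TIME_POINTS))
        return z, fc

    def test_high_z_but_small_fold_excluded(self):
        zrow = [10.0] + [1.0] * 8  # strong excursion at 3 h
        fcrow = [np.log2(1.5)] * 9  # never two-fold
        z, fc = self.build(zrow, fcrow)
        assert hs.select_significant_pathways(z, fc) == []

    def test_z_and_fold_together_included(self):
        zrow = [10.0] + [1.0] * 8
        fcrow = [2.0] + [0.0] * 8  # four-fold at the same hour
        z, fc = self.build(zrow, fcrow)
        assert hs.select_significant_pathways(z, fc) == ["P1"]

    def test_matches_clause_by_clause_oracle(self, rng):
        names = [f"P{k}" for k in range(60)]
        zmat = pd.DataFrame(rng.lognormal(2, 1, (60, 9)), index=names, columns=TIME_POINTS)
        fcmat = pd.DataFrame(rng.normal(0, 1.5, (60, 9)), index=names, columns=TIME_POINTS)
        z = pathway_zscores(zmat)
        fc = make_fc(fcmat)
        got = set(hs.select_significant_pathways(z, fc))
        expect = set()
        for p in names:
            for t in TIME_POINTS:
                if z.significant.loc[p, t] and abs(fcmat.loc[p, t]) >= 1.0:
                    expect.add(p)
                    break
        assert got == expect

    def test_null_pathways_rarely_selected(self, small_study, rng):
        """Pathways of null genes only are never enriched beyond the
        nominal threshold rate."""
        study, truth = small_study
        null_genes = list(truth.feature_class[truth.feature_class == "null"].index)
        sets = {
            f"N{k}": list(rng.choice(null_genes, 15, replace=False))
            for k in range(40)
        }
        agg = hs.aggregate_replicates(study)
        pw = hs.pathway_scores(agg, collection(sets))
        inj = [s for s, row in agg.samples.iterrows() if row["condition"] == "injured"]
        scores = pw.scores[inj]
        scores.columns = [int(agg.samples.loc[c, "time_point_h"]) for c in inj]
        z = pathway_zscores(scores)
        pw_study = hs.ExpressionStudy(pw.scores, agg.samples, None)
        fc = hs.compute_fold_changes(
            pw_study, pw_study, spec=hs.FilterSpec(min_fpkm=0.5, q_max=None)
        )
        selected = hs.select_significant_pathways(z, fc)
        assert len(selected) / 40 <= 0.05


@pytest.fixture(scope="module")
def pathway_sets(small_study):
    study, truth = small_study
    rng = np.random.default_rng(7)
    responders = list(truth.feature_class[truth.feature_class != "null"].index)
    sets = {
        f"P{k}": list(rng.choice(responders, 10, replace=False)) for k in range(60)
    }
    return collection(sets)


class TestClassifyAtPathwayLevel:
    def test_weighted_method_recovers_hour_and_period(
        self, small_study, blinded, pathway_sets
    ):
        study, _ = small_study
        test, truth = blinded
        report = hs.classify_at_pathway_level(study, test, pathway_sets, method="weighted")
        n_exact = n_period = 0
        for sid, per in report.items():
            row = truth.sample_labels.loc[sid]
            t = "control" if row["condition"] == "control" else int(row["time_point_h"])
            res = per["weighted"]
            w = res["winner"]
            w = int(w) if w != "control" else w
            n_exact += w == t
            n_period += res["coarse_period"] == hs.coarse_period(t)
        assert n_exact >= 9  # pathway level is noisier than gene level
        assert n_period >= n_exact  # adjacent confusions stay in-period

    def test_control_sample_called_control(self, small_study, blinded, pathway_sets):
        study, _ = small_study
        test, truth = blinded
        controls = truth.sample_labels[truth.sample_labels["condition"] == "control"]
        report = hs.classify_at_pathway_level(
            study, test.subset_samples(list(controls.index)[:2]),
            pathway_sets, method="specific",
        )
        for per in report.values():
            assert per["specific"]["winner"] == "control"
            assert per["specific"]["coarse_period"] == "control"

    def test_adjacent_confusion_maps_to_same_period(self):
        assert hs.coarse_period(10) == hs.coarse_period(24) == "early"
        assert hs.coarse_period(48) == hs.coarse_period(168) == "middle"
        assert hs.coarse_period(336) == hs.coarse_period(672) == "late"
        assert hs.coarse_period("control") == "control"


def test_pathway_study_reindexes_features(small_study):
    study, _ = small_study
    rng = np.random.default_rng(3)
    sets = collection({
        f"P{k}": list(rng.choice(list(study.features), 8, replace=False))
        for k in range(10)
    })
    pw = pathway_study(study, sets)
    assert list(pw.features) == [f"P{k}" for k in range(10)]
    assert pw.n_samples == study.n_samples
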