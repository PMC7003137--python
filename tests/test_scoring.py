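"""Scoring and evaluation tests: the concentration-weighted TdP score,
classification, confusion identities, the cap and subset experiments and
the score-DAPD correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from torsim import scoring
from torsim.pharm import ConcentrationPlan, TrialResult


def make_result(compound, n_ra, n_models=10, multiples=(1, 3, 10, 30, 100),
                detail=None):
    plan = ConcentrationPlan(multiples)
    score = scoring.tdp_score(n_ra, n_models, plan)
    return TrialResult(
        compound=compound, dataset_tag="t", multiples=plan.multiples,
        n_ra=tuple(n_ra), n_ra_corrected=tuple(n_ra), n_models=n_models,
        tdp_score=score, tdp_score_corrected=score, risky=score > 0,
        detail=detail if detail is not None else pd.DataFrame())


class TestTdpScore:
    def test_all_models_all_concentrations_scores_exactly_one(self):
        assert scoring.tdp_score([107] * 5, 107) == 1.0

    def test_no_ra_scores_exactly_zero(self):
        assert scoring.tdp_score([0] * 5, 107) == 0.0

    def test_ra_only_at_hundredfold_hand_derived(self):
        # weights (1, 1/3, 1/10, 1/30, 1/100), sum 443/300:
        # (107/100) / (107 * 443/300) = 3/443
        assert scoring.tdp_score([0, 0, 0, 0, 107], 107) == pytest.approx(
            3 / 443, rel=1e-12)

    def test_count_above_population_rejected(self):
        with pytest.raises(ValueError):
            scoring.tdp_score([108, 0, 0, 0, 0], 107)
        with pytest.raises(ValueError):
            scoring.tdp_score([1, 1, 1], 10)

    @given(st.integers(min_value=0, max_value=4),
           st.integers(min_value=1, max_value=20))
    def test_monotone_in_every_count(self, pos, n):
        counts = [n // 2] * 5
        base = scoring.tdp_score(counts, n)
        bumped = list(counts)
        if bumped[pos] < n:
            bumped[pos] += 1
            assert scoring.tdp_score(bumped, n) > base

    def test_low_concentration_dominates_weighting(self):
        n = 20
        at_1x = scoring.tdp_score([n, 0, 0, 0, 0], n)
        at_100x = scoring.tdp_score([0, 0, 0, 0, n], n)
        assert at_1x > at_100x

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            counts = rng.integers(0, n + 1, size=5)
            s = scoring.tdp_score(counts, n)
            assert 0.0 <= s <= 1.0


class TestClassify:
    def test_zero_is_safe(self):
        assert scoring.classify(0.0) == "safe"

    def test_tiny_positive_score_is_risky(self):
        assert scoring.classify(6e-5) == "risky"

    def test_one_is_risky(self):
        assert scoring.classify(1.0) == "risky"

    def test_risky_iff_any_ra(self):
        assert make_result("a", [0, 0, 0, 0, 1]).risky
        assert not make_result("b", [0] * 5).risky


class TestConfusion:
    def test_dataset_style_counts_reproduce_printed_percentages(self):
        cm = scoring.ConfusionMetrics(tp=17, fp=2, fn=3, tn=8)
        assert (cm.sensitivity_pct, cm.specificity_pct, cm.accuracy_pct) == \
            (85, 80, 83)
        cm2 = scoring.ConfusionMetrics(tp=25, fp=4, fn=7, tn=19)
        assert (cm2.sensitivity_pct, cm2.specificity_pct, cm2.accuracy_pct) == \
            (78, 83, 80)

    def test_perfect_predictions(self):
        cm = scoring.confusion({"a": True, "b": False},
                               {"a": True, "b": False})
        assert cm.sensitivity_pct == cm.specificity_pct == cm.accuracy_pct == 100

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError, match="b"):
            scoring.confusion({"a": True, "b": False}, {"a": True})

    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=1, max_size=30))
    def test_identities_against_independent_arithmetic(self, pairs):
        preds = {f"c{i}": p for i, (p, _) in enumerate(pairs)}
        labels = {f"c{i}": t for i, (_, t) in enumerate(pairs)}
        cm = scoring.confusion(preds, labels)
        tp = sum(p and t for p, t in pairs)
        tn = sum((not p) and (not t) for p, t in pairs)
        fp = sum(p and not t for p, t in pairs)
        fn = sum((not p) and t for p, t in pairs)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (tp, tn, fp, fn)
        assert cm.accuracy == pytest.approx((tp + tn) / len(pairs))
        if tp + fn:
            assert cm.sensitivity == pytest.approx(tp / (tp + fn))
        if tn + fp:
            assert cm.specificity == pytest.approx(tn / (tn + fp))


class TestConcentrationCap:
    def test_cap_at_maximum_is_identity(self):
        r = make_result("a", [1, 2, 3, 4, 5])
        assert scoring.capped_score(r, 100) == r.tdp_score

    def test_ra_only_at_hundredfold_reclassified_safe_under_cap_30(self):
        r = make_result("late", [0, 0, 0, 0, 8])
        scores, _ = scoring.concentration_cap_experiment([r], cap=30)
        assert scores["late"] == 0.0

    def test_renormalization_keeps_full_ra_compound_at_one(self):
        r = make_result("full", [10, 10, 10, 10, 10])
        assert scoring.capped_score(r, 30) == 1.0

    def test_cap_below_smallest_multiple_rejected(self):
        with pytest.raises(ValueError):
            scoring.capped_score(make_result("a", [0] * 5), 0.5)

    def test_risky_set_under_cap_is_subset(self):
        results = [make_result("a", [1, 1, 1, 1, 1]),
                   make_result("b", [0, 0, 0, 0, 2]),
                   make_result("c", [0] * 5)]
        risky30 = {r.compound for r in results
                   if scoring.capped_score(r, 30) > 0}
        risky100 = {r.compound for r in results
                    if scoring.capped_score(r, 100) > 0}
        assert risky30 <= risky100

    def test_confusion_attached_when_labels_given(self):
        results = [make_result("a", [1] * 5), make_result("b", [0] * 5)]
        _, cm = scoring.concentration_cap_experiment(
            results, 30, labels={"a": True, "b": False})
        assert cm.tp == 1 and cm.tn == 1


class TestScoreApdCorrelation:
    @staticmethod
    def detail_frame(apd_by_model, multiple=1.0):
        rows = [{"model_id": m, "multiple": multiple, "ok": True, "ra": False,
                 "apd90_ms": apd} for m, apd in apd_by_model.items()]
        return pd.DataFrame(rows)

    @staticmethod
    def control_frame(apd_by_model):
        return pd.DataFrame([{"model_id": m, "apd90_ms": a,
                              "has_ead": False, "has_rf": False}
                             for m, a in apd_by_model.items()])

    def test_exact_linear_relation_gives_r_squared_one(self):
        control = self.control_frame({"m1": 250.0, "m2": 260.0})
        results = []
        for i, s in enumerate([0.0, 0.2, 0.4, 0.8]):
            det = self.detail_frame({"m1": 250.0 + 100 * s,
                                     "m2": 260.0 + 100 * s})
            r = make_result(f"d{i}", [0, 0, 0, 0, 0], detail=det)
            r.tdp_score = s  # impose the linear score directly
            results.append(r)
        r2, table = scoring.score_apd_correlation(results, control)
        assert r2 == pytest.approx(1.0)
        assert len(table) == 4

    def test_zero_score_variance_reports_absent(self):
        control = self.control_frame({"m1": 250.0})
        results = [make_result(f"d{i}", [0] * 5,
                               detail=self.detail_frame({"m1": 250.0 + i}))
                   for i in range(3)]
        r2, _ = scoring.score_apd_correlation(results, control)
        assert r2 is None

    def test_fewer_than_three_compounds_rejected(self):
        control = self.control_frame({"m1": 250.0})
        results = [make_result("d", [0] * 5,
                               detail=self.detail_frame({"m1": 250.0}))]
        with pytest.raises(ValueError):
            scoring.score_apd_correlation(results * 2, control)


class TestChannelSubsetExperiment:
    def test_pure_ikr_drug_scores_identically_and_inactive_scores_zero(
            self, fixture_population, fast_protocol):
        from torsim.pharm import DrugProfile
        pure = DrugProfile(compound_name="pure", eftpc_max=1.0,
                           channels={"IKr": (0.05, 1.0)})
        inert = DrugProfile(compound_name="inert", eftpc_max=1.0,
                            channels={"IKr": (1e5, 1.0)})
        one_member = list(fixture_population)[:1]
        out = scoring.channel_subset_experiment(
            [pure, inert], one_member, ["ALL7", "HERG_ONLY"],
            plan=ConcentrationPlan((1.0, 100.0)), protocol=fast_protocol)
        table = out["scores"]
        assert table.loc["pure", "ALL7"] == table.loc["pure", "HERG_ONLY"]
        assert table.loc["inert", "ALL7"] == 0.0
        assert table.loc["inert", "HERG_ONLY"] == 0.0
        results, cm = out["ALL7"]
        assert cm is None and len(results) == 2


class TestPlotFloor:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 1e-16), (0.78, 0.78), (1e-20, 1e-16), (1.0, 1.0)])
    def test_floor(self, x, expected):
        assert scoring.score_floor_for_plot(x) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            scoring.score_floor_for_plot(-0.1)


class TestSummary:
    def test_ranked_by_score(self):
        results = [make_result("low", [0, 0, 0, 0, 1]),
                   make_result("high", [5] * 5, n_models=5),
                   make_result("none", [0] * 5)]
        frame = scoring.summary_frame(results)
        assert list(frame.compound) == ["high", "low", "none"]
        assert frame.risky.tolist() == [True, True, False]
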