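import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmus.accuracy import (
    AucMethod,
    Proportion,
    auc_binary,
    auc_binormal,
    auc_empirical,
    cohort_report,
    evaluate_rule,
    pool_rates,
    sensitivity_by_group,
)
from qmus.cohort import CohortTable, Group, MuscleId
from qmus.rules import AbnormalityProfile

from conftest import make_record


def brute_force_auc(scores, labels):
    """Exhaustive pair-counting oracle: wins 1, ties 1/2, losses 0."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


class TestProportion:
    def test_counts_and_percent(self):
        p = Proportion(33, 36)
        assert p.value == pytest.approx(33 / 36)
        assert p.percent == 92

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            Proportion(5, 3)


class TestSensitivityByGroup:
    def test_perfect_separation(self):
        pairs = [(Group.ALS, True)] * 10 + [(Group.CONTROL, False)] * 10
        rates = sensitivity_by_group(pairs)
        assert rates[Group.ALS].value == 1.0
        assert rates[Group.CONTROL].value == 0.0  # false-positive rate

    def test_pnp_33_of_36_rounds_to_92(self):
        pairs = [(Group.PNP, True)] * 33 + [(Group.PNP, False)] * 3
        rates = sensitivity_by_group(pairs)
        assert rates[Group.PNP].percent == 92

    def test_all_missing_group_omitted_with_warning(self):
        pairs = [(Group.SMA, None), (Group.ALS, True)]
        with pytest.warns(UserWarning, match="SMA"):
            rates = sensitivity_by_group(pairs)
        assert Group.SMA not in rates


class TestAucBinary:
    def test_perfect(self):
        assert auc_binary(1.0, 1.0) == 1.0

    def test_published_relaxed_rule(self):
        # pooled sensitivity of the published per-group rates vs 85% specificity
        se = pool_rates([100, 92, 93, 100], [22, 36, 91, 31]) / 100
        assert se == pytest.approx(0.94861, abs=1e-4)
        assert round(auc_binary(se, 0.85), 2) == 0.90

    def test_published_proximal_fasciculation_rule(self):
        sp = 1 - pool_rates([2, 0, 3, 16], [65, 22, 36, 31]) / 100
        assert sp == pytest.approx(0.95234, abs=1e-4)
        assert round(auc_binary(0.78, sp), 2) == 0.87

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            auc_binary(1.2, 0.5)


class TestAucEmpirical:
    def test_perfect_separation(self):
        assert auc_empirical([1, 2, 9, 10], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auc_empirical([3.0] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_hand_computed_four_pairs(self):
        # cases {3,5} vs controls {1,4}: wins (3>1),(5>1),(5>4) -> 3/4
        assert auc_empirical([3, 5, 1, 4], [1, 1, 0, 0]) == 0.75

    def test_no_orientation_flip(self):
        assert auc_empirical([1, 2, 9, 10], [1, 1, 0, 0]) == 0.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            auc_empirical([1, 2], [1, 1])


class TestAucBinormal:
    def test_equal_means_is_half(self):
        assert auc_binormal(1.0, 0.5, 1.0, 0.7) == pytest.approx(0.5)

    def test_published_pnp_vs_myo_differential(self):
        assert round(auc_binormal(2.06, 0.63, 0.88, 1.07), 2) == 0.83

    def test_degenerate_sd_limit_approaches_one(self):
        assert auc_binormal(2.0, 1e-9, 1.0, 1e-9) == pytest.approx(1.0)

    def test_non_positive_sd_rejected(self):
        with pytest.raises(ValueError):
            auc_binormal(1.0, 0.0, 0.0, 1.0)


def _bool_profiles(spec):
    """spec: list of (group, n, verdict). Returns (cohort, profiles)."""
    records, profiles = [], []
    i = 0
    for group, n, verdict in spec:
        for _ in range(n):
            i += 1
            sid = f"S{i}"
            duration = None if group is Group.CONTROL else 1.0
            records.append(make_record(sid, group, disease_duration=duration))
            profiles.append(
                AbnormalityProfile(subject_id=sid, relaxed_positive=verdict)
            )
    return CohortTable(records=records), profiles


class TestEvaluateRule:
    def test_binary_rule_reproducing_published_rates(self):
        cohort, profiles = _bool_profiles(
            [
                (Group.MYO, 22, True),
                (Group.PNP, 33, True),
                (Group.PNP, 3, False),
                (Group.ALS, 85, True),
                (Group.ALS, 6, False),
                (Group.SMA, 31, True),
                (Group.CONTROL, 10, True),
                (Group.CONTROL, 55, False),
            ]
        )
        result = evaluate_rule(
            cohort,
            profiles,
            "relaxed_positive",
            positive_groups=[Group.MYO, Group.PNP, Group.ALS, Group.SMA],
            negative_groups=[Group.CONTROL],
        )
        assert result.auc_method is AucMethod.BINARY_IDENTITY
        assert result.per_group_sensitivity[Group.PNP].percent == 92
        assert result.per_group_sensitivity[Group.ALS].percent == 93
        assert result.control_specificity.percent == 85
        assert round(result.auc, 2) == 0.90

    def test_pooled_equals_total_positives_over_total_cases(self):
        cohort, profiles = _bool_profiles(
            [
                (Group.MYO, 5, True),
                (Group.ALS, 2, True),
                (Group.ALS, 8, False),
                (Group.CONTROL, 4, False),
            ]
        )
        result = evaluate_rule(
            cohort, profiles, "relaxed_positive",
            [Group.MYO, Group.ALS], [Group.CONTROL],
        )
        assert result.pooled_sensitivity.numerator == 7
        assert result.pooled_sensitivity.denominator == 15

    def test_numeric_marker_uses_empirical_rank(self):
        records, profiles = [], []
        for i, (group, score) in enumerate(
            [(Group.PNP, 2.1), (Group.PNP, 1.9), (Group.MYO, 0.9), (Group.MYO, 2.0)]
        ):
            sid = f"N{i}"
            records.append(make_record(sid, group, disease_duration=1.0))
            profiles.append(
                AbnormalityProfile(subject_id=sid, biceps_minus_edb_cm=score)
            )
        result = evaluate_rule(
            CohortTable(records=records), profiles, "biceps_minus_edb_cm",
            [Group.PNP], [Group.MYO],
        )
        assert result.auc_method is AucMethod.EMPIRICAL_RANK
        assert result.auc == brute_force_auc([2.1, 1.9, 0.9, 2.0], [1, 1, 0, 0])

    def test_overlapping_classes_rejected(self):
        cohort, profiles = _bool_profiles([(Group.ALS, 2, True), (Group.CONTROL, 2, False)])
        with pytest.raises(ValueError, match="overlap"):
            evaluate_rule(cohort, profiles, "relaxed_positive",
                          [Group.ALS], [Group.ALS, Group.CONTROL])

    def test_empty_positive_class_rejected(self):
        cohort, profiles = _bool_profiles([(Group.CONTROL, 3, False)])
        with pytest.raises(ValueError):
            evaluate_rule(cohort, profiles, "relaxed_positive",
                          [Group.ALS], [Group.CONTROL])


class TestCohortReport:
    def test_controls_only_degrades_to_specificity(self):
        cohort, profiles = _bool_profiles([(Group.CONTROL, 10, False)])
        with pytest.warns(UserWarning):
            report = cohort_report(cohort, profiles)
        rule = report["rules"]["relaxed_positive"]
        assert "warning" in rule
        assert rule["control_specificity"]["value"] == 1.0
        assert "no patient" in report["warning"]


class TestProperties:
    @settings(max_examples=200, deadline=None)
    @given(
        scores=st.lists(
            st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=2, max_size=12
        ),
        data=st.data(),
    )
    def test_empirical_matches_brute_force(self, scores, data):
        n = len(scores)
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < n
            )
        )
        assert auc_empirical(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels), abs=1e-12
        )

    @settings(max_examples=200, deadline=None)
    @given(data=st.data())
    def test_binary_scores_reduce_to_se_sp_identity(self, data):
        n = data.draw(st.integers(min_value=4, max_value=30))
        labels = data.draw(
            st.lists(st.booleans(), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < n
            )
        )
        verdicts = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        scores = [float(v) for v in verdicts]
        n_pos = sum(labels)
        n_neg = n - n_pos
        se = sum(1 for y, v in zip(labels, verdicts) if y and v) / n_pos
        sp = sum(1 for y, v in zip(labels, verdicts) if not y and not v) / n_neg
        assert auc_empirical(scores, labels) == pytest.approx(
            auc_binary(se, sp), abs=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(
        mu_a=st.floats(-5, 5),
        mu_b=st.floats(-5, 5),
        sd_a=st.floats(0.01, 5),
        sd_b=st.floats(0.01, 5),
    )
    def test_binormal_label_swap_symmetry(self, mu_a, mu_b, sd_a, sd_b):
        forward = auc_binormal(mu_a, sd_a, mu_b, sd_b)
        backward = auc_binormal(mu_b, sd_b, mu_a, sd_a)
        assert forward == pytest.approx(1.0 - backward, abs=1e-12)
        assert 0.0 <= forward <= 1.0

    @settings(max_examples=50, deadline=None)
    @given(
        rates=st.lists(st.floats(0, 100), min_size=2, max_size=5),
        data=st.data(),
    )
    def test_pooling_is_order_invariant(self, rates, data):
        weights = data.draw(
            st.lists(
                st.integers(min_value=1, max_value=100),
                min_size=len(rates),
                max_size=len(rates),
            )
        )
        order = data.draw(st.permutations(list(range(len(rates)))))
        pooled = pool_rates(rates, weights)
        shuffled = pool_rates([rates[i] for i in order], [weights[i] for i in order])
        assert pooled == pytest.approx(shuffled, abs=1e-9)
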