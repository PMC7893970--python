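import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fancfid.errors import ValidationError
from fancfid.fidelity import (
    Composition,
    Stratum,
    cohort_fidelity,
    content_weight,
    coverage_indicator,
    fidelity_frame,
    frequency_weight,
    woman_fidelity,
)
from fancfid.records import CohortTable, Provider

from conftest import make_checklist, make_cluster, make_woman


class TestComponents:
    @pytest.mark.parametrize("visits,expected", [(0, 0), (1, 1), (7, 1)])
    def test_coverage_indicator(self, visits, expected):
        assert coverage_indicator(make_woman("w", n_visits=visits)) == expected

    @pytest.mark.parametrize(
        "visits,weight", [(0, 0.0), (1, 0.25), (2, 0.5), (3, 0.75), (4, 1.0), (6, 1.0)]
    )
    def test_frequency_weight_quarters_capped(self, visits, weight):
        assert frequency_weight(visits) == weight

    def test_frequency_weight_rejects_negative(self):
        with pytest.raises(ValueError):
            frequency_weight(-1)

    @pytest.mark.parametrize("k,expected", [(0, 0.0), (9, 9 / 17), (17, 1.0)])
    def test_content_weight_seventeenths(self, k, expected):
        assert content_weight(make_checklist(k)) == pytest.approx(expected)


class TestWomanFidelity:
    def test_non_attender_scores_zero_under_both(self):
        w = make_woman("w", n_visits=0)
        for comp in Composition:
            c = woman_fidelity(w, comp)
            assert c.fidelity == 0.0
            assert c.coverage == c.frequency_weight == c.content_weight == 0

    def test_full_adherence_scores_one_under_both(self):
        w = make_woman("w", n_visits=4, n_contents=17)
        for comp in Composition:
            assert woman_fidelity(w, comp).fidelity == 1.0

    def test_product_example_two_visits_eight_contents(self):
        # 1 x (2/4) x (8/17) = 4/17
        w = make_woman("w", n_visits=2, n_contents=8)
        assert woman_fidelity(w).fidelity == pytest.approx(4 / 17)

    @given(visits=st.integers(0, 10), contents=st.integers(0, 17))
    @settings(max_examples=200, derandomize=True)
    def test_laws_on_random_records(self, visits, contents):
        w = make_woman("w", n_visits=visits, n_contents=0 if visits == 0 else contents)
        prod = woman_fidelity(w, Composition.PRODUCT)
        mean = woman_fidelity(w, Composition.EQUAL_MEAN)
        # boundedness
        assert 0.0 <= prod.fidelity <= 1.0
        assert 0.0 <= mean.fidelity <= 1.0
        # composition ordering
        assert prod.fidelity <= mean.fidelity + 1e-12
        # product never exceeds its smallest factor
        if prod.coverage:
            assert prod.fidelity <= min(prod.frequency_weight, prod.content_weight) + 1e-12
        # monotonicity: one more visit (below 4) and one more content item
        if 1 <= visits < 4:
            w2 = make_woman("w", n_visits=visits + 1, n_contents=contents)
            for comp in Composition:
                assert woman_fidelity(w2, comp).fidelity >= woman_fidelity(w, comp).fidelity
        if visits >= 1 and contents < 17:
            w3 = make_woman("w", n_visits=visits, n_contents=contents + 1)
            for comp in Composition:
                assert woman_fidelity(w3, comp).fidelity >= woman_fidelity(w, comp).fidelity


class TestCohortFidelity:
    def _cohort(self, women):
        clusters = {"hp01": make_cluster("hp01"), "hp02": make_cluster("hp02")}
        return CohortTable(women=women, clusters=clusters)

    def test_identical_women_zero_width_ci(self):
        women = [make_woman(f"w{i}", n_visits=2, n_contents=17) for i in range(4)]
        est = cohort_fidelity(self._cohort(women))
        assert est.mean == pytest.approx(0.5)
        assert est.ci_low == pytest.approx(est.ci_high) == pytest.approx(0.5)

    def test_mean_of_zero_half_one(self):
        women = [
            make_woman("w1", n_visits=0),
            make_woman("w2", n_visits=2, n_contents=17),  # 0.5
            make_woman("w3", n_visits=4, n_contents=17),  # 1.0
        ]
        est = cohort_fidelity(self._cohort(women))
        assert est.mean == pytest.approx(0.5)
        assert est.ci_low <= est.mean <= est.ci_high
        assert est.n == 3

    def test_all_stratum_includes_non_attenders(self, tiny_cohort):
        assert cohort_fidelity(tiny_cohort, Stratum.ALL).n == 4
        assert cohort_fidelity(tiny_cohort, Stratum.HEW).n == 2
        assert cohort_fidelity(tiny_cohort, Stratum.SKILLED).n == 1

    def test_empty_stratum_raises(self):
        women = [make_woman("w1", n_visits=0)]
        with pytest.raises(ValidationError, match="empty cohort stratum"):
            cohort_fidelity(self._cohort(women), Stratum.HEW)

    def test_all_non_attenders_score_exactly_zero(self):
        women = [make_woman(f"w{i}", n_visits=0) for i in range(5)]
        est = cohort_fidelity(self._cohort(women))
        assert est.mean == 0.0 and est.ci_low == 0.0 and est.ci_high == 0.0

    def test_permutation_invariance(self, rng):
        women = [
            make_woman(f"w{i}", n_visits=int(v), n_contents=int(c))
            for i, (v, c) in enumerate(zip(rng.integers(0, 7, 30), rng.integers(0, 18, 30)))
        ]
        est1 = cohort_fidelity(self._cohort(women))
        perm = [women[i] for i in rng.permutation(len(women))]
        est2 = cohort_fidelity(self._cohort(perm))
        assert est1.mean == pytest.approx(est2.mean)
        assert est1.ci_low == pytest.approx(est2.ci_low)

    def test_cohort_mean_bounded_by_member_range(self, tiny_cohort):
        frame = fidelity_frame(tiny_cohort)
        est = cohort_fidelity(tiny_cohort)
        assert frame["fidelity"].min() <= est.mean <= frame["fidelity"].max()

    def test_t_interval_wider_than_z(self, tiny_cohort):
        z = cohort_fidelity(tiny_cohort, use_t=False)
        t = cohort_fidelity(tiny_cohort, use_t=True)
        assert (t.ci_high - t.ci_low) >= (z.ci_high - z.ci_low)


def test_fidelity_frame_matches_scalar_scores(tiny_cohort):
    frame = fidelity_frame(tiny_cohort)
    for row, w in zip(frame.itertuples(), tiny_cohort.women):
        assert row.fidelity == pytest.approx(woman_fidelity(w).fidelity)
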