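"""Assay statistics: fractions, relative fitness, ECOI, t tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from acrdyn import (
    ECOIObservation,
    StatsError,
    bonferroni_threshold,
    competition_fitness,
    ecoi,
    fraction,
    one_sample_test,
    phi_estimate,
    relative_fitness,
)

positive = st.floats(1e-6, 1e9, allow_nan=False, allow_infinity=False)
interior = st.floats(0.01, 0.99)


class TestFraction:
    @pytest.mark.parametrize("q1,q2,expected", [
        (3e7, 1e7, 0.75),
        (5.0, 5.0, 0.5),
        (0.0, 7.0, 0.0),
        (7.0, 0.0, 1.0),
    ])
    def test_hand_cases(self, q1, q2, expected):
        assert fraction(q1, q2) == pytest.approx(expected)

    @given(q1=positive, q2=positive)
    def test_complementarity(self, q1, q2):
        assert fraction(q1, q2) + fraction(q2, q1) == pytest.approx(1.0)
        assert 0.0 <= fraction(q1, q2) <= 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(StatsError, match="undefined"):
            fraction(0.0, 0.0)


class TestRelativeFitness:
    @pytest.mark.parametrize("f0,fx,expected", [
        (0.5, 0.5, 1.0),
        (0.5, 0.8, 4.0),
        (0.2, 0.1, 4.0 / 9.0),
    ])
    def test_odds_ratio_hand_cases(self, f0, fx, expected):
        assert relative_fitness(f0, fx) == pytest.approx(expected)

    @given(f0=interior, fx=interior)
    def test_label_swap_reciprocity(self, f0, fx):
        """The reference competitor's fitness is the exact reciprocal of
        the focal competitor's."""
        focal = relative_fitness(f0, fx)
        swapped = relative_fitness(1.0 - f0, 1.0 - fx)
        assert focal * swapped == pytest.approx(1.0)

    @given(f=interior)
    def test_unity_iff_no_change(self, f):
        assert relative_fitness(f, f) == pytest.approx(1.0)

    def test_boundary_gives_flagged_sentinel(self):
        lost = relative_fitness(0.5, 0.0)
        assert lost == 0.0 and lost.is_boundary
        assert "focal absent at tx" in lost.boundary
        swept = relative_fitness(0.5, 1.0)
        assert math.isinf(swept) and swept.is_boundary
        assert "reference absent at tx" in swept.boundary

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(StatsError, match="fraction_t0"):
            relative_fitness(1.2, 0.5)


class TestECOI:
    @pytest.mark.parametrize("centres,cells,moi,expected", [
        (200.0, 1e4, 1.0, 0.02),
        (0.0, 1e4, 1.0, 0.0),
        (5e3, 1e4, 0.5, 1.0),
    ])
    def test_hand_cases(self, centres, cells, moi, expected):
        assert ecoi(centres, cells, moi) == pytest.approx(expected)

    @given(c=st.floats(1.0, 1e6), scale=st.floats(0.1, 100.0))
    def test_scale_invariance(self, c, scale):
        """Proportional count inflation leaves the efficiency unchanged."""
        base = ecoi(c, 1e4, 1.0)
        assert ecoi(c * scale, 1e4 * scale, 1.0) == pytest.approx(base)

    def test_exceeding_one_is_flagged_not_clamped(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="acrdyn.stats"):
            value = ecoi(2e4, 1e4, 1.0)
        assert value == pytest.approx(2.0)
        assert any("exceeds 1" in r.message for r in caplog.records)

    def test_zero_cells_rejected(self):
        with pytest.raises(StatsError, match="cell"):
            ecoi(100.0, 0.0, 1.0)

    def test_observation_dataclass_roundtrip(self):
        obs = ECOIObservation(centres=200, cells=1e4, moi=1.0, host="bim1")
        assert obs.ecoi() == pytest.approx(0.02)
        with pytest.raises(StatsError, match="MOI"):
            ECOIObservation(centres=1, cells=10, moi=0.0)


class TestPhiEstimate:
    @pytest.mark.parametrize("er,ek,expected", [
        (0.02, 0.8, 0.025),
        (0.37, 0.37, 1.0),
        (0.0, 0.8, 0.0),
    ])
    def test_hand_cases(self, er, ek, expected):
        assert phi_estimate(er, ek) == pytest.approx(expected)

    def test_zero_knockout_rejected(self):
        with pytest.raises(StatsError, match="knockout"):
            phi_estimate(0.1, 0.0)


class TestOneSampleTest:
    def test_all_equal_to_null(self):
        res = one_sample_test([3.5] * 6, 3.5)
        assert res.t == 0.0
        assert res.p == 1.0
        assert res.zero_variance

    def test_six_replicates_give_five_df(self):
        res = one_sample_test([1.1, 0.9, 1.2, 1.05, 0.95, 1.0], 1.0)
        assert res.df == 5
        assert res.n == 6

    def test_against_textbook_formula(self):
        """Independent oracle: t = (xbar - mu) / (s / sqrt(n)) and the
        two-tailed p from the Student-t survival function."""
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        mu = 3.0
        xbar = np.mean(values)
        s = np.std(values, ddof=1)
        t_expected = (xbar - mu) / (s / math.sqrt(6))
        p_expected = 2.0 * sps.t.sf(abs(t_expected), 5)
        res = one_sample_test(values, mu)
        assert res.t == pytest.approx(t_expected)
        assert res.p == pytest.approx(p_expected)
        half = sps.t.ppf(0.975, 5) * s / math.sqrt(6)
        assert res.ci == pytest.approx((xbar - half, xbar + half))

    def test_one_tailed_halves_concordant_p(self):
        values = [1.3, 1.1, 1.5, 1.2, 1.4, 1.25]
        two = one_sample_test(values, 1.0, tail="two-sided")
        greater = one_sample_test(values, 1.0, tail="greater")
        assert greater.p == pytest.approx(two.p / 2.0)
        less = one_sample_test(values, 1.0, tail="less")
        assert less.p == pytest.approx(1.0 - two.p / 2.0)

    def test_log_scale_back_transforms_reporting(self):
        """Ratio data analysed on logs: estimate is the geometric mean
        and the CI is back-transformed."""
        values = [2.0, 4.0, 8.0, 2.0, 4.0, 8.0]
        res = one_sample_test(values, 1.0, log_scale=True)
        assert res.estimate == pytest.approx(4.0)
        assert res.ci[0] < 4.0 < res.ci[1]
        # Same t as testing the logs against 0 on the linear scale.
        ref = one_sample_test(np.log(values), 0.0)
        assert res.t == pytest.approx(ref.t)

    def test_log_scale_rejects_nonpositive(self):
        with pytest.raises(StatsError, match="positive"):
            one_sample_test([1.0, -2.0, 3.0], 1.0, log_scale=True)

    def test_single_value_rejected(self):
        with pytest.raises(StatsError, match="2 replicates"):
            one_sample_test([1.0], 1.0)

    def test_unknown_tail_rejected(self):
        with pytest.raises(StatsError, match="tail"):
            one_sample_test([1.0, 2.0], 1.0, tail="upper")


class TestBonferroni:
    @pytest.mark.parametrize("alpha,n,expected", [
        (0.05, 1, 0.05),
        (0.05, 3, 0.05 / 3),
        (0.05, 5, 0.01),
    ])
    def test_printed_rule(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_invalid_comparison_count_rejected(self):
        with pytest.raises(StatsError, match="n_comparisons"):
            bonferroni_threshold(0.05, 0)


class TestCompetitionFitness:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["replicate", "timepoint",
                                           "competitor", "quantity"])

    def test_quantities_and_fractions_agree(self):
        """Computing fitness from raw quantities equals composing the
        fraction and odds-ratio formulas by hand."""
        table = self._table([
            (1, 0.0, "focal", 5e6), (1, 0.0, "reference", 5e6),
            (1, 3.0, "focal", 8e6), (1, 3.0, "reference", 2e6),
            (2, 0.0, "focal", 2e6), (2, 0.0, "reference", 8e6),
            (2, 3.0, "focal", 1e6), (2, 3.0, "reference", 9e6),
        ])
        fits = competition_fitness(table, focal="focal")
        assert fits[1] == pytest.approx(
            relative_fitness(fraction(5e6, 5e6), fraction(8e6, 2e6)))
        assert fits[2] == pytest.approx(
            relative_fitness(fraction(2e6, 8e6), fraction(1e6, 9e6)))

    def test_pooled_variant_averages_quantities_first(self):
        table = self._table([
            (1, 0.0, "focal", 4e6), (1, 0.0, "reference", 6e6),
            (1, 3.0, "focal", 6e6), (1, 3.0, "reference", 4e6),
            (2, 0.0, "focal", 6e6), (2, 0.0, "reference", 4e6),
            (2, 3.0, "focal", 8e6), (2, 3.0, "reference", 2e6),
        ])
        pooled = competition_fitness(table, focal="focal",
                                     per_replicate=False)
        f0 = fraction(5e6, 5e6)
        fx = fraction(7e6, 3e6)
        assert pooled["pooled"] == pytest.approx(relative_fitness(f0, fx))

    def test_missing_column_rejected(self):
        with pytest.raises(StatsError, match="missing columns"):
            competition_fitness(pd.DataFrame({"replicate": [1]}),
                                focal="focal")
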