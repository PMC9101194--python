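"""Upper confidence limits, fuzzy numbers, membership and the fuzzy test."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2, norm

from pffuzzy import (
    DegenerateFuzzyNumberError,
    FitnessSpec,
    Outcome,
    ParameterError,
    build_fuzzy_index,
    fuzzy_test,
    membership,
    upper_confidence_limit,
)


def forward_limit(pf_star, n, a):
    """Independent evaluation of the confidence-limit map used as oracle."""
    return pf_star * math.sqrt(chi2.ppf(1 - a / 2, n - 1) / n) + norm.ppf(
        1 - a / 2
    ) / math.sqrt(n)


def spec(k=6.0, phi1=0.4, phi2=0.8):
    return FitnessSpec("it", "item", "larger_better", limit=0.0, k=k,
                       phi1=phi1, phi2=phi2)


class TestUpperConfidenceLimit:
    @pytest.mark.parametrize(
        "pf_star, expected",
        [(4.03, 6.178), (6.09, 9.019), (6.04, 8.950), (5.93, 8.799)],
    )
    def test_published_values(self, pf_star, expected):
        assert upper_confidence_limit(pf_star, 10, 0.05) == pytest.approx(
            expected, abs=1e-3
        )

    def test_zero_estimate_leaves_only_mean_term(self):
        got = upper_confidence_limit(0.0, 10, 0.05)
        assert got == pytest.approx(norm.ppf(0.975) / math.sqrt(10), abs=1e-12)
        assert got == pytest.approx(0.6198, abs=5e-4)

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            upper_confidence_limit(1.0, 1, 0.05)
        with pytest.raises(ParameterError):
            upper_confidence_limit(1.0, 10, 0.0)
        with pytest.raises(ParameterError):
            upper_confidence_limit(float("nan"), 10, 0.05)


class TestBuildFuzzyIndex:
    @pytest.mark.parametrize(
        "pf_star, pf_m, pf_r",
        [
            (4.03, 3.681, 6.178),
            (6.09, 5.563, 9.019),
            (6.04, 5.517, 8.950),
            (5.93, 5.416, 8.799),
        ],
    )
    def test_published_fuzzy_numbers(self, pf_star, pf_m, pf_r):
        fz = build_fuzzy_index(pf_star, 10, 0.05)
        assert fz.pf_m == pytest.approx(pf_m, abs=1e-3)
        assert fz.pf_r == pytest.approx(pf_r, abs=1e-3)
        assert fz.ucl == fz.pf_r

    def test_zero_estimate_has_zero_apex(self):
        assert build_fuzzy_index(0.0, 7).pf_m == 0.0

    def test_apex_below_point_estimate(self):
        # chi-square median < n-1 < n, so the apex shrinks the estimate
        for n in (2, 5, 10, 50):
            assert build_fuzzy_index(3.0, n).pf_m < 3.0

    @given(
        pf=st.floats(min_value=0.0, max_value=20.0),
        n=st.integers(min_value=2, max_value=100),
        alpha=st.floats(min_value=0.001, max_value=0.499),
    )
    @settings(max_examples=200, deadline=None)
    def test_ordering(self, pf, n, alpha):
        fz = build_fuzzy_index(pf, n, alpha)
        assert fz.pf_m < fz.pf_r

    def test_monotone_in_pf_star(self):
        grid = np.linspace(-1.0, 8.0, 30)
        ms, rs, ratios = [], [], []
        for pf in grid:
            fz = build_fuzzy_index(float(pf), 10, 0.05)
            ms.append(fz.pf_m)
            rs.append(fz.pf_r)
            ratios.append(fuzzy_test(fz, spec()).ratio)
        for seq in (ms, rs, ratios):
            assert all(a < b for a, b in zip(seq, seq[1:]))


class TestMembership:
    def test_apex_and_tails(self):
        fz = build_fuzzy_index(4.03, 10, 0.05)
        assert membership(fz, fz.pf_m) == 1.0
        assert membership(fz, fz.pf_m - 0.1) == 0.0
        assert membership(fz, fz.pf_r) == 0.0
        assert membership(fz, fz.pf_r + 1.0) == 0.0

    def test_forward_inverse_round_trip(self):
        fz = build_fuzzy_index(4.03, 10, 0.05)
        eta = membership(fz, 5.0)
        assert forward_limit(fz.pf_star, fz.n, eta) == pytest.approx(5.0, abs=1e-6)

    def test_round_trip_on_random_grid(self):
        """Inverting the confidence-limit map recovers x to 1e-6."""
        rng = np.random.default_rng(42)
        fz = build_fuzzy_index(4.03, 10, 0.05)
        xs = rng.uniform(fz.pf_m, fz.pf_r, size=100)
        xs = xs[(xs > fz.pf_m) & (xs < fz.pf_r)]
        for x in xs:
            eta = membership(fz, float(x))
            assert 0.05 < eta < 1.0
            assert forward_limit(fz.pf_star, fz.n, eta) == pytest.approx(
                float(x), abs=1e-6
            )

    def test_non_increasing_right_of_apex(self):
        fz = build_fuzzy_index(4.03, 10, 0.05)
        xs = np.linspace(fz.pf_m, fz.pf_r - 1e-9, 50)
        etas = [membership(fz, float(x)) for x in xs]
        assert all(a >= b for a, b in zip(etas, etas[1:]))


class TestFuzzyTest:
    def test_published_decisions(self):
        cases = {
            4.03: (0.178, 2.497, 0.071, Outcome.IMPROVE),
            6.09: (3.019, 3.456, 0.874, Outcome.MAINTAIN),
            6.04: (2.950, 3.433, 0.859, Outcome.MAINTAIN),
            5.93: (2.799, 3.383, 0.827, Outcome.MAINTAIN),
        }
        for pf_star, (d_r, d_t, ratio, outcome) in cases.items():
            dec = fuzzy_test(build_fuzzy_index(pf_star, 10, 0.05), spec())
            assert dec.d_r == pytest.approx(d_r, abs=2e-3)
            assert dec.d_t == pytest.approx(d_t, abs=2e-3)
            assert dec.ratio == pytest.approx(ratio, abs=2e-3)
            assert dec.outcome is outcome

    def test_boundary_k_at_right_endpoint(self):
        fz = build_fuzzy_index(2.0, 10, 0.05)
        dec = fuzzy_test(fz, spec(k=fz.pf_r))
        assert dec.ratio == pytest.approx(0.0, abs=1e-12)
        assert dec.outcome is Outcome.IMPROVE

    def test_ratio_unclamped(self):
        fz = build_fuzzy_index(2.0, 10, 0.05)
        assert fuzzy_test(fz, spec(k=fz.pf_r + 1.0)).ratio < 0.0
        assert fuzzy_test(fz, spec(k=fz.pf_m - 1.0)).ratio > 1.0

    def test_degenerate_base_rejected(self):
        # a sufficiently negative estimate collapses the base
        fz = build_fuzzy_index(-50.0, 10, 0.05)
        assert fz.pf_r - fz.pf_m <= 0
        with pytest.raises(DegenerateFuzzyNumberError):
            fuzzy_test(fz, spec())

    @given(
        pf=st.floats(min_value=0.0, max_value=15.0),
        k=st.floats(min_value=0.0, max_value=15.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_maintain_implies_classical_non_rejection(self, pf, k):
        """maintain forces PF_R > k, so the classical UCL test agrees."""
        dec = fuzzy_test(build_fuzzy_index(pf, 10, 0.05), spec(k=k))
        if dec.outcome is Outcome.MAINTAIN:
            assert dec.d_r > 0


class TestAreaRatioCrossCheck:
    def test_dr_dt_approximates_right_area_fraction_direction(self):
        """The base-fraction statistic and the numeric area fraction of the
        membership graph right of k order the worked-example items the
        same way (the simplification replaces, not equals, the area)."""
        xs_ratios = []
        areas = []
        for pf_star in (4.03, 6.09, 6.04, 5.93):
            fz = build_fuzzy_index(pf_star, 10, 0.05)
            dec = fuzzy_test(fz, spec())
            grid = np.linspace(fz.pf_m + 1e-9, fz.pf_r - 1e-9, 400)
            eta = np.array([membership(fz, float(x)) for x in grid])
            total = np.trapezoid(eta, grid)
            right = np.trapezoid(np.where(grid >= 6.0, eta, 0.0), grid)
            xs_ratios.append(dec.ratio)
            areas.append(right / total)
        assert np.argsort(xs_ratios).tolist() == np.argsort(areas).tolist()
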