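"""Unit and property tests for the closed-form layer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kindisp import analytics as ka
from kindisp.analytics import Demography, DispersalRegime, SocialEffects
from kindisp.errors import DegenerateError, DomainError


def regime(x, mu=0.0):
    return DispersalRegime(mean_rate=x, density_slope=mu)


class TestTypes:
    def test_demography_validation(self):
        with pytest.raises(DomainError):
            Demography(n=0, c=0.5)
        with pytest.raises(DomainError):
            Demography(n=2, c=1.5)
        with pytest.raises(DomainError):
            Demography(n=2, c=0.5, k=0)

    def test_regime_validation(self):
        with pytest.raises(DomainError):
            DispersalRegime(mean_rate=-0.1)
        assert DispersalRegime(0.5, -0.3).density_slope == -0.3

    def test_effects_validation(self):
        with pytest.raises(DomainError):
            SocialEffects(benefit=0.0, cost=0.1)
        with pytest.raises(DomainError):
            SocialEffects(benefit=0.1, cost=0.1, baseline=0.0)


class TestRelatedness:
    def test_well_mixed_limit(self):
        # full costless dispersal: whole-group relatedness is 1/n
        assert ka.relatedness(Demography(2, 0.0), 1.0) == pytest.approx(0.5)
        assert ka.relatedness(Demography(8, 0.0), 1.0) == pytest.approx(1 / 8)

    def test_single_breeder_is_clonal(self):
        # algebra: at n=1 the denominator collapses to (1 - c xbar)^2
        assert ka.relatedness(Demography(1, 0.5), 2 / 3) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_frozen_value(self):
        assert ka.relatedness(Demography(2, 0.2), 0.5) == pytest.approx(
            0.5912408759124088, abs=1e-12
        )

    @pytest.mark.parametrize("n,c", [(1, 0.0), (4, 0.3), (12, 0.9)])
    def test_no_dispersal_means_clonal_patch(self, n, c):
        assert ka.relatedness(Demography(n, c), 0.0) == pytest.approx(1.0)

    def test_degenerate_denominator(self):
        with pytest.raises(DegenerateError):
            ka.relatedness(Demography(3, 1.0), 1.0)

    def test_out_of_range(self):
        with pytest.raises(DomainError):
            ka.relatedness(Demography(3, 0.2), 1.2)

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.integers(1, 30),
        c=st.floats(0.0, 0.99),
        x=st.floats(0.0, 1.0),
    )
    def test_bounded_in_unit_interval(self, n, c, x):
        r = ka.relatedness(Demography(n, c), x)
        assert -1e-12 <= r <= 1.0 + 1e-12


class TestScaleAndLoad:
    def test_kin_competition_annulled_at_optimal_slope(self):
        assert ka.scale_of_competition(regime(0.5, 0.5), 0.3) == 0.0

    def test_density_independent_costless(self):
        assert ka.scale_of_competition(regime(0.5, 0.0), 0.0) == pytest.approx(
            0.25
        )

    def test_frozen_value(self):
        assert ka.scale_of_competition(
            regime(0.5, 0.3), 0.2
        ) == pytest.approx(0.5 / 0.9 * 0.2 / 0.9, abs=1e-12)

    def test_full_dispersal_gives_zero_scale(self):
        assert ka.scale_of_competition(regime(1.0, 0.2), 0.5) == 0.0

    @pytest.mark.parametrize(
        "x,mu,c,expected",
        [(0.7, 0.0, 0.4, 0.0), (0.7, 0.3, 0.0, 0.0), (0.5, 0.3, 0.2, 0.06 / 0.9)],
    )
    def test_mortality_load(self, x, mu, c, expected):
        assert ka.mortality_load(regime(x, mu), c) == pytest.approx(
            expected, abs=1e-12
        )

    def test_degenerate(self):
        with pytest.raises(DegenerateError):
            ka.mortality_load(regime(1.0, 0.1), 1.0)


class TestPotential:
    def test_reduces_to_relatedness(self):
        assert ka.potential_general(0.3, 0.0, 0.0) == pytest.approx(0.3)

    def test_matches_explicit_composition(self):
        r = 0.5912408759124088
        a = 0.5 / 0.9 * 0.2 / 0.9
        chi = 0.06 / 0.9
        assert ka.potential_general(r, a, chi) == pytest.approx(
            0.5394736842105263, abs=1e-12
        )

    def test_clonal_limit(self):
        # chi = c^2 with r = 1, a = 0: (1 - c^2)/(1 - c^2) = 1
        assert ka.potential_general(1.0, 0.0, 0.25) == pytest.approx(1.0)

    def test_singularity(self):
        with pytest.raises(DegenerateError):
            ka.potential_general(1.0, 1.0, 0.0)

    def test_explicit_density_independent_is_inverse_n(self):
        assert ka.potential_explicit(
            Demography(5, 0.4), regime(0.6, 0.0)
        ) == pytest.approx(0.2, abs=1e-15)

    def test_explicit_frozen_values(self):
        assert ka.potential_explicit(
            Demography(2, 0.2), regime(0.5, 0.3)
        ) == pytest.approx(0.5394736842105263, abs=1e-12)
        below = ka.potential_explicit(Demography(2, 0.2), regime(0.5, -0.3))
        assert below == pytest.approx(0.453125, abs=1e-12)
        assert below < 0.5  # negative density dependence inhibits altruism

    @settings(max_examples=200, deadline=None)
    @given(
        n=st.integers(1, 20),
        c=st.floats(0.0, 0.95),
        x=st.floats(0.05, 0.95),
        mu=st.floats(-0.5, 0.5),
    )
    def test_composition_identity(self, n, c, x, mu):
        demog = Demography(n, c)
        reg = regime(x, mu)
        explicit = ka.potential_explicit(demog, reg)
        composed = ka.potential_general(
            ka.relatedness(demog, x),
            ka.scale_of_competition(reg, c),
            ka.mortality_load(reg, c),
        )
        assert explicit == pytest.approx(composed, abs=1e-10)


class TestHamiltonMargin:
    def test_zero_at_threshold(self):
        demog = Demography(3, 0.3)
        reg = regime(0.4, 0.2)
        thresh = ka.potential_explicit(demog, reg)
        eff = SocialEffects(benefit=1.0, cost=thresh)
        assert ka.hamilton_margin(eff, demog, reg) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_well_mixed_reduces_to_inverse_n(self):
        demog = Demography(2, 0.0)
        reg = regime(1.0, 0.0)
        assert (
            ka.hamilton_margin(SocialEffects(1.0, 0.4), demog, reg) > 0
        )  # 0.4 < 1/2
        assert ka.hamilton_margin(SocialEffects(1.0, 0.6), demog, reg) < 0

    def test_sign_flips_at_optimal_dispersal_threshold(self):
        demog = Demography(2, 0.2)
        xs = ka.optimal_dispersal_rate(demog)
        reg = regime(xs, 1.0 - xs)
        # threshold = 0.517945...
        assert ka.hamilton_margin(SocialEffects(1.0, 0.51), demog, reg) > 0
        assert ka.hamilton_margin(SocialEffects(1.0, 0.53), demog, reg) < 0

    @settings(max_examples=100, deadline=None)
    @given(
        n=st.integers(1, 15),
        c=st.floats(0.0, 0.9),
        x=st.floats(0.05, 0.95),
        mu=st.floats(-0.4, 0.4),
        ratio=st.floats(0.01, 0.99),
    )
    def test_threshold_consistency(self, n, c, x, mu, ratio):
        demog = Demography(n, c)
        reg = regime(x, mu)
        margin = ka.hamilton_margin(
            SocialEffects(benefit=1.0, cost=ratio), demog, reg
        )
        thresh = ka.potential_explicit(demog, reg)
        if abs(ratio - thresh) > 1e-9:
            assert (margin > 0) == (ratio < thresh)


class TestOptimalDispersal:
    def test_hamilton_may(self):
        assert ka.optimal_dispersal_rate(Demography(1, 0.5)) == pytest.approx(
            2 / 3, abs=1e-12
        )

    @pytest.mark.parametrize("n", [1, 2, 7])
    def test_costless_dispersal_is_full(self, n):
        assert ka.optimal_dispersal_rate(Demography(n, 0.0)) == pytest.approx(
            1.0
        )

    def test_frozen_value(self):
        assert ka.optimal_dispersal_rate(Demography(2, 0.2)) == pytest.approx(
            0.6782161153045774, abs=1e-12
        )

    def test_guard_binds_only_at_full_cost(self):
        assert ka.optimal_dispersal_rate(Demography(3, 1.0)) == 0.0
        for c in np.linspace(0.01, 0.99, 25):
            assert ka.optimal_dispersal_rate(Demography(3, float(c))) > 0.0

    def test_ess_identity(self):
        for n in range(1, 21):
            for c in np.linspace(0.05, 0.95, 19):
                demog = Demography(n, float(c))
                xs = ka.optimal_dispersal_rate(demog)
                lhs = (1 - xs) * ka.relatedness(demog, xs) / (1 - c * xs)
                assert lhs == pytest.approx(c, abs=1e-10)

    def test_at_unit_density_matches_mean(self):
        demog = Demography(2, 0.2)
        assert ka.optimal_dispersal_at_density(1.0, demog) == pytest.approx(
            ka.optimal_dispersal_rate(demog), abs=1e-14
        )

    def test_constant_non_disperser(self):
        demog = Demography(2, 0.2)
        quota = 1.0 - ka.optimal_dispersal_rate(demog)
        assert ka.optimal_dispersal_at_density(2.0, demog) == pytest.approx(
            0.8391080576522887, abs=1e-9
        )
        for P in (0.5, 1.0, 2.0, 4.0):
            xP = ka.optimal_dispersal_at_density(P, demog)
            if xP > 0.0:
                assert P * (1 - xP) == pytest.approx(quota, abs=1e-12)

    def test_low_density_clamps_to_zero(self):
        assert ka.optimal_dispersal_at_density(0.2, Demography(2, 0.2)) == 0.0

    def test_density_domain(self):
        with pytest.raises(DomainError):
            ka.optimal_dispersal_at_density(0.0, Demography(2, 0.2))


class TestPotentialUnderOptimalDispersal:
    @pytest.mark.parametrize(
        "n,c,expected",
        [
            (7, 0.0, 1 / 7),
            (1, 0.5, 1.0),
            (2, 0.2, 0.5179459711738557),
            (10, 0.8, 0.47386631886738),
        ],
    )
    def test_frozen_values(self, n, c, expected):
        assert ka.potential_under_optimal_dispersal(
            Demography(n, c)
        ) == pytest.approx(expected, abs=1e-9)

    def test_exceeds_inverse_n(self):
        for n in (2, 3, 5, 10, 20):
            for c in np.linspace(0.05, 0.95, 19):
                A = ka.potential_under_optimal_dispersal(Demography(n, float(c)))
                assert A > 1.0 / n

    def test_mortality_consequence_equals_cost_squared(self):
        # chi * r = c^2 at the dispersal optimum
        for n in (1, 3, 9):
            for c in (0.2, 0.5, 0.8):
                demog = Demography(n, c)
                xs = ka.optimal_dispersal_rate(demog)
                reg = DispersalRegime(xs, 1.0 - xs)
                chi_r = ka.mortality_load(reg, c) * ka.relatedness(demog, xs)
                assert chi_r == pytest.approx(c * c, abs=1e-10)


class TestSummarize:
    def test_defaults_to_ess_regime(self):
        s = ka.summarize(Demography(2, 0.2))
        assert s.optimal_mean_dispersal == pytest.approx(0.6782161153045774)
        assert s.scale_of_competition == pytest.approx(0.0, abs=1e-12)
        assert s.potential == pytest.approx(0.5179459711738557, abs=1e-9)

    def test_explicit_regime(self):
        s = ka.summarize(Demography(2, 0.2), regime(0.5, 0.3), P=2.0)
        assert s.relatedness == pytest.approx(0.5912408759124088)
        assert s.potential == pytest.approx(0.5394736842105263)
        assert s.relative_density == 2.0


class TestMonotonicities:
    grid_c = np.linspace(0.05, 0.95, 10)

    def test_relatedness_signs(self):
        # at n = 1 a patch is clonal (r = 1) for every x and c, so the
        # strict signs in x and c apply from n = 2 upward
        for c in self.grid_c:
            for x in np.linspace(0.05, 0.95, 10):
                for n in (1, 2, 5, 10):
                    r0 = ka.relatedness(Demography(n, float(c)), float(x))
                    assert ka.relatedness(
                        Demography(n + 1, float(c)), float(x)
                    ) < r0  # dr/dn < 0
                    if n > 1:
                        assert ka.relatedness(
                            Demography(n, float(c)), float(x) + 0.02
                        ) < r0  # dr/dx < 0
                        assert ka.relatedness(
                            Demography(n, float(c) + 0.02), float(x)
                        ) > r0  # dr/dc > 0

    def test_potential_increasing_in_density_slope(self):
        # dA/dmu has the sign of 1 - (1+c)x, so the increase holds on
        # x < 1/(1+c) — the region containing every ESS dispersal rate
        # (x* <= 1/(1+c), with equality at n = 1)
        for n in (2, 5):
            for c in (0.0, 0.4):
                for x in (0.2, 0.5, 0.8):
                    if (1 + c) * (x + 0.0) >= 1.0:
                        continue
                    for mu in np.linspace(-0.4, 0.4, 9):
                        lo = ka.potential_explicit(
                            Demography(n, c), regime(x, float(mu))
                        )
                        hi = ka.potential_explicit(
                            Demography(n, c), regime(x, float(mu) + 0.05)
                        )
                        assert hi > lo

    def test_ess_dispersal_signs(self):
        for c in self.grid_c:
            for n in (1, 2, 5, 10):
                x0 = ka.optimal_dispersal_rate(Demography(n, float(c)))
                assert ka.optimal_dispersal_rate(
                    Demography(n + 1, float(c))
                ) < x0
                assert ka.optimal_dispersal_rate(
                    Demography(n, float(c) + 0.02)
                ) < x0

    def test_potential_along_optimal_manifold(self):
        for c in self.grid_c:
            for n in (2, 3, 5, 10):
                A0 = ka.potential_under_optimal_dispersal(
                    Demography(n, float(c))
                )
                assert (
                    ka.potential_under_optimal_dispersal(
                        Demography(n + 1, float(c))
                    )
                    < A0
                )  # dA/dn < 0
                assert (
                    ka.potential_under_optimal_dispersal(
                        Demography(n, float(c) + 0.02)
                    )
                    > A0
                )  # dA/dc > 0
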