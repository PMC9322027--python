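"""Eyring conversions, pKa equilibria, composite and observed rates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from acylmig import (
    Conditions,
    StepRates,
    UnitError,
    ValidationError,
    composite_rate,
    convert_rate_units,
    energy_profile_from_kobs,
    eyring_barrier_from_rate,
    eyring_rate_from_barrier,
    keq_from_pka,
    observed_rate,
    ph_coefficient,
)
from acylmig.datasets import (
    ANIONIC_COMPOSITES_ALPHA_GLC,
    NEUTRAL_COMPOSITES_ALPHA_GLC,
    OBSERVED_ALPHA_GLC_EXPERIMENTAL,
    OBSERVED_ALPHA_GLC_PREDICTED,
    OBSERVED_BETA_GLC_EXPERIMENTAL,
    PKA_ALPHA_GLC,
    alpha_glc_mechanism,
)

COND = Conditions()


class TestEyring:
    def test_rate_equal_to_prefactor_has_zero_barrier(self):
        assert eyring_barrier_from_rate(COND.prefactor) == pytest.approx(
            0.0, abs=1e-12
        )
        assert COND.prefactor == pytest.approx(6.21e12, rel=1e-3)

    @pytest.mark.parametrize(
        "rate, barrier",
        [(6.28e-5, 23.2), (8.80e1, 14.8)],
    )
    def test_published_rates_reproduce_barriers(self, rate, barrier):
        assert round(eyring_barrier_from_rate(rate, COND), 1) == barrier

    def test_zero_barrier_gives_prefactor_rate(self):
        assert eyring_rate_from_barrier(0.0) == COND.prefactor

    def test_high_barrier_rate_vanishes_monotonically(self):
        assert eyring_rate_from_barrier(100.0) < 1e-50
        barriers = np.linspace(0, 60, 20)
        rates = [eyring_rate_from_barrier(b) for b in barriers]
        assert np.all(np.diff(rates) < 0)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValidationError):
            eyring_barrier_from_rate(0.0)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(min_value=-15.0, max_value=13.0))
    def test_round_trip_exact_over_fifteen_decades(self, log10k):
        k = 10.0**log10k
        back = eyring_rate_from_barrier(eyring_barrier_from_rate(k))
        assert back == pytest.approx(k, rel=1e-12)

    @pytest.mark.parametrize(
        "table",
        [
            NEUTRAL_COMPOSITES_ALPHA_GLC,
            ANIONIC_COMPOSITES_ALPHA_GLC,
            OBSERVED_ALPHA_GLC_EXPERIMENTAL,
            OBSERVED_ALPHA_GLC_PREDICTED,
            OBSERVED_BETA_GLC_EXPERIMENTAL,
        ],
        ids=["neutral", "anionic", "obs-exp", "obs-pred", "obs-beta-glc"],
    )
    def test_published_rate_barrier_pairs_self_consistent(self, table):
        # rate -> barrier direction is robust to the printed rounding
        for name, (rate, dg) in table.items():
            recomputed = eyring_barrier_from_rate(rate, COND)
            assert recomputed == pytest.approx(dg, abs=0.1), name


class TestKeqAndPh:
    def test_keq_of_zero_pka_is_one(self):
        assert keq_from_pka(0.0) == 1.0

    def test_keq_matches_published_values(self):
        keq1 = keq_from_pka(PKA_ALPHA_GLC["2Ac"])
        assert f"{keq1:.1e}" == "1.3e-13"
        assert keq_from_pka(PKA_ALPHA_GLC["3Ac"]) == pytest.approx(1.0e-12)

    @pytest.mark.parametrize(
        "ph, coeff", [(8.0, 1.0), (9.0, 10.0), (7.0, 0.1), (6.0, 0.01)]
    )
    def test_ph_coefficient_powers_of_ten(self, ph, coeff):
        assert ph_coefficient(ph) == pytest.approx(coeff)

    def test_ph_coefficient_printed_rounding(self):
        assert round(ph_coefficient(7.5), 2) == 0.32

    def test_out_of_range_ph_rejected(self):
        with pytest.raises(ValidationError):
            ph_coefficient(15.0)


class TestCompositeRate:
    def test_fast_collapse_limit_is_first_step(self):
        fwd, _ = composite_rate(
            StepRates(ka=2.0, k_minus_a=1e-9, kb=1e6, k_minus_b=1.0)
        )
        assert fwd == pytest.approx(2.0, rel=1e-6)

    def test_balanced_constants_halve_forward_rate(self):
        fwd, rev = composite_rate(
            StepRates(ka=1.0, k_minus_a=1.0, kb=1.0, k_minus_b=1.0)
        )
        assert fwd == 0.5 and rev == 0.5

    def test_pre_equilibrium_limit(self):
        # k_minus_a >> kb: forward composite ~ ka*kb/k_minus_a
        s = StepRates(ka=1e-3, k_minus_a=10.0, kb=0.1, k_minus_b=1.0)
        fwd, _ = composite_rate(s)
        assert fwd == pytest.approx(s.ka * s.kb / s.k_minus_a, rel=0.01)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.floats(min_value=-4, max_value=4),
        st.floats(min_value=-4, max_value=4),
        st.floats(min_value=-4, max_value=4),
        st.floats(min_value=-4, max_value=4),
    )
    def test_forward_composite_never_exceeds_first_step(self, a, ma, b, mb):
        s = StepRates(
            ka=10.0**a, k_minus_a=10.0**ma, kb=10.0**b, k_minus_b=10.0**mb
        )
        fwd, rev = composite_rate(s)
        assert fwd <= s.ka and fwd > 0 and rev > 0

    def test_matches_two_step_integration_oracle(self):
        # effective A -> B rate of A <-> I -> B measured from the slow decay
        s = StepRates(ka=1e-3, k_minus_a=10.0, kb=1.0, k_minus_b=1e-12)
        fwd, _ = composite_rate(s)
        assert fwd == pytest.approx(9.0909e-5, rel=1e-3)
        m = np.array(
            [
                [-s.ka, s.k_minus_a, 0.0],
                [s.ka, -(s.k_minus_a + s.kb), 0.0],
                [0.0, s.kb, 0.0],
            ]
        )
        sol = solve_ivp(
            lambda _, c: m @ c,
            (0.0, 200.0),
            [1.0, 0.0, 0.0],
            t_eval=[100.0, 200.0],
            rtol=1e-11,
            atol=1e-14,
        )
        unreacted = 1.0 - sol.y[2]
        k_eff = np.log(unreacted[0] / unreacted[1]) / 100.0
        assert fwd == pytest.approx(k_eff, rel=0.01)


class TestObservedRate:
    def test_pure_anionic_arithmetic(self):
        pred = observed_rate(0.0, 1.0, 1e-13, Conditions(pH=8.0))
        assert pred.k_obs == pytest.approx(1e-5)
        assert pred.anionic_fraction == 1.0

    def test_alpha_glc_first_step_prediction(self):
        pred = observed_rate(
            NEUTRAL_COMPOSITES_ALPHA_GLC["k3"][0],
            ANIONIC_COMPOSITES_ALPHA_GLC["k2"][0],
            keq_from_pka(PKA_ALPHA_GLC["2Ac"]),
            Conditions(pH=8.0),
        )
        assert pred.k_obs == pytest.approx(1.11e-3, rel=0.01)
        assert pred.anionic_term / pred.neutral_term > 1e5
        assert pred.k_obs == pred.neutral_term + pred.anionic_term

    def test_anionic_only_mode_drops_neutral_term(self):
        pred = observed_rate(
            4.76e-10, 88.0, 1.3e-13, Conditions(pH=8.0), anionic_only=True
        )
        assert pred.neutral_term == 0.0
        assert pred.k_obs == pred.anionic_term

    def test_ph_linearity_of_anionic_pathway(self):
        k8 = observed_rate(0.0, 88.0, 1.3e-13, Conditions(pH=8.0)).k_obs
        k9 = observed_rate(0.0, 88.0, 1.3e-13, Conditions(pH=9.0)).k_obs
        assert k9 / k8 == pytest.approx(10.0)
        # slope 1 on log-log scale vs [OH-]
        phs = np.linspace(6.0, 10.0, 9)
        ks = [observed_rate(0.0, 88.0, 1.3e-13, Conditions(pH=p)).k_obs for p in phs]
        slope = np.polyfit(phs, np.log10(ks), 1)[0]
        assert slope == pytest.approx(1.0, abs=1e-12)

    def test_observed_rates_increase_with_ph(self):
        ks = [
            observed_rate(4.76e-10, 88.0, 1.3e-13, Conditions(pH=p)).k_obs
            for p in np.linspace(2.0, 12.0, 11)
        ]
        assert np.all(np.diff(ks) > 0)


class TestUnits:
    @pytest.mark.parametrize(
        "k, src, dst, expected",
        [
            (0.0, "h^-1", "s^-1", 0.0),
            (3600.0, "h^-1", "s^-1", 1.0),
            (1.0, "s^-1", "h^-1", 3600.0),
            (5.0, "h^-1", "h^-1", 5.0),
        ],
    )
    def test_conversion_factor(self, k, src, dst, expected):
        assert convert_rate_units(k, src, dst) == expected

    def test_glc_k1_bridges_to_observed_units(self):
        k_s = convert_rate_units(2.26e-1, "h^-1", "s^-1")
        assert f"{k_s:.2e}" == "6.28e-05"

    def test_unknown_unit_rejected(self):
        with pytest.raises(UnitError):
            convert_rate_units(1.0, "h^-1", "fortnight^-1")


class TestEnergyProfile:
    def test_symmetric_step_is_thermoneutral(self):
        prof = energy_profile_from_kobs([(1e-4, 1e-4)])
        assert prof.minima == (0.0, 0.0)

    def test_alpha_glc_experimental_profile_descends_to_terminal_isomer(self):
        pairs = [
            (
                OBSERVED_ALPHA_GLC_EXPERIMENTAL[f"k{i}obs"][0],
                OBSERVED_ALPHA_GLC_EXPERIMENTAL[f"k-{i}obs"][0],
            )
            for i in (1, 2, 3)
        ]
        prof = energy_profile_from_kobs(pairs, COND)
        minima = np.array(prof.minima)
        # terminal O6 isomer is the global minimum, well below O2
        assert minima[-1] == minima.min()
        assert minima[-1] < minima[0] - 1.0
        # each barrier top lies above both flanking minima
        for i, mx in enumerate(prof.maxima):
            assert mx >= prof.minima[i] and mx >= prof.minima[i + 1]

    def test_profile_is_path_direction_independent(self):
        pairs = [(6.28e-5, 5.11e-5), (5.06e-5, 1.01e-4), (1.21e-3, 7.83e-5)]
        fwd = energy_profile_from_kobs(pairs, COND)
        rev = energy_profile_from_kobs(
            [(kb, kf) for kf, kb in reversed(pairs)], COND
        )
        mirrored = np.array(fwd.minima[::-1]) - fwd.minima[-1]
        np.testing.assert_allclose(rev.minima, mirrored, atol=1e-12)
        mirrored_max = np.array(fwd.maxima[::-1]) - fwd.minima[-1]
        np.testing.assert_allclose(rev.maxima, mirrored_max, atol=1e-12)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValidationError):
            energy_profile_from_kobs([(0.0, 1.0)])


class TestMechanismSpec:
    def test_first_step_observed_rates_and_profile(self):
        spec = alpha_glc_mechanism()
        (fwd, bwd), = spec.observed()
        assert fwd.k_obs == pytest.approx(1.11e-3, rel=0.01)
        # reverse: k-2 * Keq2 / [H+] = 6.82 * 1e-12 / 1e-8
        assert bwd.k_obs == pytest.approx(6.82e-4, rel=0.01)
        prof = spec.energy_profile()
        assert len(prof.minima) == 2 and len(prof.maxima) == 1
        # simplified anionic-only model barely differs at pH 8
        prof2 = spec.energy_profile(anionic_only=True)
        np.testing.assert_allclose(prof.minima, prof2.minima, atol=1e-5)

    def test_conditions_validation(self):
        with pytest.raises(ValidationError):
            Conditions(temperature=-1.0)
        with pytest.raises(ValidationError):
            Conditions(kappa=0.0)
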