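import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dmsofold import (
    PhysicalConstants,
    RelaxationRecord,
    RelaxSimSpec,
    estimate_tauc_r2r1,
    exchange_screen_r1r2,
    fit_model_free,
    forward_rates,
    lipari_szabo_J,
    reduced_jmap,
    simulate_relaxation,
)
from dmsofold.relax import RelaxationError, rigid_r2_over_r1

CONST = PhysicalConstants()


class TestLipariSzabo:
    def test_rigid_lorentzian_at_zero(self):
        assert lipari_szabo_J(0.0, 1.0, 7.7e-9) == pytest.approx(0.4 * 7.7e-9)
        assert lipari_szabo_J(0.0, 1.0, 7.7e-9) == pytest.approx(3.08e-9, rel=1e-12)

    def test_value_at_15N_frequency(self):
        w = 2.0 * math.pi * 70.966e6
        # closed form: 0.4 * tc / (1 + (w tc)^2)
        expected = 0.4 * 7.7e-9 / (1.0 + (w * 7.7e-9) ** 2)
        assert lipari_szabo_J(w, 1.0, 7.7e-9) == pytest.approx(expected, rel=1e-12)
        assert lipari_szabo_J(w, 1.0, 7.7e-9) == pytest.approx(2.41e-10, rel=2e-3)

    def test_tau_e_term(self):
        w = 1e8
        S2, tc, te = 0.8, 7.7e-9, 50e-12
        tau = 1.0 / (1.0 / tc + 1.0 / te)
        expected = 0.4 * (S2 * tc / (1 + (w * tc) ** 2)
                          + (1 - S2) * tau / (1 + (w * tau) ** 2))
        assert lipari_szabo_J(w, S2, tc, te) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(RelaxationError):
            lipari_szabo_J(0.0, 1.2, 7.7e-9)
        with pytest.raises(RelaxationError):
            lipari_szabo_J(0.0, 0.5, -1e-9)

    @given(
        S2=st.floats(0.0, 1.0),
        tc_ns=st.floats(1.0, 20.0),
        field=st.sampled_from([50.684, 70.966]),
    )
    def test_monotone_spectral_densities(self, S2, tc_ns, field):
        # J(0) >= J(wN) >= J(0.87 wH)
        wN = CONST.omega_N(field)
        wH = CONST.omega_H(field)
        tc = tc_ns * 1e-9
        j0 = lipari_szabo_J(0.0, S2, tc)
        jn = lipari_szabo_J(wN, S2, tc)
        jh = lipari_szabo_J(0.87 * wH, S2, tc)
        assert j0 >= jn >= jh


class TestForwardRates:
    def test_extreme_narrowing_limit(self):
        # dipolar R1 -> R2; the small residual comes from the CSA term
        # (7/6 ratio), a few percent of the total at this field
        R1, R2, _ = forward_rates(1.0, 1e-12, None, 70.966)
        assert R2 / R1 == pytest.approx(1.0, abs=0.02)
        d2_only = PhysicalConstants(delta_sigma_ppm=0.0)
        R1, R2, _ = forward_rates(1.0, 1e-12, None, 70.966, constants=d2_only)
        assert R2 / R1 == pytest.approx(1.0, abs=1e-6)

    def test_paf_regime_magnitudes(self):
        R1, R2, NOE = forward_rates(0.87, 7.7e-9, None, 70.966)
        assert 0.5 < R1 < 3.0
        assert 5.0 < R2 < 20.0
        assert 0.6 < NOE < 0.95

    def test_rex_additivity(self):
        base = forward_rates(0.87, 7.7e-9, None, 70.966, Rex=0.0)
        withx = forward_rates(0.87, 7.7e-9, None, 70.966, Rex=5.0)
        assert withx[1] - base[1] == pytest.approx(5.0, rel=1e-12)
        assert withx[0] == base[0]
        assert withx[2] == base[2]

    def test_array_matches_scalar(self):
        S2 = np.array([0.8, 0.9])
        R1, R2, NOE = forward_rates(S2, 7.7e-9, None, 70.966)
        for i, s in enumerate(S2):
            r1, r2, noe = forward_rates(float(s), 7.7e-9, None, 70.966)
            assert R1[i] == pytest.approx(r1)
            assert R2[i] == pytest.approx(r2)
            assert NOE[i] == pytest.approx(noe)


class TestReducedJmap:
    @pytest.mark.parametrize("field", [50.684, 70.966])
    def test_rigid_roundtrip_within_2pct(self, field):
        R1, R2, NOE = forward_rates(1.0, 7.7e-9, None, field)
        rec = RelaxationRecord(1, R1, 0.0, R2, 0.0, NOE, 0.0)
        j = reduced_jmap(rec, field)
        wN = CONST.omega_N(field)
        wH = CONST.omega_H(field)
        assert j.J0 == pytest.approx(lipari_szabo_J(0.0, 1.0, 7.7e-9), rel=0.02)
        assert j.JwN == pytest.approx(lipari_szabo_J(wN, 1.0, 7.7e-9), rel=0.02)
        assert j.JwH == pytest.approx(lipari_szabo_J(0.87 * wH, 1.0, 7.7e-9),
                                      rel=0.05)
        assert not j.unphysical

    @settings(deadline=None, max_examples=40)
    @given(
        S2=st.floats(0.5, 1.0),
        tc_ns=st.floats(2.0, 15.0),
        field=st.sampled_from([50.684, 70.966]),
    )
    def test_roundtrip_property(self, S2, tc_ns, field):
        tc = tc_ns * 1e-9
        R1, R2, NOE = forward_rates(S2, tc, None, field)
        j = reduced_jmap(RelaxationRecord(1, R1, 0.0, R2, 0.0, NOE, 0.0), field)
        wN = CONST.omega_N(field)
        assert j.J0 == pytest.approx(lipari_szabo_J(0.0, S2, tc), rel=0.02)
        assert j.JwN == pytest.approx(lipari_szabo_J(wN, S2, tc), rel=0.02)

    def test_noe_one_gives_zero_high_freq(self):
        rec = RelaxationRecord(1, 1.5, 0.0, 10.0, 0.0, 1.0, 0.0)
        j = reduced_jmap(rec, 70.966)
        assert j.JwH == 0.0

    def test_rigid_locus_parameterized_by_tauc(self):
        # mapped rigid points fall on the no-internal-motion curve
        for tc_ns in (3.0, 7.7, 12.0):
            R1, R2, NOE = forward_rates(1.0, tc_ns * 1e-9, None, 70.966)
            j = reduced_jmap(RelaxationRecord(1, R1, 0.0, R2, 0.0, NOE, 0.0),
                             70.966)
            # invert J(wN) for tau_c and check J(0) consistency
            wN = CONST.omega_N(70.966)
            # rigid: JwN = 0.4 tc/(1+(wN tc)^2) -> solve quadratic in tc
            a = j.JwN * wN**2
            tc_sol = (0.4 + math.sqrt(0.16 - 4 * a * j.JwN)) / (2 * a)
            assert 0.4 * tc_sol == pytest.approx(j.J0, rel=0.03)

    def test_negative_j0_flagged(self):
        rec = RelaxationRecord(1, 2.0, 0.0, 0.05, 0.0, 0.2, 0.0)
        j = reduced_jmap(rec, 70.966)
        assert j.J0 < 0
        assert j.unphysical


class TestRecordValidation:
    def test_nonpositive_rate_rejected(self):
        with pytest.raises(RelaxationError, match="residue 7"):
            RelaxationRecord(7, 1.0, 0.0, 0.0, 0.0, 0.8, 0.0)

    def test_noe_sanity_bound(self):
        with pytest.raises(RelaxationError):
            RelaxationRecord(1, 1.0, 0.0, 10.0, 0.0, 1.3, 0.0)


class TestEstimateTauc:
    def test_rigid_noiseless_recovery(self, rigid_noiseless_relaxation):
        est = estimate_tauc_r2r1(rigid_noiseless_relaxation)
        assert est.tau_c_ns == pytest.approx(7.7, rel=0.005)

    def test_mutant_regime_at_lower_field(self):
        ds = simulate_relaxation(RelaxSimSpec(
            n_residues=50, s2_mean=1.0, s2_sd=0.0, tau_c_ns=12.0,
            field_15N_MHz=50.684, noise_sd=0.0))
        est = estimate_tauc_r2r1(ds)
        assert est.tau_c_ns == pytest.approx(12.0, rel=0.005)

    def test_s2_spread_does_not_bias(self):
        # without tau_e, R2/R1 is independent of S2
        ds = simulate_relaxation(RelaxSimSpec(
            n_residues=50, tau_c_ns=7.7, noise_sd=0.0, seed=2))
        est = estimate_tauc_r2r1(ds)
        assert est.tau_c_ns == pytest.approx(7.7, rel=0.005)

    def test_extreme_narrowing_flagged(self):
        ds = simulate_relaxation(RelaxSimSpec(
            n_residues=10, s2_mean=1.0, s2_sd=0.0, tau_c_ns=0.01,
            noise_sd=0.0))
        # bypass the NOE mobility filter to expose the solver-grid flag
        with pytest.raises(RelaxationError, match="narrowing"):
            estimate_tauc_r2r1(ds, noe_min=-10.0)

    def test_extreme_narrowing_caught_by_noe_filter(self):
        ds = simulate_relaxation(RelaxSimSpec(
            n_residues=10, s2_mean=1.0, s2_sd=0.0, tau_c_ns=0.01,
            noise_sd=0.0))
        with pytest.raises(RelaxationError, match="filtered"):
            estimate_tauc_r2r1(ds)

    def test_too_few_residues(self):
        ds = simulate_relaxation(RelaxSimSpec(n_residues=3, noise_sd=0.0))
        with pytest.raises(RelaxationError):
            estimate_tauc_r2r1(ds)

    def test_rigid_ratio_monotone(self):
        ratios = [rigid_r2_over_r1(t * 1e-9, 70.966) for t in (1.0, 5.0, 10.0, 20.0)]
        assert ratios == sorted(ratios)


class TestFitModelFree:
    def test_noiseless_inverse(self):
        ds = simulate_relaxation(RelaxSimSpec(
            n_residues=50, tau_c_ns=7.7, noise_sd=0.0, seed=4))
        mf = fit_model_free(ds, mc_reps=2, seed=0)
        assert mf.tau_c_ns == pytest.approx(7.7, rel=1e-3)
        truth = np.array([ds.truth["S2"][r] for r in mf.residues])
        np.testing.assert_allclose(mf.S2, truth, rtol=1e-3)

    def test_rigid_noiseless_all_s2_one(self, rigid_noiseless_relaxation):
        mf = fit_model_free(rigid_noiseless_relaxation, mc_reps=2, seed=0)
        np.testing.assert_allclose(mf.S2, 1.0, atol=1e-3)

    def test_paf_regime_recovery(self, paf_regime_relaxation):
        ds = paf_regime_relaxation
        mf = fit_model_free(ds, mc_reps=100, seed=0)
        assert mf.tau_c_ns == pytest.approx(7.7, rel=0.03)
        truth = np.array([ds.truth["S2"][r] for r in mf.residues])
        rms = float(np.sqrt(np.mean((mf.S2 - truth) ** 2)))
        assert rms <= 0.02
        assert float(np.mean(mf.S2)) == pytest.approx(0.87, abs=0.03)

    def test_error_scaling_invariance_noiseless(self):
        # uniform scaling of all stated errors must not move S2 on clean data
        ds = simulate_relaxation(RelaxSimSpec(
            n_residues=30, tau_c_ns=7.7, noise_sd=0.0, seed=6))
        for rec in ds.records:
            rec.R1_err, rec.R2_err, rec.NOE_err = 0.01, 0.1, 0.01
        mf1 = fit_model_free(ds, mc_reps=2, seed=0)
        for rec in ds.records:
            rec.R1_err, rec.R2_err, rec.NOE_err = 0.05, 0.5, 0.05
        mf2 = fit_model_free(ds, mc_reps=2, seed=0)
        np.testing.assert_allclose(mf1.S2, mf2.S2, rtol=1e-9)

    def test_mc_errors_reproducible(self, paf_regime_relaxation):
        mf1 = fit_model_free(paf_regime_relaxation, mc_reps=25, seed=7)
        mf2 = fit_model_free(paf_regime_relaxation, mc_reps=25, seed=7)
        assert mf1.tau_c_err_ns == mf2.tau_c_err_ns
        np.testing.assert_array_equal(mf1.S2_err, mf2.S2_err)

    def test_s2_bounds_respected(self, paf_regime_relaxation):
        mf = fit_model_free(paf_regime_relaxation, mc_reps=2, seed=0)
        assert np.all(mf.S2 >= 0.0)
        assert np.all(mf.S2 <= 1.0)


class TestExchangeScreen:
    def test_no_rex_no_flags(self):
        ds = simulate_relaxation(RelaxSimSpec(
            n_residues=40, s2_mean=0.87, s2_sd=0.0, tau_c_ns=7.7, noise_sd=0.0))
        screen = exchange_screen_r1r2(ds)
        assert screen.flagged.sum() == 0

    def test_single_injected_rex_flagged(self):
        ds = simulate_relaxation(RelaxSimSpec(
            n_residues=40, s2_mean=0.87, s2_sd=0.0, tau_c_ns=7.7,
            rex_residues={17: 5.0}, noise_sd=0.0))
        screen = exchange_screen_r1r2(ds)
        flagged = screen.residues[screen.flagged]
        assert list(flagged) == [17]

    def test_product_error_propagation_matches_mc(self):
        # analytic error vs Monte-Carlo of the product for one record
        rng = np.random.default_rng(0)
        R1, R1e, R2, R2e = 1.5, 0.03, 10.0, 0.2
        mc = (R1 + rng.normal(0, R1e, 40000)) * (R2 + rng.normal(0, R2e, 40000))
        ds = simulate_relaxation(RelaxSimSpec(
            n_residues=10, s2_mean=0.87, s2_sd=0.0, noise_sd=0.0))
        ds.records[0].R1, ds.records[0].R1_err = R1, R1e
        ds.records[0].R2, ds.records[0].R2_err = R2, R2e
        screen = exchange_screen_r1r2(ds)
        assert screen.product_err[0] == pytest.approx(np.std(mc), rel=0.05)

    def test_rex_raises_statistic_by_expected_amount(self):
        base = simulate_relaxation(RelaxSimSpec(
            n_residues=20, s2_mean=0.87, s2_sd=0.0, noise_sd=0.0))
        withx = simulate_relaxation(RelaxSimSpec(
            n_residues=20, s2_mean=0.87, s2_sd=0.0, noise_sd=0.0,
            rex_residues={5: 5.0}))
        s0 = exchange_screen_r1r2(base)
        s1 = exchange_screen_r1r2(withx)
        i = list(s1.residues).index(5)
        R1 = base.records[i].R1
        assert s1.product[i] - s0.product[i] == pytest.approx(5.0 * R1, rel=1e-9)
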