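"""Lipari-Szabo spectral density, rate prediction and model-free fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from akfray.constants import GAMMA_H, GAMMA_N, PhysicalConstants
from akfray.modelfree import (
    DiffusionModel,
    ModelFreeParams,
    axial_tau_eff,
    chi2,
    estimate_tau_m,
    fit_residue,
    local_tau_m,
    optimize_tau_m,
    predict_rates,
    spectral_density,
)
from akfray.relaxation import RelaxationRecord


def record_from_truth(s2, tau_e_ps, tau_m_ns, consts, rel_err=0.01, noise=0.0, seed=0):
    p = ModelFreeParams(s2=s2, tau_e_ps=tau_e_ps, tau_m_ns=tau_m_ns)
    t1, t2, noe = predict_rates(p, consts)
    rng = np.random.default_rng(seed)
    if noise > 0:
        t1 += rng.normal(0, noise * t1)
        t2 += rng.normal(0, noise * t2)
        noe += rng.normal(0, noise)
    return RelaxationRecord(
        residue=1, t1=t1, t1_err=rel_err * t1, t2=t2, t2_err=rel_err * t2,
        noe=noe, noe_err=max(rel_err, noise), field_mhz=consts.field_mhz,
    )


class TestSpectralDensity:
    def test_rigid_limit_single_lorentzian(self):
        p = ModelFreeParams(s2=1.0, tau_e_ps=500.0, tau_m_ns=9.0, model="M1")
        tm = 9e-9
        for w in (0.0, 1e8, 5e9):
            assert spectral_density(p, w) == pytest.approx(tm / (1 + (w * tm) ** 2))

    def test_zero_frequency_fast_internal_limit(self):
        p = ModelFreeParams(s2=0.7, tau_e_ps=1e-6, tau_m_ns=9.0)
        assert spectral_density(p, 0.0) == pytest.approx(0.7 * 9e-9, rel=1e-3)

    def test_hand_evaluated_value(self):
        """Direct arithmetic evaluation of the two-Lorentzian form at
        omega = 2 pi * 86.15 MHz for S2=0.85, tau_m=9 ns, tau_e=50 ps."""
        w = 2 * math.pi * 86.15e6
        tm, te, s2 = 9e-9, 50e-12, 0.85
        tau = 1.0 / (1.0 / tm + 1.0 / te)
        expected = s2 * tm / (1 + (w * tm) ** 2) + (1 - s2) * tau / (1 + (w * tau) ** 2)
        p = ModelFreeParams(s2=0.85, tau_e_ps=50.0, tau_m_ns=9.0)
        assert spectral_density(p, w) == pytest.approx(expected, rel=1e-12)

    @given(
        s2=st.floats(0.01, 1.0),
        te=st.floats(1.0, 2000.0),
        tm=st.floats(1.0, 30.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_decreasing_and_nonnegative(self, s2, te, tm):
        p = ModelFreeParams(s2=s2, tau_e_ps=te, tau_m_ns=tm)
        w = np.linspace(0.0, 6e9, 200)
        j = spectral_density(p, w)
        assert np.all(j >= 0)
        assert np.all(np.diff(j) < 0)

    def test_extended_model_reduces_to_simple_when_sf2_is_one(self):
        simple = ModelFreeParams(s2=0.8, tau_e_ps=300.0, tau_m_ns=9.0, model="M2")
        ext = ModelFreeParams(
            s2=0.8, tau_e_ps=300.0, tau_m_ns=9.0, model="M5", sf2=1.0, ss2=0.8
        )
        w = np.linspace(0, 6e9, 50)
        assert np.allclose(spectral_density(simple, w), spectral_density(ext, w))

    def test_invalid_s2_rejected(self):
        with pytest.raises(ValueError):
            ModelFreeParams(s2=1.2, tau_m_ns=9.0)


class TestPredictRates:
    def test_extreme_narrowing_dipolar_t1_equals_t2(self):
        """With dipolar relaxation only, T1/T2 -> 1 as tau_m -> 0."""
        c = PhysicalConstants(850.0, csa_ppm=0.0)
        p = ModelFreeParams(s2=1.0, tau_e_ps=0.0, tau_m_ns=1e-4, model="M1")
        t1, t2, _ = predict_rates(p, c)
        assert t1 / t2 == pytest.approx(1.0, rel=1e-6)

    def test_extreme_narrowing_with_csa_ratio(self):
        """CSA relaxes T2 7/6 times faster than T1 in the narrowing limit,
        shifting the ratio to (2.5 d2 + 7 c2/6)/(2.5 d2 + c2)."""
        c = PhysicalConstants(850.0)
        p = ModelFreeParams(s2=1.0, tau_e_ps=0.0, tau_m_ns=1e-4, model="M1")
        t1, t2, _ = predict_rates(p, c)
        expected = (2.5 * c.d2 + (7.0 / 6.0) * c.c2) / (2.5 * c.d2 + c.c2)
        assert t1 / t2 == pytest.approx(expected, rel=1e-5)

    def test_noe_narrowing_limit(self):
        """Dipolar-only NOE tends to the canonical 1 + gammaH/(2 gammaN)."""
        c = PhysicalConstants(850.0, csa_ppm=0.0)
        p = ModelFreeParams(s2=1.0, tau_e_ps=0.0, tau_m_ns=1e-5, model="M1")
        _, _, noe = predict_rates(p, c)
        assert noe == pytest.approx(1.0 + 0.5 * GAMMA_H / GAMMA_N, rel=1e-5)

    def test_t2_strictly_decreasing_in_tau_m(self, consts850):
        t2s = [
            predict_rates(ModelFreeParams(s2=0.85, tau_e_ps=50.0, tau_m_ns=tm), consts850)[1]
            for tm in np.linspace(2.0, 25.0, 24)
        ]
        assert np.all(np.diff(t2s) < 0)

    def test_invalid_field_rejected(self):
        with pytest.raises(ValueError):
            PhysicalConstants(field_mhz=-600.0)


class TestChi2:
    def test_zero_at_exact_prediction(self, consts850):
        p = ModelFreeParams(s2=0.85, tau_e_ps=50.0, tau_m_ns=9.0)
        rec = record_from_truth(0.85, 50.0, 9.0, consts850)
        assert chi2(p, rec, consts850) == pytest.approx(0.0, abs=1e-18)

    def test_one_sigma_offset_gives_unit_chi2(self, consts850):
        p = ModelFreeParams(s2=0.85, tau_e_ps=50.0, tau_m_ns=9.0)
        rec = record_from_truth(0.85, 50.0, 9.0, consts850)
        rec.t1 += rec.t1_err
        assert chi2(p, rec, consts850) == pytest.approx(1.0, rel=1e-9)

    def test_equals_sum_of_squared_zscores(self, consts850, rng):
        p = ModelFreeParams(s2=0.7, tau_e_ps=120.0, tau_m_ns=11.0)
        t1c, t2c, noec = predict_rates(p, consts850)
        rec = RelaxationRecord(1, 1.1, 0.02, 0.08, 0.003, 0.6, 0.03)
        expected = (
            ((rec.t1 - t1c) / rec.t1_err) ** 2
            + ((rec.t2 - t2c) / rec.t2_err) ** 2
            + ((rec.noe - noec) / rec.noe_err) ** 2
        )
        assert chi2(p, rec, consts850) == pytest.approx(expected, rel=1e-12)

    def test_zero_sigma_rejected(self, consts850):
        rec = RelaxationRecord(1, 1.0, 0.0, 0.08, 0.01, 0.8, 0.02)
        with pytest.raises(ValueError):
            chi2(ModelFreeParams(s2=0.9, tau_m_ns=9.0), rec, consts850)


class TestDiffusionEstimation:
    def test_isotropic_recovery(self, consts850):
        recs = [
            record_from_truth(s2, 50.0, 9.0, consts850, noise=0.005, seed=i)
            for i, s2 in enumerate(np.linspace(0.8, 0.95, 15))
        ]
        for i, r in enumerate(recs):
            r.residue = i + 1
        diff = estimate_tau_m(recs, consts850)
        tau = optimize_tau_m(recs, consts850, diff.tau_m_ns)
        assert diff.kind == "isotropic"
        assert tau == pytest.approx(9.0, rel=0.02)

    def test_identical_ratios_give_exact_isotropic_tau(self, consts850):
        recs = []
        for i in range(12):
            r = record_from_truth(1.0, 0.0, 9.0, consts850)
            r.residue = i + 1
            recs.append(r)
        diff = estimate_tau_m(recs, consts850)
        assert diff.kind == "isotropic"
        assert diff.tau_m_ns == pytest.approx(9.0, rel=1e-4)

    def test_too_few_rigid_residues_rejected(self, consts850):
        recs = [record_from_truth(0.9, 50.0, 9.0, consts850)]
        recs[0].residue = 1
        with pytest.raises(ValueError, match="rigid residues"):
            estimate_tau_m(recs, consts850)

    def test_axial_anisotropy_recovery(self, consts850):
        """Records generated with a Woessner axially symmetric tensor
        (D_par/D_perp = 1.3) recover the ratio within 10%."""
        rng = np.random.default_rng(4)
        axis = np.array([0.0, 0.0, 1.0])
        recs, vecs = [], {}
        for i in range(30):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            alpha = math.acos(abs(v @ axis))
            tau_eff = axial_tau_eff(9.0, 1.3, alpha)
            r = record_from_truth(0.9, 0.0, tau_eff, consts850, noise=0.002, seed=i)
            r.residue = i + 1
            recs.append(r)
            vecs[i + 1] = v
        diff = estimate_tau_m(recs, consts850, nh_vectors=vecs)
        assert diff.kind == "axial"
        assert diff.ratio == pytest.approx(1.3, rel=0.10)
        assert abs(diff.axis @ axis) > 0.95

    def test_local_tau_m_inverts_ratio(self, consts850):
        rec = record_from_truth(1.0, 0.0, 12.0, consts850)
        assert local_tau_m(rec, consts850) == pytest.approx(12.0, rel=1e-4)


class TestFitResidue:
    def test_noiseless_recovery_selects_m2(self, consts850):
        rec = record_from_truth(0.85, 50.0, 9.0, consts850)
        diff = DiffusionModel("isotropic", 9.0)
        res = fit_residue(rec, diff, consts850, n_mc=0)
        assert res.ok and res.model == "M2"
        assert res.params.s2 == pytest.approx(0.85, abs=1e-4)
        assert res.params.tau_e_ps == pytest.approx(50.0, rel=0.01)

    def test_rigid_truth_selects_m1_at_bound(self, consts850):
        rec = record_from_truth(1.0, 0.0, 9.0, consts850)
        diff = DiffusionModel("isotropic", 9.0)
        res = fit_residue(rec, diff, consts850, n_mc=0)
        assert res.model == "M1"
        assert res.params.s2 == pytest.approx(1.0, abs=1e-6)

    def test_chi2_at_optimum_not_above_truth_chi2(self, consts850):
        rec = record_from_truth(0.7, 200.0, 9.0, consts850)
        diff = DiffusionModel("isotropic", 9.0)
        res = fit_residue(rec, diff, consts850, n_mc=0)
        truth = ModelFreeParams(s2=0.7, tau_e_ps=200.0, tau_m_ns=9.0)
        assert res.chi2 <= chi2(truth, rec, consts850) + 1e-9

    def test_optimizer_beats_grid_oracle(self, consts850):
        """Fitted chi2 must be <= the best point on a dense (S2, tau_e)
        lattice at fixed tau_m, for 20 seeded noisy records."""
        diff = DiffusionModel("isotropic", 9.0)
        s2g = np.linspace(0.0, 1.0, 200)
        teg = np.linspace(0.0, 2000.0, 200)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            s2 = rng.uniform(0.5, 0.95)
            te = rng.uniform(10.0, 500.0)
            rec = record_from_truth(s2, te, 9.0, consts850, noise=0.01, seed=seed)
            res = fit_residue(rec, diff, consts850, n_mc=0)
            best = _grid_chi2(rec, consts850, 9.0, s2g, teg)
            assert res.chi2 <= best + 1e-6

    def test_mc_errors_positive_for_noisy_record(self, consts850):
        rec = record_from_truth(0.85, 50.0, 9.0, consts850, noise=0.01, seed=3)
        diff = DiffusionModel("isotropic", 9.0)
        res = fit_residue(rec, diff, consts850, n_mc=50, rng=np.random.default_rng(0))
        assert res.s2_err > 0


def _grid_chi2(rec, c, tau_m_ns, s2_grid, te_grid):
    """Vectorized brute-force chi2 lattice, written independently of the
    package's forward code path."""
    wh = 2 * math.pi * c.field_mhz * 1e6
    wn = wh * abs(GAMMA_N) / GAMMA_H
    freqs = np.array([0.0, wn, wh - wn, wh, wh + wn])
    tm = tau_m_ns * 1e-9
    s2 = s2_grid[:, None, None]
    te = np.maximum(te_grid[None, :, None] * 1e-12, 1e-20)
    tau = 1.0 / (1.0 / tm + 1.0 / te)
    w = freqs[None, None, :]
    j = 0.4 * (s2 * tm / (1 + (w * tm) ** 2) + (1 - s2) * tau / (1 + (w * tau) ** 2))
    j0, jn, jhmn, jh, jhpn = (j[..., k] for k in range(5))
    d2, c2 = c.d2, c.c2
    r1 = (d2 / 4) * (jhmn + 3 * jn + 6 * jhpn) + c2 * jn
    r2 = (d2 / 8) * (4 * j0 + jhmn + 3 * jn + 6 * jh + 6 * jhpn) + (c2 / 6) * (
        4 * j0 + 3 * jn
    )
    noe = 1.0 + (GAMMA_H / GAMMA_N) * (d2 / 4) * (6 * jhpn - jhmn) / r1
    x2 = (
        ((rec.t1 - 1 / r1) / rec.t1_err) ** 2
        + ((rec.t2 - 1 / r2) / rec.t2_err) ** 2
        + ((rec.noe - noe) / rec.noe_err) ** 2
    )
    return float(x2.min())
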