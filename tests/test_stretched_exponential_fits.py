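"""Gamma- and alpha-exponent estimators: forward-inverse consistency,
limits, noise behavior and the estimator contract."""

import numpy as np
import pytest

from tadmri import (
    AlphaDecayModel,
    GammaDecayModel,
    add_rician_noise,
    q_from_b,
)
from tadmri.protocol import ALPHA_DELTAS, ALPHA_RG


def gamma_q_grid(gamma_proto, direction=0):
    vols = gamma_proto.volumes()
    sub = vols[vols.direction_index == direction]
    return q_from_b(sub["b_s_mm2"].to_numpy(), gamma_proto.delta,
                    sub["Delta_ms"].to_numpy(), "radian")  # rad/mm


def eq15_signal(q_rad_mm, gamma, dgen_si, Delta_ms=40.0, amplitude=0.85,
                offset=0.15):
    q_si = q_rad_mm * 1e3
    return amplitude * np.exp(-dgen_si * q_si ** (2 * gamma)
                              * Delta_ms * 1e-3) + offset


def dgen_at(attenuation, gamma, q_max_rad_mm, Delta_ms=40.0):
    return attenuation / ((q_max_rad_mm * 1e3) ** (2 * gamma) * Delta_ms * 1e-3)


class TestGammaDecayModel:
    @pytest.mark.parametrize("gamma_true", [0.6, 0.8, 0.95])
    def test_noiseless_recovery(self, gamma_proto, gamma_true):
        q = gamma_q_grid(gamma_proto)
        dg = dgen_at(3.0, gamma_true, q.max())
        S = eq15_signal(q, gamma_true, dg)
        est = GammaDecayModel().fit(q, S)
        assert est.valid_ and est.converged_
        assert est.gamma_ == pytest.approx(gamma_true, abs=1e-3)
        assert est.dgen_ == pytest.approx(dg, rel=1e-2)

    def test_gaussian_limit_hits_upper_bound(self, gamma_proto):
        """Normal diffusion: p3 runs to its bound of 2 (gamma = 1)."""
        q = gamma_q_grid(gamma_proto)
        S = eq15_signal(q, 1.0, dgen_at(3.0, 1.0, q.max()))
        est = GammaDecayModel().fit(q, S)
        assert est.p3_ == pytest.approx(2.0, abs=1e-3)
        assert est.at_bound_

    def test_amplitude_scale_only_changes_p1(self, gamma_proto):
        """Free amplitude: scaling the offset-free part leaves gamma alone."""
        q = gamma_q_grid(gamma_proto)
        dg = dgen_at(3.0, 0.8, q.max())
        S = eq15_signal(q, 0.8, dg)
        S_scaled = (S - 0.15) * 1.7 + 0.15
        a = GammaDecayModel().fit(q, S)
        b = GammaDecayModel().fit(q, S_scaled)
        assert b.gamma_ == pytest.approx(a.gamma_, abs=1e-6)
        assert b.amplitude_ == pytest.approx(1.7 * a.amplitude_, rel=1e-4)

    def test_d0_term_absorbed_by_amplitude(self, gamma_proto):
        """The baseline D0*q0^2 correction rescales p1, never gamma."""
        q = gamma_q_grid(gamma_proto)
        S = eq15_signal(q, 0.75, dgen_at(3.0, 0.75, q.max()))
        plain = GammaDecayModel(d0=0.0).fit(q, S)
        corrected = GammaDecayModel(d0=0.7e-3).fit(q, S)
        assert corrected.gamma_ == pytest.approx(plain.gamma_, abs=1e-6)
        assert corrected.amplitude_ > plain.amplitude_

    def test_rician_noise_median_error(self, gamma_proto):
        q = gamma_q_grid(gamma_proto)
        dg = dgen_at(3.0, 0.8, q.max())
        S = eq15_signal(q, 0.8, dg)
        errs = []
        for seed in range(30):
            noisy = add_rician_noise(S, snr=30, seed=seed)
            est = GammaDecayModel().fit(q, noisy)
            errs.append(abs(est.gamma_ - 0.8))
        assert np.median(errs) <= 0.08

    def test_estimator_sd_decreases_with_snr(self, gamma_proto):
        """Monotone bias/variance: SD of gamma-hat falls as SNR rises."""
        q = gamma_q_grid(gamma_proto)
        S = eq15_signal(q, 0.8, dgen_at(3.0, 0.8, q.max()))
        sds = []
        for snr in (10, 20, 40, 80):
            vals = [GammaDecayModel().fit(
                q, add_rician_noise(S, snr=snr, seed=seed)).gamma_
                for seed in range(25)]
            sds.append(np.std(vals))
        assert sds == sorted(sds, reverse=True)

    def test_invalid_input_flagged_not_raised(self):
        est = GammaDecayModel().fit(np.full(6, np.nan), np.full(6, np.nan))
        assert not est.valid_
        assert np.isnan(est.gamma_)

    def test_deterministic(self, gamma_proto):
        q = gamma_q_grid(gamma_proto)
        S = add_rician_noise(eq15_signal(q, 0.7, dgen_at(3.0, 0.7, q.max())),
                             snr=20, seed=0)
        a = GammaDecayModel().fit(q, S)
        b = GammaDecayModel().fit(q, S)
        assert a.gamma_ == b.gamma_ and a.dgen_ == b.dgen_

    def test_sklearn_params_round_trip(self):
        est = GammaDecayModel(Delta=50.0, p4=0.1)
        assert GammaDecayModel(**est.get_params()).get_params() == est.get_params()


def alpha_signal(alpha, dgen=0.7e-3, q0_rad_mm=None, t1_ms=None):
    Delta = np.asarray(ALPHA_DELTAS)
    dt = Delta * 1e-3
    S = np.exp(-dgen * q0_rad_mm**2 * dt**alpha)
    if t1_ms is not None:
        S = S * np.exp(-Delta / t1_ms)
    return Delta, S


@pytest.fixture(scope="module")
def q0(alpha_proto):
    vols = alpha_proto.volumes()
    sub = vols[vols.direction_index == 0]
    q = q_from_b(sub["b_s_mm2"].to_numpy(), alpha_proto.delta,
                 sub["Delta_ms"].to_numpy(), "radian")
    return float(np.sqrt(np.mean(q**2)))


class TestAlphaDecayModel:
    @pytest.mark.parametrize("alpha_true", [0.6, 0.75, 1.0])
    def test_noiseless_recovery(self, q0, alpha_true):
        Delta, S = alpha_signal(alpha_true, q0_rad_mm=q0)
        est = AlphaDecayModel(q0=q0).fit(Delta, S)
        assert est.alpha_ == pytest.approx(alpha_true, abs=1e-3)
        assert est.dgen_ == pytest.approx(0.7e-3, rel=1e-3)

    def test_t1_corrected_fit_recovers_exactly(self, q0):
        Delta, S = alpha_signal(0.75, q0_rad_mm=q0, t1_ms=760.0)
        est = AlphaDecayModel(q0=q0, t1_correction=True, t1=760.0).fit(Delta, S)
        assert est.alpha_ == pytest.approx(0.75, abs=1e-3)

    def test_t1_factor_absorbed_when_alpha_is_one(self, q0):
        """At alpha = 1 the Delta/T1 decay folds into the stretched term:
        fits with and without the known T1 factor agree on alpha exactly
        (the only regime where that absorption is algebraically possible;
        amplitude and diffusion constant differ)."""
        Delta, S = alpha_signal(1.0, q0_rad_mm=q0, t1_ms=760.0)
        on = AlphaDecayModel(q0=q0, t1_correction=True, t1=760.0).fit(Delta, S)
        off = AlphaDecayModel(q0=q0).fit(Delta, S)
        assert on.alpha_ == pytest.approx(1.0, abs=1e-3)
        assert off.alpha_ == pytest.approx(on.alpha_, abs=1e-3)
        assert off.dgen_ > on.dgen_  # absorbs 1/T1

    def test_uncorrected_fit_biased_at_low_alpha(self, q0):
        """Without the T1 factor the linear Delta/T1 term drags the
        stretching exponent upward when alpha < 1."""
        Delta, S = alpha_signal(0.7, q0_rad_mm=q0, t1_ms=760.0)
        off = AlphaDecayModel(q0=q0).fit(Delta, S)
        assert off.alpha_ > 0.75

    def test_nonpositive_samples_dropped(self, q0):
        Delta, S = alpha_signal(0.8, q0_rad_mm=q0)
        S = S.copy()
        S[2] = 0.0
        est = AlphaDecayModel(q0=q0).fit(Delta, S)
        assert est.valid_
        assert est.n_dropped_ == 1
        assert est.alpha_ == pytest.approx(0.8, abs=1e-3)

    def test_too_few_samples_invalid(self, q0):
        est = AlphaDecayModel(q0=q0).fit(np.array([40.0, 60, 80, 150]),
                                         np.array([1.0, 0.9, 0.8, 0.7]))
        assert not est.valid_

    def test_scale_equivariance(self, q0):
        Delta, S = alpha_signal(0.8, q0_rad_mm=q0)
        a = AlphaDecayModel(q0=q0).fit(Delta, S)
        b = AlphaDecayModel(q0=q0).fit(Delta, 3.3 * S)
        assert b.alpha_ == pytest.approx(a.alpha_, abs=1e-9)
        assert b.amplitude_ == pytest.approx(3.3 * a.amplitude_, rel=1e-6)

    def test_rg_schedule_round_trip(self, q0):
        """RG-scaled signal divided by the RG ratio reproduces the
        unscaled series to machine precision."""
        Delta, S = alpha_signal(0.8, q0_rad_mm=q0)
        rg = np.asarray(ALPHA_RG)
        scaled = S * rg / rg[0]
        unscaled = scaled * rg[0] / rg
        assert np.allclose(unscaled, S, rtol=1e-12)

    def test_squared_dgen_variant(self, q0):
        """The p2^2 reading of the fit expression recovers sqrt(Dgen)."""
        Delta, S = alpha_signal(0.8, dgen=0.7e-3, q0_rad_mm=q0)
        est = AlphaDecayModel(q0=q0, squared_dgen=True).fit(Delta, S)
        assert est.alpha_ == pytest.approx(0.8, abs=1e-3)
        assert est.dgen_ == pytest.approx(0.7e-3, rel=1e-3)
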