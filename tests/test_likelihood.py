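"""Likelihood contributions, the false-zero integral and its quadrature."""

import numpy as np
import pytest
from scipy.integrate import quad as adaptive_quad
from scipy.special import betainc, expit
from scipy.stats import norm

from marzic.core import (
    MediationDataset,
    ModelParams,
    OutcomeParams,
    SubjectRecord,
    ZIBParams,
    zib_logpdf,
    outcome_mean,
)
from marzic.likelihood import (
    QuadratureSpec,
    integrate_h,
    log_integral_h,
    loglik_nonzero,
    loglik_zero,
    total_loglik,
)


def _h_oracle(rec, params):
    """Adaptive-quadrature oracle for the false-zero integral."""
    o, med = params.outcome, params.mediator
    mu = med.mu(rec.x)
    aa, bb = mu * med.phi, (1 - mu) * med.phi

    def h(m):
        mean = (o.beta0 + o.beta1 * m + o.beta2
                + (o.beta3 + o.beta4) * rec.x + o.beta5 * rec.x * m)
        return (m ** (aa - 1) * (1 - m) ** (bb - 1)
                * np.exp(-(rec.y - mean) ** 2 / (2 * o.delta ** 2)))

    upper = min(1.0 / rec.lib_size, 1.0 - 1e-12)
    val, err = adaptive_quad(h, 0, upper, points=[0], limit=400)
    return val


class TestIntegrateH:
    def test_uniform_kernel_closed_form(self, uniform_zib_params):
        rec = SubjectRecord(y=0.0, m_obs=0.0, r=0, lib_size=10, x=0.0)
        assert integrate_h(rec, uniform_zib_params) == pytest.approx(0.1, rel=1e-12)

    def test_constant_gaussian_factor(self, uniform_zib_params):
        rec = SubjectRecord(y=1.0, m_obs=0.0, r=0, lib_size=10, x=0.0)
        expected = np.exp(-0.5) * 0.1
        assert integrate_h(rec, uniform_zib_params) == pytest.approx(expected, rel=1e-12)

    def test_incomplete_beta_closed_form_when_betas_zero(self, low_ra_params):
        """With a flat Gaussian factor the integral is an incomplete Beta."""
        med = low_ra_params.mediator
        params = ModelParams(
            outcome=OutcomeParams(0, 0, 0, 0, 0, 0, delta=1.0), mediator=med)
        rec = SubjectRecord(y=0.0, m_obs=0.0, r=0, lib_size=31607, x=1.0)
        mu = med.mu(1.0)
        aa, bb = mu * med.phi, (1 - mu) * med.phi
        from scipy.special import betaln
        expected = float(
            betainc(aa, bb, 1.0 / 31607) * np.exp(betaln(aa, bb)))
        assert integrate_h(rec, params) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_adaptive_oracle(self, seed):
        """Fixed-order rule after the substitution vs adaptive refinement."""
        rng = np.random.default_rng(seed)
        params = ModelParams(
            outcome=OutcomeParams(*rng.normal(0, 2, 6), delta=rng.uniform(0.5, 3)),
            mediator=ZIBParams(alpha0=rng.uniform(-7, 0), alpha1=rng.normal(),
                               phi=rng.uniform(0.2, 60), gamma0=rng.normal(),
                               gamma1=rng.normal()),
        )
        rec = SubjectRecord(y=rng.normal(0, 3), m_obs=0.0, r=0,
                            lib_size=int(rng.uniform(50, 10**6)), x=rng.binomial(1, 0.5))
        mine = integrate_h(rec, params)
        oracle = _h_oracle(rec, params)
        assert mine == pytest.approx(oracle, rel=1e-8)

    def test_strong_singularity(self):
        """mu*phi = 0.1 puts a hard endpoint singularity at zero."""
        params = ModelParams(
            outcome=OutcomeParams(0.5, 2.0, 0.3, -0.2, 0.1, 0.4, delta=1.3),
            mediator=ZIBParams(alpha0=-6.2, alpha1=0.4, phi=50.0,
                               gamma0=-1.16, gamma1=-0.5))
        rec = SubjectRecord(y=1.7, m_obs=0.0, r=0, lib_size=31607, x=1.0)
        assert integrate_h(rec, params) == pytest.approx(_h_oracle(rec, params),
                                                         rel=1e-8)

    def test_node_count_convergence(self):
        """32 vs 128 nodes agree to 1e-9 relative on a random grid."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            theta = np.concatenate([
                rng.normal(0, 1, 6), [rng.uniform(0.5, 2)],
                [rng.uniform(-6, 0)], [rng.normal()], [rng.uniform(0.5, 40)],
                [rng.normal()], [rng.normal()]])
            y = np.array([rng.normal()])
            x = np.array([float(rng.binomial(1, 0.5))])
            lib = np.array([rng.uniform(100, 10**6)])
            v32 = log_integral_h(theta, y, x, lib, QuadratureSpec(32))
            v128 = log_integral_h(theta, y, x, lib, QuadratureSpec(128))
            assert v32[0] == pytest.approx(v128[0], rel=1e-9, abs=1e-9)

    def test_degenerate_library_size(self, uniform_zib_params):
        # 1/L > 1: integrate over (0, 1) instead
        rec = SubjectRecord(y=0.0, m_obs=0.0, r=0, lib_size=0.5, x=0.0)
        assert integrate_h(rec, uniform_zib_params) == pytest.approx(1.0, rel=1e-9)


class TestLoglikContributions:
    def test_nonzero_uniform_example(self, uniform_zib_params):
        rec = SubjectRecord(y=0.0, m_obs=0.5, r=1, lib_size=10, x=0.0)
        expected = -0.5 * np.log(2 * np.pi) + np.log(0.8)
        assert loglik_nonzero(rec, uniform_zib_params) == pytest.approx(
            expected, abs=1e-9)

    def test_nonzero_is_normal_plus_zib(self, low_ra_params):
        """Definitional decomposition on random admissible inputs."""
        rng = np.random.default_rng(3)
        o = low_ra_params.outcome
        for _ in range(100):
            rec = SubjectRecord(y=rng.normal(0, 5), m_obs=rng.uniform(1e-4, 0.9),
                                r=1, lib_size=10**6, x=float(rng.binomial(1, 0.5)))
            expected = (norm.logpdf(rec.y, outcome_mean(o, rec.m_obs, rec.x), o.delta)
                        + zib_logpdf(rec.m_obs, low_ra_params.mediator, rec.x))
            assert loglik_nonzero(rec, low_ra_params) == pytest.approx(
                expected, abs=1e-10)

    def test_zero_mixture_example(self, uniform_zib_params):
        rec = SubjectRecord(y=0.0, m_obs=0.0, r=0, lib_size=10, x=0.0)
        expected = -0.5 * np.log(2 * np.pi) + np.log(0.2 + 0.8 * 0.1)
        assert loglik_zero(rec, uniform_zib_params) == pytest.approx(expected, abs=1e-9)

    def test_zero_reduces_to_normal_when_all_structural(self):
        """Delta = 1 leaves only the true-zero branch: a plain normal term."""
        params = ModelParams(
            outcome=OutcomeParams(1.0, 2.0, 3.0, -1.0, 0.5, 0.0, delta=2.0),
            mediator=ZIBParams(alpha0=-1, alpha1=0, phi=5, gamma0=50.0, gamma1=0.0))
        rec = SubjectRecord(y=0.7, m_obs=0.0, r=0, lib_size=1000, x=1.0)
        expected = norm.logpdf(0.7, 1.0 - 1.0, 2.0)
        assert loglik_zero(rec, params) == pytest.approx(expected, abs=1e-8)

    def test_zero_huge_library_kills_false_zero_branch(self, uniform_zib_params):
        rec = SubjectRecord(y=0.0, m_obs=0.0, r=0, lib_size=1e12, x=0.0)
        expected = norm.logpdf(0.0, 0.0, 1.0) + np.log(0.2)
        assert loglik_zero(rec, uniform_zib_params) == pytest.approx(expected, abs=1e-6)

    def test_contract_violations(self, uniform_zib_params):
        from marzic.core import MarzicError
        pos = SubjectRecord(y=0.0, m_obs=0.4, r=1, lib_size=10, x=0.0)
        zero = SubjectRecord(y=0.0, m_obs=0.0, r=0, lib_size=10, x=0.0)
        with pytest.raises(MarzicError):
            loglik_zero(pos, uniform_zib_params)
        with pytest.raises(MarzicError):
            loglik_nonzero(zero, uniform_zib_params)


class TestTotalLoglik:
    def test_equals_per_record_sum(self, small_low_ra_dataset, low_ra_params):
        data, _, _ = small_low_ra_dataset
        subset = MediationDataset(records=data.records[:10])
        total = total_loglik(subset, low_ra_params)
        brute = sum(
            loglik_nonzero(r, low_ra_params) if r.r
            else loglik_zero(r, low_ra_params)
            for r in subset.records)
        assert total == pytest.approx(brute, abs=1e-9)

    def test_additivity_under_duplication(self, small_low_ra_dataset, low_ra_params):
        data, _, _ = small_low_ra_dataset
        subset = MediationDataset(records=data.records[:20])
        doubled = MediationDataset(records=subset.records * 2)
        assert total_loglik(doubled, low_ra_params) == pytest.approx(
            2 * total_loglik(subset, low_ra_params), rel=1e-12)

    @pytest.mark.filterwarnings("ignore::UserWarning")
    @pytest.mark.filterwarnings(
        "ignore::scipy.integrate.IntegrationWarning")
    def test_joint_density_has_total_probability_one(self, low_ra_params):
        """Integrating exp(loglik) over all (y, m*) outcomes gives 1.

        The observed-zero term carries the whole m* = 0 slice; the
        observed-positive term is integrated over m* in (1/L, 1) because
        the LOD rule makes smaller abundances unobservable.
        """
        lib, x = 5000.0, 1.0

        def zero_slice(y):
            rec = SubjectRecord(y=y, m_obs=0.0, r=0, lib_size=lib, x=x)
            return np.exp(loglik_zero(rec, low_ra_params))

        def pos_slice(y):
            def inner(m):
                rec = SubjectRecord(y=y, m_obs=m, r=1, lib_size=lib, x=x)
                return np.exp(loglik_nonzero(rec, low_ra_params))
            val, _ = adaptive_quad(inner, 1.0 / lib, 1.0, points=[1.0 / lib],
                                   limit=200)
            return val

        total = 0.0
        for f in (zero_slice, pos_slice):
            val, _ = adaptive_quad(f, -30, 40, limit=300)
            total += val
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_smooth_in_parameters(self, small_low_ra_dataset, low_ra_params):
        """Finite-difference slopes are stable: no kinks for the optimizer."""
        data, _, _ = small_low_ra_dataset
        theta0 = low_ra_params.to_vector()
        for i in (0, 7, 10):  # beta0, alpha0, gamma0
            vals = []
            for h in (1e-4, 1e-5):
                tp, tm = theta0.copy(), theta0.copy()
                tp[i] += h
                tm[i] -= h
                from marzic.likelihood import total_loglik_arrays
                y, m, r, L, x = data.arrays()
                vals.append((total_loglik_arrays(tp, y, m, r, L, x)
                             - total_loglik_arrays(tm, y, m, r, L, x)) / (2 * h))
            assert vals[0] == pytest.approx(vals[1], rel=1e-3, abs=1e-6)
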