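"""Bell rates, rupture-force distributions, lifetimes, looping, mixtures."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from mtweez import (
    LoadingProtocol,
    RateParams,
    TwoStateRates,
    bell_rate,
    fit_bell,
    fit_exponential_lifetime,
    fit_looping,
    fit_rupture_mixture,
    looping_probability,
    rupture_force_pdf,
    sample_rupture_forces,
)


class TestBellRate:
    def test_zero_force_gives_k0(self, env23):
        p = RateParams(k0=3.7, delta_x=2.0)
        assert bell_rate(0.0, p, env23) == 3.7

    def test_unit_exponent(self, env23):
        # F*dx = kBT exactly -> one e-fold
        p = RateParams(k0=1.0, delta_x=env23.kBT)
        assert bell_rate(1.0, p, env23) == pytest.approx(np.e, rel=1e-12)

    def test_rate_ratio_identity(self, env23):
        p = RateParams(k0=0.2, delta_x=-13.8)
        ratio = bell_rate(2.9, p, env23) / bell_rate(1.7, p, env23)
        assert ratio == pytest.approx(np.exp(1.2 * -13.8 / env23.kBT), rel=1e-12)

    def test_negative_delta_x_suppressed_by_force(self, env23):
        p = RateParams(k0=1.0, delta_x=-5.0)
        assert bell_rate(3.0, p, env23) < bell_rate(1.0, p, env23)


class TestFitBell:
    def test_exact_on_noiseless_line(self, env23):
        truth = RateParams(k0=0.05, delta_x=1.7)
        forces = np.array([2.0, 5.0, 8.0, 11.0])
        res = fit_bell(forces, bell_rate(forces, truth, env23), env23)
        assert res.k0 == pytest.approx(truth.k0, rel=1e-10)
        assert res.delta_x == pytest.approx(truth.delta_x, rel=1e-10)

    def test_two_point_looping_extrapolation(self, env23):
        # printed looping rates: 0.58 s^-1 at 1.7 pN, 0.01 s^-1 at 2.9 pN
        res = fit_bell([1.7, 2.9], [0.58, 0.01], env23)
        assert res.delta_x == pytest.approx(-13.8, abs=0.1)
        assert res.k0 == pytest.approx(1.8e2, rel=0.05)

    def test_recovery_under_multiplicative_noise(self, env23, rng):
        truth = RateParams(k0=0.02, delta_x=1.5)
        forces = np.array([3.0, 6.0, 9.0, 12.0])
        clean = bell_rate(forces, truth, env23)
        hits = 0
        for _ in range(100):
            noisy = clean * rng.lognormal(0.0, 0.05, size=4)
            res = fit_bell(forces, noisy, env23)
            if (abs(res.k0 - truth.k0) <= 0.1 * truth.k0
                    and abs(res.delta_x - truth.delta_x) <= 0.1 * truth.delta_x):
                hits += 1
        assert hits >= 80

    def test_permutation_invariance(self, env23):
        forces = [2.0, 8.0, 5.0, 11.0]
        rates = [0.1, 1.5, 0.5, 4.0]
        a = fit_bell(forces, rates, env23)
        b = fit_bell(forces[::-1], rates[::-1], env23)
        assert a.k0 == pytest.approx(b.k0)
        assert a.delta_x == pytest.approx(b.delta_x)

    def test_input_validation(self, env23):
        with pytest.raises(ValueError):
            fit_bell([2.0], [0.1], env23)
        with pytest.raises(ValueError):
            fit_bell([2.0, 3.0], [0.1, 0.0], env23)
        with pytest.raises(ValueError):
            fit_bell([2.0, 2.0], [0.1, 0.2], env23)


class TestRuptureForceDistribution:
    def test_normalization(self, env23):
        dist = rupture_force_pdf(LoadingProtocol(1.0, 0.5, 60.0),
                                 RateParams(k0=1.85e-3, delta_x=1.88), env23)
        total, _ = quad(dist.pdf, 0.5, np.inf)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_modal_force_loading_rate_shift(self, env23):
        params = RateParams(k0=1.85e-3, delta_x=1.88)
        slow = rupture_force_pdf(LoadingProtocol(0.2, 0.5, 60.0), params, env23)
        fast = rupture_force_pdf(LoadingProtocol(5.0, 0.5, 60.0), params, env23)
        shift = fast.modal_force - slow.modal_force
        assert shift == pytest.approx(env23.kBT / 1.88 * np.log(25), rel=1e-9)

    def test_mode_is_pdf_argmax(self, env23):
        params = RateParams(k0=1.85e-3, delta_x=1.88)
        dist = rupture_force_pdf(LoadingProtocol(1.0, 0.5, 60.0), params, env23)
        grid = np.linspace(0.5, 40, 20000)
        assert grid[np.argmax(dist.pdf(grid))] == pytest.approx(
            dist.modal_force, abs=0.01)

    def test_sampled_forces_match_cdf(self, env23, rng):
        params = RateParams(k0=1.85e-3, delta_x=1.88)
        protocol = LoadingProtocol(1.0, 0.5, 60.0)
        dist = rupture_force_pdf(protocol, params, env23)
        sample = sample_rupture_forces(protocol, params, env23, 1000, rng)
        assert kstest(sample[~np.isnan(sample)], dist.cdf).pvalue > 0.01

    def test_negative_delta_x_rejected(self, env23):
        with pytest.raises(ValueError):
            rupture_force_pdf(LoadingProtocol(1.0, 0.5, 60.0),
                              RateParams(k0=1.0, delta_x=-1.0), env23)


class TestExponentialLifetime:
    def test_degenerate_sample_and_se_formula(self):
        res = fit_exponential_lifetime([10.0] * 101)
        assert res.tau == 10.0
        assert res.se == pytest.approx(1.0)  # tau / sqrt(n - 1)
        assert res.n == 101

    def test_mle_is_sample_mean(self, rng):
        dwells = rng.exponential(30.0, 100)
        assert fit_exponential_lifetime(dwells).tau == pytest.approx(
            float(np.mean(dwells)))

    def test_histogram_mode_agrees_with_mle(self, rng):
        # binning costs efficiency: the two estimators agree within 15%
        # in the large majority of n=100 samples, not in every one
        agree = sum(
            abs(fit_exponential_lifetime(d, method="histogram").tau
                - fit_exponential_lifetime(d, method="mle").tau)
            <= 0.15 * fit_exponential_lifetime(d, method="mle").tau
            for d in (rng.exponential(30.0, 100) for _ in range(20)))
        assert agree >= 17

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_exponential_lifetime([5.0])
        with pytest.raises(ValueError):
            fit_exponential_lifetime([5.0, -1.0])


class TestLoopingProbability:
    def test_zero_delta_t(self):
        assert looping_probability(0.0, TwoStateRates(0.58, 0.01)) == 0.0

    def test_plateau_limit(self):
        rates = TwoStateRates(0.58, 0.01)
        assert looping_probability(1e6, rates) == pytest.approx(
            0.58 / 0.59, rel=1e-12)

    def test_printed_rate_value(self):
        # k_p=0.58, k_u=0.01, dt=5 s
        assert looping_probability(5.0, TwoStateRates(0.58, 0.01)) == \
            pytest.approx(0.932, abs=5e-4)

    def test_monotone_and_bounded(self):
        rates = TwoStateRates(0.3, 0.05)
        dts = np.linspace(0, 50, 100)
        p = looping_probability(dts, rates)
        assert np.all(np.diff(p) >= 0)
        assert np.all(p <= rates.plateau + 1e-12)


class TestFitLooping:
    def test_exact_recovery_noiseless(self):
        rates = TwoStateRates(0.2, 0.01)
        dts = np.array([1, 2, 5, 10, 20, 40, 80], dtype=float)
        res = fit_looping(dts, looping_probability(dts, rates))
        assert res.k_p == pytest.approx(0.2, abs=1e-6)
        assert res.k_u == pytest.approx(0.01, abs=1e-6)
        assert not res.ill_conditioned

    def test_plateau_identity(self):
        rates = TwoStateRates(0.2, 0.05)
        dts = np.array([1, 3, 8, 20, 50], dtype=float)
        res = fit_looping(dts, looping_probability(dts, rates))
        assert res.plateau == pytest.approx(res.k_p / (res.k_p + res.k_u))

    def test_permutation_invariance(self):
        rates = TwoStateRates(0.2, 0.02)
        dts = np.array([1, 4, 10, 30, 60], dtype=float)
        p = looping_probability(dts, rates)
        a = fit_looping(dts, p)
        b = fit_looping(dts[::-1], p[::-1])
        assert a.k_p == pytest.approx(b.k_p)
        assert a.k_u == pytest.approx(b.k_u)

    def test_unreached_plateau_flagged(self):
        rates = TwoStateRates(0.02, 0.002)  # relaxation time ~45 s
        dts = np.array([1.0, 2.0, 4.0])
        res = fit_looping(dts, looping_probability(dts, rates))
        assert res.ill_conditioned

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_looping([1.0, 2.0, 5.0], [0.0, 0.0, 0.0])


class TestRuptureMixture:
    def test_single_component(self, rng):
        forces = rng.normal(15.0, 1.0, 50)
        res = fit_rupture_mixture(forces, n_components=1)
        assert res.weight_strong == 1.0
        assert res.weak is None
        assert res.strong[0] == pytest.approx(15.0, abs=0.5)

    def test_two_component_recovery(self, rng):
        n_strong = rng.binomial(500, 0.7)
        forces = np.concatenate([rng.normal(20, 2, n_strong),
                                 rng.normal(12, 2, 500 - n_strong)])
        res = fit_rupture_mixture(forces, n_components=2)
        assert res.weight_strong == pytest.approx(0.70, abs=0.05)
        assert res.strong[0] > res.weak[0]
        assert res.converged

    def test_agrees_with_sklearn_reference(self, rng):
        from sklearn.mixture import GaussianMixture

        forces = np.concatenate([rng.normal(20, 2, 350),
                                 rng.normal(12, 2, 150)])
        res = fit_rupture_mixture(forces, n_components=2)
        gm = GaussianMixture(2, random_state=0, n_init=5).fit(forces[:, None])
        strong = int(np.argmax(gm.means_.ravel()))
        assert res.weight_strong == pytest.approx(gm.weights_[strong], abs=0.02)
        assert res.strong[0] == pytest.approx(gm.means_.ravel()[strong], abs=0.3)

    def test_permutation_invariance(self, rng):
        forces = np.concatenate([rng.normal(20, 2, 70), rng.normal(12, 2, 30)])
        a = fit_rupture_mixture(forces)
        b = fit_rupture_mixture(forces[::-1])
        assert a.weight_strong == b.weight_strong
        assert a.strong == b.strong

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_rupture_mixture(np.arange(10.0), n_components=2)
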