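"""Force-dependent transition kinetics.

Single-barrier (Bell/Arrhenius) rate law, rupture-force distributions under
a constant loading rate, exponential dwell-time statistics, two-state
looping kinetics, and two-population rupture-force mixtures.

The rate of a force-dependent transition is modeled as

    k(F) = k0 · exp(F·Δx / kBT),

with k0 the zero-force rate and Δx the (signed) transition distance:
positive Δx means the transition is accelerated by force (rupture,
unfolding), negative Δx that it is suppressed (loop formation, refolding).

Fitting operations follow a Model → fit() → Results pattern; every Results
object carries the estimates, their standard errors, and a ``summary()``
table.  Convenience functions (``fit_bell``, ``fit_exponential_lifetime``,
``fit_looping``, ``fit_rupture_mixture``) construct the model and fit it in
one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import norm

from .polymer import Environment

__all__ = [
    "RateParams",
    "TwoStateRates",
    "DwellSample",
    "LoadingProtocol",
    "RuptureMixture",
    "bell_rate",
    "BellRateModel",
    "BellRateResults",
    "fit_bell",
    "RuptureForceDistribution",
    "rupture_force_pdf",
    "ExponentialLifetimeModel",
    "fit_exponential_lifetime",
    "looping_probability",
    "LoopingKineticsModel",
    "LoopingKineticsResults",
    "fit_looping",
    "RuptureMixtureModel",
    "fit_rupture_mixture",
]


def _summary_table(title: str, rows: list[tuple[str, str]]) -> str:
    width = max(len(k) for k, _ in rows) + 2
    lines = [title, "=" * max(len(title), width + 16)]
    lines += [f"{k:<{width}}{v}" for k, v in rows]
    return "\n".join(lines)


@dataclass(frozen=True)
class RateParams:
    """Bell-law parameters of one force-dependent transition.

    k0 : zero-force rate (s⁻¹), > 0.
    delta_x : transition distance (nm), signed; positive = force-accelerated.
    """

    k0: float
    delta_x: float
    k0_se: float = float("nan")
    delta_x_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be > 0")


@dataclass(frozen=True)
class TwoStateRates:
    """Looping/unlooping (or fold/unfold) rate pair at one force."""

    k_p: float
    k_u: float
    k_p_se: float = float("nan")
    k_u_se: float = float("nan")

    def __post_init__(self) -> None:
        if self.k_p < 0 or self.k_u < 0:
            raise ValueError("rates must be >= 0")
        if self.k_p == 0 and self.k_u == 0:
            raise ValueError("k_p and k_u cannot both be 0")

    @property
    def plateau(self) -> float:
        """Equilibrium looped probability k_p/(k_p + k_u)."""
        return self.k_p / (self.k_p + self.k_u)


@dataclass(frozen=True)
class LoadingProtocol:
    """Linear force ramp: F(t) = f_start + rate·t until f_end."""

    rate: float
    f_start: float
    f_end: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("loading rate must be > 0")
        if self.f_end <= self.f_start:
            raise ValueError("f_end must exceed f_start")


def bell_rate(force, params: RateParams, env: Environment):
    """Bell/Arrhenius rate k(F) = k0·exp(F·Δx/kBT) (s⁻¹); force in pN ≥ 0."""
    force = np.asarray(force, dtype=float)
    if np.any(force < 0):
        raise ValueError("force must be >= 0")
    out = params.k0 * np.exp(force * params.delta_x / env.kBT)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Bell fit
# ---------------------------------------------------------------------------

class BellRateModel:
    """Fit the Bell law to measured (force, rate) points.

    Least squares on the linearized form ln k = ln k0 + F·Δx/kBT; requires
    at least two distinct forces and strictly positive rates.
    """

    def __init__(self, forces: Sequence[float], rates: Sequence[float],
                 env: Environment) -> None:
        forces = np.asarray(forces, dtype=float)
        rates = np.asarray(rates, dtype=float)
        if forces.shape != rates.shape or forces.ndim != 1:
            raise ValueError("forces and rates must be 1-d and equal length")
        if len(np.unique(forces)) < 2:
            raise ValueError("need >= 2 distinct forces")
        if np.any(rates <= 0):
            raise ValueError("all rates must be > 0")
        order = np.argsort(forces, kind="stable")
        self.forces = forces[order]
        self.rates = rates[order]
        self.env = env

    def fit(self) -> "BellRateResults":
        x, y = self.forces, np.log(self.rates)
        n = len(x)
        if n > 2:
            coeffs, cov = np.polyfit(x, y, 1, cov=True)
        else:
            coeffs = np.polyfit(x, y, 1)
            cov = np.full((2, 2), np.nan)
        slope, intercept = float(coeffs[0]), float(coeffs[1])
        slope_se = float(np.sqrt(cov[0, 0])) if np.isfinite(cov[0, 0]) else float("nan")
        inter_se = float(np.sqrt(cov[1, 1])) if np.isfinite(cov[1, 1]) else float("nan")
        kBT = self.env.kBT
        params = RateParams(
            k0=float(np.exp(intercept)),
            delta_x=slope * kBT,
            k0_se=float(np.exp(intercept)) * inter_se,
            delta_x_se=slope_se * kBT,
        )
        resid = y - (slope * x + intercept)
        return BellRateResults(model=self, params=params,
                               resid_log=resid)


@dataclass(frozen=True)
class BellRateResults:
    model: BellRateModel
    params: RateParams
    resid_log: np.ndarray

    @property
    def k0(self) -> float:
        return self.params.k0

    @property
    def delta_x(self) -> float:
        return self.params.delta_x

    def predict(self, forces):
        return bell_rate(forces, self.params, self.model.env)

    def summary(self) -> str:
        p = self.params
        return _summary_table("Bell rate fit", [
            ("n points", str(len(self.model.forces))),
            ("k0 (s^-1)", f"{p.k0:.6g} +/- {p.k0_se:.3g}"),
            ("delta_x (nm)", f"{p.delta_x:.6g} +/- {p.delta_x_se:.3g}"),
            ("temperature (C)", f"{self.model.env.temperature:g}"),
        ])


def fit_bell(forces, rates, env: Environment) -> BellRateResults:
    """Fit k(F) = k0·exp(F·Δx/kBT) through measured rates; see BellRateModel."""
    return BellRateModel(forces, rates, env).fit()


# ---------------------------------------------------------------------------
# Rupture-force distribution under a linear ramp
# ---------------------------------------------------------------------------

class RuptureForceDistribution:
    """First-passage rupture-force distribution under a linear force ramp.

    For a Bell rate k(F) and loading rate r, the survival probability from
    f_start is S(F) = exp(−(1/r)∫ k df) with the closed-form Bell integral,
    and the rupture-force density is p(F) = k(F)·S(F)/r.  The modal force is

        F* = (kBT/Δx)·ln(r·Δx/(k0·kBT))

    whenever the logarithm's argument exceeds 1.
    """

    def __init__(self, protocol: LoadingProtocol, params: RateParams,
                 env: Environment) -> None:
        if params.delta_x <= 0:
            raise ValueError("rupture branch requires delta_x > 0")
        self.protocol = protocol
        self.params = params
        self.env = env

    def _hazard_integral(self, force):
        """(1/r)∫_{f_start}^{F} k(f) df, elementwise."""
        p, pr, kBT = self.params, self.protocol, self.env.kBT
        force = np.asarray(force, dtype=float)
        a = p.delta_x / kBT
        return (p.k0 / (pr.rate * a)) * (
            np.exp(a * force) - np.exp(a * pr.f_start)
        )

    def pdf(self, force):
        force = np.asarray(force, dtype=float)
        p, pr, kBT = self.params, self.protocol, self.env.kBT
        # log-space: the hazard integral overwhelms the rate at large F,
        # where naive evaluation hits inf * 0
        log_k = np.log(p.k0) + np.maximum(force, 0.0) * p.delta_x / kBT
        with np.errstate(over="ignore"):
            log_pdf = log_k - np.log(pr.rate) - self._hazard_integral(force)
        out = np.where(force < pr.f_start, 0.0, np.exp(log_pdf))
        return float(out) if out.ndim == 0 else out

    def cdf(self, force):
        force = np.asarray(force, dtype=float)
        out = 1.0 - np.exp(-self._hazard_integral(force))
        out = np.where(force < self.protocol.f_start, 0.0, out)
        return float(out) if out.ndim == 0 else out

    @property
    def modal_force(self) -> float:
        p, kBT = self.params, self.env.kBT
        arg = self.protocol.rate * p.delta_x / (p.k0 * kBT)
        if arg <= 1.0:
            return self.protocol.f_start
        return max((kBT / p.delta_x) * np.log(arg), self.protocol.f_start)

    def censored_fraction(self) -> float:
        """Probability that no rupture occurs before f_end."""
        return float(np.exp(-self._hazard_integral(self.protocol.f_end)))


def rupture_force_pdf(protocol: LoadingProtocol, params: RateParams,
                      env: Environment) -> RuptureForceDistribution:
    """Analytic rupture-force distribution; see RuptureForceDistribution."""
    return RuptureForceDistribution(protocol, params, env)


# ---------------------------------------------------------------------------
# Exponential lifetime
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DwellSample:
    """Fitted mean lifetime of an exponential dwell sample.

    The standard error follows the τ/√(N−1) convention used for
    force-dependent lifetime plots.
    """

    dwells: np.ndarray
    tau: float
    se: float
    n: int
    method: str = "mle"

    def summary(self) -> str:
        return _summary_table("Exponential lifetime fit", [
            ("n dwells", str(self.n)),
            ("tau (s)", f"{self.tau:.6g} +/- {self.se:.3g}"),
            ("method", self.method),
        ])


class ExponentialLifetimeModel:
    """Mean lifetime τ of exponentially distributed dwell times.

    The default estimator is the maximum-likelihood one (the sample mean),
    which is unbiased and binning-free.  ``method="histogram"`` instead
    least-squares fits a Doane-binned dwell histogram to A·exp(−t/τ), the
    way lifetime plots are conventionally fitted, as a cross-check.
    """

    def __init__(self, dwells: Sequence[float]) -> None:
        dwells = np.asarray(dwells, dtype=float)
        if dwells.ndim != 1 or len(dwells) < 2:
            raise ValueError("need >= 2 dwell times")
        if np.any(dwells <= 0):
            raise ValueError("dwell times must be > 0")
        self.dwells = dwells

    def fit(self, method: str = "mle") -> DwellSample:
        n = len(self.dwells)
        if method == "mle":
            tau = float(np.mean(self.dwells))
        elif method == "histogram":
            tau = self._fit_histogram()
        else:
            raise ValueError(f"unknown method {method!r}")
        return DwellSample(dwells=self.dwells, tau=tau,
                           se=tau / np.sqrt(n - 1), n=n, method=method)

    def _fit_histogram(self) -> float:
        from scipy.optimize import minimize

        counts, edges = np.histogram(self.dwells, bins="doane")
        centers = 0.5 * (edges[:-1] + edges[1:])
        mean = float(np.mean(self.dwells))

        # Poisson likelihood on the binned counts: unweighted LS would let
        # sparse tail bins drag the decay constant
        def nll(theta):
            log_amp, log_tau = theta
            lam = np.exp(log_amp - centers / np.exp(log_tau))
            return float(np.sum(lam - counts * np.log(lam)))

        res = minimize(nll, [np.log(max(counts.max(), 1.0)), np.log(mean)],
                       method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        return float(np.exp(res.x[1]))


def fit_exponential_lifetime(dwells, method: str = "mle") -> DwellSample:
    """Fit τ to a dwell-time sample; see ExponentialLifetimeModel."""
    return ExponentialLifetimeModel(dwells).fit(method=method)


# ---------------------------------------------------------------------------
# Looping kinetics
# ---------------------------------------------------------------------------

def looping_probability(delta_t, rates: TwoStateRates):
    """Looped probability after waiting Δt, starting unlooped.

    P(Δt) = k_p/(k_p+k_u) · (1 − exp(−(k_p+k_u)·Δt)); monotone in Δt and
    bounded by the plateau k_p/(k_p+k_u).
    """
    delta_t = np.asarray(delta_t, dtype=float)
    if np.any(delta_t < 0):
        raise ValueError("delta_t must be >= 0")
    k = rates.k_p + rates.k_u
    out = rates.plateau * (1.0 - np.exp(-k * delta_t))
    return float(out) if out.ndim == 0 else out


class LoopingKineticsModel:
    """Fit the two-state looping model to measured P(Δt) points.

    Weighted nonlinear least squares of
    P(Δt) = k_p/(k_p+k_u)·(1 − e^{−(k_p+k_u)Δt}).  When per-point cycle
    counts are given, the weights are the inverse binomial variances
    √(P(1−P)/n_cycles); otherwise the fit is unweighted.
    """

    def __init__(self, delta_ts: Sequence[float],
                 probabilities: Sequence[float],
                 n_cycles: Sequence[int] | int | None = None) -> None:
        dt = np.asarray(delta_ts, dtype=float)
        p = np.asarray(probabilities, dtype=float)
        if dt.shape != p.shape or dt.ndim != 1 or len(dt) < 3:
            raise ValueError("need >= 3 (delta_t, probability) points")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.any(p > 0):
            raise ValueError("all probabilities are zero: rates unidentifiable")
        order = np.argsort(dt, kind="stable")
        self.delta_ts = dt[order]
        self.probabilities = p[order]
        if n_cycles is None:
            self.sigma = None
        else:
            nc = np.broadcast_to(np.asarray(n_cycles, dtype=float), dt.shape)[order]
            var = np.clip(self.probabilities * (1 - self.probabilities), 1e-4, None)
            self.sigma = np.sqrt(var / nc)

    def fit(self) -> "LoopingKineticsResults":
        dt, p = self.delta_ts, self.probabilities
        plateau0 = min(max(float(p.max()), 1e-3), 1 - 1e-6)
        # initial total rate from the earliest point on the rise
        ksum0 = 1.0 / max(dt[p > 0][0], 1e-6)

        def model(t, k_p, k_u):
            k = k_p + k_u
            return (k_p / k) * (1.0 - np.exp(-k * t))

        p0 = (plateau0 * ksum0, max((1 - plateau0) * ksum0, 1e-6))
        popt, pcov = curve_fit(
            model, dt, p, p0=p0, sigma=self.sigma, absolute_sigma=self.sigma is not None,
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
        )
        k_p, k_u = map(float, popt)
        se = np.sqrt(np.diag(pcov))
        rates = TwoStateRates(k_p=max(k_p, 1e-300), k_u=k_u,
                              k_p_se=float(se[0]), k_u_se=float(se[1]))
        # plateau unidentifiable if no point reaches ~ one relaxation time
        ill = bool(dt.max() * (k_p + k_u) < 1.0)
        return LoopingKineticsResults(model=self, rates=rates, ill_conditioned=ill)


@dataclass(frozen=True)
class LoopingKineticsResults:
    model: LoopingKineticsModel
    rates: TwoStateRates
    ill_conditioned: bool

    @property
    def k_p(self) -> float:
        return self.rates.k_p

    @property
    def k_u(self) -> float:
        return self.rates.k_u

    @property
    def plateau(self) -> float:
        return self.rates.plateau

    def predict(self, delta_t):
        return looping_probability(delta_t, self.rates)

    def summary(self) -> str:
        r = self.rates
        return _summary_table("Two-state looping fit", [
            ("n points", str(len(self.model.delta_ts))),
            ("k_p (s^-1)", f"{r.k_p:.6g} +/- {r.k_p_se:.3g}"),
            ("k_u (s^-1)", f"{r.k_u:.6g} +/- {r.k_u_se:.3g}"),
            ("plateau", f"{r.plateau:.4f}"),
            ("ill-conditioned", str(self.ill_conditioned)),
        ])


def fit_looping(delta_ts, probabilities, n_cycles=None) -> LoopingKineticsResults:
    """Fit (k_p, k_u) to a measured looping-probability time course."""
    return LoopingKineticsModel(delta_ts, probabilities, n_cycles).fit()


# ---------------------------------------------------------------------------
# Rupture-force mixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RuptureMixture:
    """Two-population rupture-force decomposition.

    The component with the higher mean force is labeled "strong";
    weight_strong is its mixture fraction.
    """

    weight_strong: float
    strong: tuple[float, float]            # (mean pN, sd pN)
    weak: tuple[float, float] | None
    weight_strong_se: float = float("nan")
    converged: bool = True
    n_iter: int = 0

    def summary(self) -> str:
        rows = [
            ("weight_strong", f"{self.weight_strong:.4f} +/- {self.weight_strong_se:.3g}"),
            ("strong (pN)", f"mean {self.strong[0]:.3f}, sd {self.strong[1]:.3f}"),
        ]
        if self.weak is not None:
            rows.append(("weak (pN)", f"mean {self.weak[0]:.3f}, sd {self.weak[1]:.3f}"))
        rows += [("converged", str(self.converged)), ("iterations", str(self.n_iter))]
        return _summary_table("Rupture-force mixture fit", rows)


class RuptureMixtureModel:
    """Gaussian mixture (1 or 2 components) on the rupture-force axis.

    Expectation-maximization with deterministic moment-based initialization
    (component means at the 30th/70th percentiles), a 500-iteration cap and
    a 1e-8 log-likelihood tolerance, so that refitting the same data always
    returns the same result regardless of input order.
    """

    MAX_ITER = 500
    TOL = 1e-8

    def __init__(self, rupture_forces: Sequence[float], n_components: int = 2) -> None:
        x = np.sort(np.asarray(rupture_forces, dtype=float))
        if n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if n_components == 2 and len(x) < 20:
            raise ValueError("need >= 20 rupture forces for a 2-component fit")
        if len(x) < 2:
            raise ValueError("need >= 2 rupture forces")
        self.x = x
        self.n_components = n_components

    def _em(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool, int]:
        mu = np.percentile(x, [30.0, 70.0])
        sd = np.full(2, max(float(np.std(x)), 1e-6))
        w = np.array([0.5, 0.5])
        prev = -np.inf
        converged = False
        it = 0
        for it in range(1, self.MAX_ITER + 1):
            dens = w * norm.pdf(x[:, None], mu, np.maximum(sd, 1e-8))
            tot = dens.sum(axis=1)
            tot = np.maximum(tot, 1e-300)
            loglik = float(np.sum(np.log(tot)))
            resp = dens / tot[:, None]
            nk = resp.sum(axis=0)
            w = nk / len(x)
            mu = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-12)
            var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / np.maximum(nk, 1e-12)
            sd = np.sqrt(np.maximum(var, 1e-12))
            if abs(loglik - prev) < self.TOL * (1 + abs(loglik)):
                converged = True
                break
            prev = loglik
        return w, mu, sd, converged, it

    def fit(self, n_bootstrap: int = 0, seed: int | None = None) -> RuptureMixture:
        x = self.x
        if self.n_components == 1:
            return RuptureMixture(
                weight_strong=1.0,
                strong=(float(np.mean(x)), float(np.std(x, ddof=1))),
                weak=None, weight_strong_se=0.0, converged=True, n_iter=0,
            )
        w, mu, sd, converged, it = self._em(x)
        strong = int(np.argmax(mu))
        se = float("nan")
        if n_bootstrap > 0:
            rng = np.random.default_rng(seed)
            ws = np.empty(n_bootstrap)
            for b in range(n_bootstrap):
                xb = np.sort(rng.choice(x, size=len(x), replace=True))
                wb, mub, _, _, _ = self._em(xb)
                ws[b] = wb[int(np.argmax(mub))]
            se = float(np.std(ws, ddof=1))
        return RuptureMixture(
            weight_strong=float(w[strong]),
            strong=(float(mu[strong]), float(sd[strong])),
            weak=(float(mu[1 - strong]), float(sd[1 - strong])),
            weight_strong_se=se, converged=converged, n_iter=it,
        )


def fit_rupture_mixture(rupture_forces, n_components: int = 2,
                        n_bootstrap: int = 0, seed: int | None = None) -> RuptureMixture:
    """Fit a 1- or 2-component Gaussian mixture to rupture forces."""
    return RuptureMixtureModel(rupture_forces, n_components).fit(
        n_bootstrap=n_bootstrap, seed=seed)
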