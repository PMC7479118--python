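"""Equilibrium folding thermodynamics of N tandem domains.

At equilibrium under a constant force, N identical independent two-state
domains populate the occupancy levels n ∈ {0..N} (number of unfolded
domains) binomially:

    P_N(n) = C(N, n) · pⁿ · (1−p)^(N−n),

with p the unfolded probability of a single domain.  From p the
force-dependent folding free-energy difference follows as

    ΔG(F) = −kBT · ln((1−p)/p),

which decomposes into the zero-force folding energy and the conformational
term: ΔG(F) = ΔG0 + Δφ(F), with Δφ(F) the extension-difference integral
from :mod:`mtweez.polymer`.  The critical force Fc at which folded and
unfolded states are equally populated solves ΔG0 + Δφ(Fc) = 0.

Energies are reported in kBT units throughout; uncertainties propagate by
first-order quadrature sums, with the force-calibration uncertainty
(10% relative by default) entering through Δφ.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit
from scipy.stats import binom

from .polymer import (
    Environment,
    FoldedDomainParams,
    PeptideParams,
    conformational_free_energy,
    folded_extension,
    peptide_extension,
)

__all__ = [
    "OccupancyFit",
    "ThermoResult",
    "binomial_occupancy",
    "BinomialOccupancyModel",
    "fit_unfolded_probability",
    "free_energy_from_probability",
    "free_energy_se",
    "zero_force_free_energy",
    "critical_force",
    "thermo_from_measurement",
    "temperature_series",
]


def binomial_occupancy(n: int, N: int, p: float) -> float:
    """P_N(n) = C(N,n)·pⁿ·(1−p)^(N−n), the binomial occupancy probability."""
    if not 0 <= n <= N:
        raise ValueError(f"n must lie in [0, {N}]")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    return float(binom.pmf(n, N, p))


@dataclass(frozen=True)
class OccupancyFit:
    """Fitted single-domain unfolded probability from an occupancy histogram.

    counts[n] is the number of observations with n of the N domains
    unfolded; p is the binomial MLE (n̄/N), p_se its bootstrap standard
    error, and p_lsq the least-squares cross-check against the normalized
    histogram.  ``boundary`` flags an estimate pinned at 0 or 1.
    """

    counts: np.ndarray
    N: int
    p: float
    p_se: float
    p_lsq: float
    boundary: bool

    @property
    def probabilities(self) -> np.ndarray:
        """Normalized occupancy probabilities."""
        return self.counts / self.counts.sum()

    def predicted(self) -> np.ndarray:
        """Binomial probabilities at the fitted p."""
        return binom.pmf(np.arange(self.N + 1), self.N, self.p)

    def summary(self) -> str:
        lines = [
            "Binomial occupancy fit",
            "======================",
            f"N domains        {self.N}",
            f"total counts     {int(self.counts.sum())}",
            f"p (MLE)          {self.p:.4f} +/- {self.p_se:.4f}",
            f"p (LSQ check)    {self.p_lsq:.4f}",
            f"boundary flag    {self.boundary}",
        ]
        return "\n".join(lines)


class BinomialOccupancyModel:
    """Fit Binomial(N, p) to an occupancy-count histogram.

    p is estimated by the closed-form binomial MLE, the count-weighted mean
    occupancy divided by N, and cross-checked by least squares against the
    normalized counts.  The standard error comes from bootstrap resampling
    of the raw occupancy labels.
    """

    def __init__(self, counts: Sequence[float], N: int) -> None:
        counts = np.asarray(counts, dtype=float)
        if N < 1:
            raise ValueError("N must be >= 1")
        if counts.shape != (N + 1,):
            raise ValueError(f"counts must have length N+1 = {N + 1}")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.sum() <= 0:
            raise ValueError("total count must be > 0")
        self.counts = counts
        self.N = N

    @staticmethod
    def _mle(counts: np.ndarray, N: int) -> float:
        n = np.arange(N + 1)
        return float((n * counts).sum() / (N * counts.sum()))

    def fit(self, n_bootstrap: int = 1000, seed: int | None = None) -> OccupancyFit:
        counts, N = self.counts, self.N
        p = self._mle(counts, N)
        boundary = p in (0.0, 1.0)

        # least-squares cross-check on the normalized histogram
        if boundary:
            p_lsq = p
        else:
            n = np.arange(N + 1)
            probs = counts / counts.sum()
            popt, _ = curve_fit(lambda nn, q: binom.pmf(nn, N, q), n, probs,
                                p0=(p,), bounds=(0.0, 1.0))
            p_lsq = float(popt[0])

        p_se = float("nan")
        if n_bootstrap > 0 and not boundary:
            # resampling the raw occupancy labels with replacement is a
            # multinomial redraw of the counts
            rng = np.random.default_rng(seed)
            total = int(counts.sum())
            boot = rng.multinomial(total, counts / counts.sum(),
                                   size=n_bootstrap)
            p_boot = (boot * np.arange(N + 1)).sum(axis=1) / (N * total)
            p_se = float(np.std(p_boot, ddof=1))
        elif boundary:
            p_se = 0.0
        return OccupancyFit(counts=counts, N=N, p=p, p_se=p_se,
                            p_lsq=p_lsq, boundary=boundary)


def fit_unfolded_probability(counts, N: int, n_bootstrap: int = 1000,
                             seed: int | None = None) -> OccupancyFit:
    """Fit the binomial occupancy model; see BinomialOccupancyModel."""
    return BinomialOccupancyModel(counts, N).fit(n_bootstrap=n_bootstrap, seed=seed)


def free_energy_from_probability(p: float, env: Environment | None = None) -> float:
    """ΔG(F) in kBT from the unfolded probability: −ln((1−p)/p).

    Antisymmetric under p → 1−p; zero at p = ½.  The environment fixes only
    the kBT scale and does not alter the dimensionless value; it is accepted
    for interface symmetry with the pN·nm-returning operations.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie strictly inside (0, 1); the free energy "
                         "diverges at the boundaries")
    return float(-np.log((1.0 - p) / p))


def free_energy_se(p: float, p_se: float) -> float:
    """First-order SE of ΔG(F)/kBT propagated from the SE of p."""
    return p_se / (p * (1.0 - p))


def zero_force_free_energy(dG_F: float, dPhi_F: float,
                           dG_F_se: float = 0.0, dPhi_F_se: float = 0.0
                           ) -> tuple[float, float]:
    """ΔG0 = ΔG(F) − Δφ(F) in kBT with quadrature-summed uncertainty."""
    if not (np.isfinite(dG_F) and np.isfinite(dPhi_F)):
        raise ValueError("inputs must be finite")
    return dG_F - dPhi_F, float(np.hypot(dG_F_se, dPhi_F_se))


def critical_force(
    dG0: float,
    unfolded: PeptideParams,
    folded: FoldedDomainParams,
    env: Environment,
    *,
    f_max: float = 50.0,
) -> tuple[float, bool]:
    """Critical force Fc (pN) solving ΔG0 + Δφ(Fc) = 0.

    Returns (Fc, flagged).  Δφ is monotone increasing wherever the unfolded
    chain is longer than the folded rod, so the bracketed root is unique.
    ΔG0 ≥ 0 (unstable at zero force) returns (0, True); a root above f_max
    returns (f_max, True).
    """
    if dG0 >= 0:
        return 0.0, True

    def g(force: float) -> float:
        return dG0 + conformational_free_energy(force, unfolded, folded, env)

    lo, hi = 1e-3, f_max
    if g(hi) < 0:
        return f_max, True
    if g(lo) > 0:
        return lo, True
    fc = brentq(g, lo, hi, xtol=1e-9)
    return float(fc), False


@dataclass(frozen=True)
class ThermoResult:
    """Full thermodynamic characterization at one (force, temperature) point.

    Energies in kBT, forces in pN; every quantity carries its propagated
    uncertainty.  Invariants: dG0 = dG_F − dPhi_F and ΔG0 + Δφ(Fc) ≈ 0.
    """

    force: float
    temperature: float
    p: float
    p_se: float
    dPhi_F: float
    dPhi_F_se: float
    dG_F: float
    dG_F_se: float
    dG0: float
    dG0_se: float
    Fc: float
    Fc_se: float
    Fc_flagged: bool = False

    def summary(self) -> str:
        rows = [
            ("force (pN)", f"{self.force:g}"),
            ("temperature (C)", f"{self.temperature:g}"),
            ("p unfolded", f"{self.p:.4f} +/- {self.p_se:.4f}"),
            ("dPhi(F) (kBT)", f"{self.dPhi_F:.3f} +/- {self.dPhi_F_se:.3f}"),
            ("dG(F) (kBT)", f"{self.dG_F:.3f} +/- {self.dG_F_se:.3f}"),
            ("dG0 (kBT)", f"{self.dG0:.3f} +/- {self.dG0_se:.3f}"),
            ("Fc (pN)", f"{self.Fc:.3f} +/- {self.Fc_se:.3f}"
                        + (" (flagged)" if self.Fc_flagged else "")),
        ]
        width = max(len(k) for k, _ in rows) + 2
        return "\n".join(["Folding thermodynamics", "======================"]
                         + [f"{k:<{width}}{v}" for k, v in rows])

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "force", "temperature", "p", "p_se", "dPhi_F", "dPhi_F_se",
            "dG_F", "dG_F_se", "dG0", "dG0_se", "Fc", "Fc_se", "Fc_flagged")}


def _extension_gap(force: float, unfolded: PeptideParams,
                   folded: FoldedDomainParams, env: Environment) -> float:
    return (peptide_extension(force, unfolded, env)
            - folded_extension(force, folded, env))


def thermo_from_measurement(
    force: float,
    temperature: float,
    p: float,
    p_se: float,
    unfolded: PeptideParams,
    folded: FoldedDomainParams,
    *,
    dPhi_F: float | None = None,
    dPhi_F_se: float | None = None,
    force_rel_err: float = 0.10,
) -> ThermoResult:
    """Derive the full thermodynamic chain from a measured (F, T, p).

    Δφ(F) is computed by WLC quadrature from the polymer parameters unless a
    measured value is supplied.  Its uncertainty comes from the relative
    force-calibration error: σ_Δφ = (x_u − x_f)(F)·(force_rel_err·F)/kBT.
    ΔG, ΔG0 and Fc follow with first-order error propagation; the Fc
    uncertainty is σ_ΔG0 divided by the slope dΔφ/dF at Fc.
    """
    env = Environment(temperature)
    if dPhi_F is None:
        dPhi_F = conformational_free_energy(force, unfolded, folded, env)
    if dPhi_F_se is None:
        dPhi_F_se = (_extension_gap(force, unfolded, folded, env)
                     * force_rel_err * force / env.kBT)
    dG_F = free_energy_from_probability(p)
    dG_F_se = free_energy_se(p, p_se)
    dG0, dG0_se = zero_force_free_energy(dG_F, dPhi_F, dG_F_se, dPhi_F_se)
    Fc, flagged = critical_force(dG0, unfolded, folded, env)
    if flagged:
        Fc_se = float("nan")
    else:
        slope = _extension_gap(Fc, unfolded, folded, env) / env.kBT
        Fc_se = dG0_se / slope if slope > 0 else float("nan")
    return ThermoResult(
        force=force, temperature=temperature, p=p, p_se=p_se,
        dPhi_F=dPhi_F, dPhi_F_se=dPhi_F_se, dG_F=dG_F, dG_F_se=dG_F_se,
        dG0=dG0, dG0_se=dG0_se, Fc=Fc, Fc_se=Fc_se, Fc_flagged=flagged,
    )


def temperature_series(results: Sequence[ThermoResult],
                       force_tol: float = 1e-6) -> tuple[pd.DataFrame, dict]:
    """Tabulate ΔG0 and Fc against temperature at a common force.

    Returns (table sorted by temperature, trend dict) where each trend is
    "increasing", "decreasing", "constant" or "non-monotone".  Mixing forces
    beyond ``force_tol`` is rejected: the comparison is only meaningful at a
    fixed force.
    """
    if len(results) < 2:
        raise ValueError("need >= 2 temperatures")
    forces = np.array([r.force for r in results])
    if np.ptp(forces) > force_tol:
        raise ValueError("results span different forces; temperature trends "
                         "require a common force")
    rows = sorted(results, key=lambda r: r.temperature)
    temps = [r.temperature for r in rows]
    if len(set(temps)) < 2:
        raise ValueError("need >= 2 distinct temperatures")
    table = pd.DataFrame([r.to_dict() for r in rows])

    def trend(values: np.ndarray) -> str:
        d = np.diff(values)
        if np.all(d == 0):
            return "constant"
        if np.all(d >= 0):
            return "increasing"
        if np.all(d <= 0):
            return "decreasing"
        return "non-monotone"

    trends = {
        "dG0": trend(table["dG0"].to_numpy()),
        "Fc": trend(table["Fc"].to_numpy()),
    }
    return table, trends
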