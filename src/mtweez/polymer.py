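"""Force-extension models for the mechanical elements of a tethered construct.

A magnetic-tweezers tether is a series of mechanical elements — a double-
stranded DNA handle, folded protein domains, and unfolded polypeptide
segments — that share a common tension.  Each element type has its own
force-extension law:

* unfolded polypeptide: inextensible worm-like chain (WLC), Marko-Siggia
  interpolation, inverted numerically;
* folded domain: rigid rod of length ``d`` with thermal orientational
  averaging (Langevin function);
* dsDNA handle: extensible WLC in the high-force approximation.

On top of the element laws the module provides the observables the
single-molecule analysis needs: the total extension of a construct state,
predicted transition step sizes Δx(F) between two states, and the
force-dependent conformational free-energy difference

    Δφ(F) = ∫₀F (x_u(f) − x_f(f)) df,

between the unfolded and the folded state of one domain, in units of kBT.

Units are fixed throughout the package: force in pN, length in nm, time in
s, energy in pN·nm (or kBT where stated); temperature is Celsius at the
interface and enters only through kBT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

__all__ = [
    "BOLTZMANN_PN_NM",
    "Environment",
    "PeptideParams",
    "FoldedDomainParams",
    "HandleParams",
    "ConstructState",
    "kBT_at_temperature",
    "wlc_relative_extension",
    "peptide_extension",
    "folded_extension",
    "handle_extension",
    "state_extension",
    "step_size_curve",
    "conformational_free_energy",
]

#: Boltzmann constant in pN·nm/K.
BOLTZMANN_PN_NM = 0.0138065

#: Validity floor of the high-force extensible-WLC handle model (pN).
HANDLE_FORCE_FLOOR = 0.5


def kBT_at_temperature(temperature: float) -> float:
    """Thermal energy kBT in pN·nm at a temperature given in Celsius.

    Raises
    ------
    ValueError
        If the temperature is at or below absolute zero.
    """
    if temperature <= -273.15:
        raise ValueError(
            f"non-physical temperature {temperature} °C (must exceed -273.15 °C)"
        )
    return BOLTZMANN_PN_NM * (temperature + 273.15)


@dataclass(frozen=True)
class Environment:
    """Thermal environment of the experiment.

    Parameters
    ----------
    temperature : float
        Bath temperature in Celsius.  kBT is derived from it and is the only
        way temperature enters the models.
    """

    temperature: float

    def __post_init__(self) -> None:
        kBT_at_temperature(self.temperature)  # validate

    @property
    def kBT(self) -> float:
        """Thermal energy in pN·nm."""
        return kBT_at_temperature(self.temperature)


@dataclass(frozen=True)
class PeptideParams:
    """Unfolded (disordered) polypeptide segment, inextensible WLC.

    contour_per_residue is the crystallographic contour-length gain per
    released residue (nm/residue); persistence_length the WLC bending
    persistence length (nm).
    """

    n_residues: int
    contour_per_residue: float = 0.38
    persistence_length: float = 0.8

    def __post_init__(self) -> None:
        if self.n_residues < 0:
            raise ValueError("n_residues must be >= 0")
        if self.contour_per_residue <= 0 or self.persistence_length <= 0:
            raise ValueError("contour_per_residue and persistence_length must be > 0")

    @property
    def contour_length(self) -> float:
        return self.n_residues * self.contour_per_residue


@dataclass(frozen=True)
class FoldedDomainParams:
    """Folded domain treated as a rigid rod of end-to-end length rod_length (nm)."""

    rod_length: float

    def __post_init__(self) -> None:
        if self.rod_length < 0:
            raise ValueError("rod_length must be >= 0")


@dataclass(frozen=True)
class HandleParams:
    """Double-stranded DNA handle, extensible WLC (high-force approximation)."""

    n_bp: int = 572
    persistence_length: float = 45.0
    stretch_modulus: float = 1200.0
    rise_per_bp: float = 0.338

    def __post_init__(self) -> None:
        if min(self.n_bp, self.persistence_length, self.stretch_modulus,
               self.rise_per_bp) <= 0:
            raise ValueError("all handle parameters must be positive")

    @property
    def contour_length(self) -> float:
        return self.n_bp * self.rise_per_bp


ElementKind = Literal["peptide", "folded_domain", "handle"]
Element = tuple[ElementKind, PeptideParams | FoldedDomainParams | HandleParams]


@dataclass(frozen=True)
class ConstructState:
    """One mechanical state of a tethered construct.

    The state is an ordered series of elements under common tension; its
    extension at force F is the sum of the element extensions at F.
    """

    elements: tuple[Element, ...]
    label: str = ""

    def __init__(self, elements: Iterable[Element], label: str = "") -> None:
        object.__setattr__(self, "elements", tuple(elements))
        object.__setattr__(self, "label", label)
        for kind, params in self.elements:
            if kind not in ("peptide", "folded_domain", "handle"):
                raise ValueError(f"unknown element kind {kind!r}")

    def extension(self, force: float, env: Environment) -> float:
        return state_extension(self, force, env)


# ---------------------------------------------------------------------------
# Element force-extension laws
# ---------------------------------------------------------------------------

def _marko_siggia(x_hat: float) -> float:
    """Dimensionless Marko-Siggia force f̂ at relative extension x̂ ∈ [0, 1)."""
    return x_hat + 0.25 / (1.0 - x_hat) ** 2 - 0.25


def wlc_relative_extension(f_hat):
    """Relative extension x/Lc of an inextensible WLC at dimensionless force.

    Inverts the Marko-Siggia interpolation

        f̂ = x̂ + 1/(4(1−x̂)²) − 1/4,      f̂ = F·Lp/kBT,

    by bracketed root-finding; strictly increasing in ``f_hat``.  Accepts a
    scalar or an array.
    """
    f = np.asarray(f_hat, dtype=float)
    if np.any(f < 0):
        raise ValueError("dimensionless force must be >= 0")

    def invert(fi: float) -> float:
        if fi == 0.0:
            return 0.0
        # upper bracket: x̂ < 1 − ½√(1/f̂) for large f̂; generic safe bracket
        hi = 1.0 - 1e-16
        return brentq(lambda x: _marko_siggia(x) - fi, 0.0, hi,
                      xtol=1e-15, rtol=8.9e-16)

    if f.ndim == 0:
        return invert(float(f))
    return np.array([invert(fi) for fi in f.ravel()]).reshape(f.shape)


def peptide_extension(force: float, params: PeptideParams, env: Environment) -> float:
    """Mean extension (nm) of an unfolded polypeptide at force (pN)."""
    if force < 0:
        raise ValueError("force must be >= 0")
    if params.n_residues == 0:
        return 0.0
    f_hat = force * params.persistence_length / env.kBT
    return params.contour_length * float(wlc_relative_extension(f_hat))


def folded_extension(force: float, params: FoldedDomainParams, env: Environment) -> float:
    """Mean extension (nm) of a folded domain (rigid rod, Langevin average).

    x_f(F) = d·(coth(a) − 1/a) with a = F·d/kBT; → 0 as F → 0, → d as F → ∞.
    """
    if force < 0:
        raise ValueError("force must be >= 0")
    d = params.rod_length
    if d == 0.0 or force == 0.0:
        return 0.0
    a = force * d / env.kBT
    if a < 1e-4:  # series: L(a) = a/3 - a^3/45 + ...
        return d * (a / 3.0 - a**3 / 45.0)
    return d * (1.0 / np.tanh(a) - 1.0 / a)


def handle_extension(force: float, params: HandleParams, env: Environment) -> float:
    """Extension (nm) of the dsDNA handle, extensible WLC.

    x(F) = L₀·[1 − ½√(kBT/(F·Lp)) + F/S].  The high-force approximation is
    invalid at low tension; calls below 0.5 pN are rejected rather than
    silently extrapolated.
    """
    if force < HANDLE_FORCE_FLOOR:
        raise ValueError(
            f"handle model invalid below {HANDLE_FORCE_FLOOR} pN (got {force} pN)"
        )
    return params.contour_length * (
        1.0
        - 0.5 * np.sqrt(env.kBT / (force * params.persistence_length))
        + force / params.stretch_modulus
    )


_EXTENSION_FN = {
    "peptide": peptide_extension,
    "folded_domain": folded_extension,
    "handle": handle_extension,
}


def state_extension(state: ConstructState, force: float, env: Environment) -> float:
    """Total extension (nm) of a construct state: sum of element extensions."""
    return sum(_EXTENSION_FN[kind](force, params, env)
               for kind, params in state.elements)


def step_size_curve(
    before: ConstructState,
    after: ConstructState,
    forces: Sequence[float],
    env: Environment,
) -> np.ndarray:
    """Predicted transition step sizes Δx(F) = x_after(F) − x_before(F) (nm).

    Overlays rupture/unfolding events on force-step-size plots; the curve for
    an unfolding transition grows with force as the released chain stretches.
    """
    forces = np.asarray(forces, dtype=float)
    return np.array([
        state_extension(after, f, env) - state_extension(before, f, env)
        for f in forces
    ])


def conformational_free_energy(
    force: float,
    unfolded: PeptideParams,
    folded: FoldedDomainParams,
    env: Environment,
    *,
    f_low: float = 0.0,
) -> float:
    """Conformational free-energy difference Δφ(F) in kBT.

    Δφ(F) = (1/kBT) ∫_{f_low}^{F} (x_u(f) − x_f(f)) df by adaptive quadrature.
    Δφ(0) = 0 and Δφ is non-decreasing wherever x_u ≥ x_f.
    """
    if force < 0 or f_low < 0:
        raise ValueError("force must be >= 0")

    def integrand(f: float) -> float:
        return (peptide_extension(f, unfolded, env)
                - folded_extension(f, folded, env))

    if force == f_low:
        return 0.0
    val, err = quad(integrand, f_low, force, limit=200)
    if not np.isfinite(val) or err > 1e-6 * max(1.0, abs(val)) + 1e-8:
        raise RuntimeError(
            f"quadrature failed for Δφ on [{f_low}, {force}] pN: "
            f"value={val}, abserr={err}"
        )
    return val / env.kBT
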