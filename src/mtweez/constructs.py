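"""Default tether constructs for the helix-heterotetramer experiments.

Three tether geometries recur in this package:

* a looping construct: two complementary helix-hairpins (a, b) joined by a
  long flexible linker, pulled through a 572-bp dsDNA handle with tandem
  I27 spacers.  Complex formation loops the linker (short tether); rupture
  releases linker plus the unfolding a/b helices (long tether).
* tandem folding constructs: N identical two-state domains (four I27
  repeats, or six spectrin repeats) anchored through the same handle.

The polymer parameters below are conventional polypeptide/dsDNA values
(0.38 nm contour per residue, 0.8 nm peptide persistence length, 45 nm /
1200 pN extensible-WLC handle); folded domains are rods of roughly their
crystallographic end-to-end lengths.  The default kinetic parameters are
calibrated so the simulated observables match the published ones (modal
rupture forces of ~8/~12/~15 pN at 0.2/1/5 pN/s for the unzipping-geometry
complex; looping rates of ~0.58 s⁻¹ at 1.7 pN falling to ~0.01 s⁻¹ at
2.9 pN); they are calibrated stand-ins, not measured constants.
"""

from __future__ import annotations

from .kinetics import RateParams
from .polymer import (
    ConstructState,
    FoldedDomainParams,
    HandleParams,
    PeptideParams,
)
from .simulate import KineticScheme, Transition

__all__ = [
    "I27",
    "SR4",
    "HELIX_HAIRPIN",
    "AB_COMPLEX_ROD",
    "DEFAULT_HANDLE",
    "LINKER_RESIDUES",
    "AB_RESIDUES",
    "I27_RESIDUES",
    "SR4_RESIDUES",
    "UNLOOP_RATE",
    "LOOP_RATE",
    "looping_states",
    "looping_scheme",
    "tandem_states",
    "tandem_scheme",
]

# Folded-domain rod lengths (nm)
I27 = FoldedDomainParams(rod_length=4.4)
SR4 = FoldedDomainParams(rod_length=5.0)
HELIX_HAIRPIN = FoldedDomainParams(rod_length=4.0)
#: The assembled four-helix a/b complex, modeled as one rod.
AB_COMPLEX_ROD = FoldedDomainParams(rod_length=4.0)

DEFAULT_HANDLE = HandleParams(n_bp=572)

I27_RESIDUES = 89
SR4_RESIDUES = 104
#: FH1-domain flexible linker between the a and b components (residues 582-764).
LINKER_RESIDUES = 183
#: Residues released when the separated a and b helix-hairpins unfold.
AB_RESIDUES = 150

#: Complex rupture (unlooping) under unzipping geometry at 23 °C; calibrated
#: to the published modal rupture forces at 0.2/1/5 pN/s.
UNLOOP_RATE = RateParams(k0=1.85e-3, delta_x=1.88)
#: Loop formation; the two-point Bell solution of the printed looping rates
#: (0.58 s⁻¹ at 1.7 pN, 0.01 s⁻¹ at 2.9 pN at 23 °C).
LOOP_RATE = RateParams(k0=1.8e2, delta_x=-13.8)


def looping_states(
    *,
    handle: HandleParams = DEFAULT_HANDLE,
    n_spacers: int = 4,
    spacer: FoldedDomainParams = I27,
    linker_residues: int = LINKER_RESIDUES,
    ab_residues: int = AB_RESIDUES,
    complex_rod: FoldedDomainParams = AB_COMPLEX_ROD,
) -> tuple[ConstructState, ConstructState]:
    """(looped, unlooped) states of the a1a2-L-b1b2 looping construct.

    In the looped state the linker contributes no extension and the a/b
    complex is a short rod; rupture releases the linker and unfolds the a/b
    helices into disordered peptide.
    """
    shared: list = [("handle", handle)]
    shared += [("folded_domain", spacer)] * n_spacers
    looped = ConstructState([*shared, ("folded_domain", complex_rod)],
                            label="looped")
    unlooped = ConstructState(
        [*shared, ("peptide", PeptideParams(linker_residues + ab_residues))],
        label="unlooped",
    )
    return looped, unlooped


def looping_scheme(
    *,
    loop_rate: RateParams = LOOP_RATE,
    unloop_rate: RateParams = UNLOOP_RATE,
    initial: str = "unlooped",
    **state_kwargs,
) -> KineticScheme:
    """Two-state looping/unlooping scheme of the linked a-L-b construct."""
    looped, unlooped = looping_states(**state_kwargs)
    return KineticScheme(
        states={"looped": looped, "unlooped": unlooped},
        transitions=[
            Transition("unlooped", "looped", loop_rate, label="loop"),
            Transition("looped", "unlooped", unloop_rate, label="unloop"),
        ],
        initial=initial,
    )


def tandem_states(
    n_domains: int = 4,
    *,
    residues_per_domain: int = I27_RESIDUES,
    folded: FoldedDomainParams = I27,
    handle: HandleParams = DEFAULT_HANDLE,
    anchor: FoldedDomainParams = AB_COMPLEX_ROD,
) -> dict[str, ConstructState]:
    """States of an N-tandem-domain construct, keyed "0u".."Nu" (n unfolded)."""
    states = {}
    for n in range(n_domains + 1):
        elements: list = [("handle", handle), ("folded_domain", anchor)]
        elements += [("folded_domain", folded)] * (n_domains - n)
        if n:
            elements.append(("peptide", PeptideParams(n * residues_per_domain)))
        states[f"{n}u"] = ConstructState(elements, label=f"{n}u")
    return states


def tandem_scheme(
    n_domains: int = 4,
    *,
    unfold_rate: RateParams,
    refold_rate: RateParams | None = None,
    initial: str = "0u",
    **state_kwargs,
) -> KineticScheme:
    """Kinetic scheme of N independent two-state domains.

    Independence makes the aggregate dynamics a birth-death chain on the
    number of unfolded domains n, with unfolding rate (N−n)·k_u(F) and
    refolding rate n·k_f(F) — the same independence assumption that underlies
    the binomial occupancy model.
    """
    states = tandem_states(n_domains, **state_kwargs)
    transitions = []
    for n in range(n_domains):
        transitions.append(Transition(
            f"{n}u", f"{n + 1}u", unfold_rate,
            label="unfold", multiplicity=n_domains - n,
        ))
        if refold_rate is not None:
            transitions.append(Transition(
                f"{n + 1}u", f"{n}u", refold_rate,
                label="refold", multiplicity=n + 1,
            ))
    return KineticScheme(states=states, transitions=transitions, initial=initial)
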