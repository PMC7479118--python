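# mtweez

Analysis toolkit for single-molecule magnetic-tweezers force spectroscopy
of tethered protein constructs: engineered helix-heterotetramer
(coiled-coil) anchors, their looping/unlooping kinetics, and the
equilibrium folding thermodynamics of tandem protein domains (titin I27,
α-actinin spectrin repeats) measured through them.

It is written for experimentalists and modelers who have bead-height time
series — or want physically faithful synthetic ones — and need the full
chain from raw traces to thermodynamic quantities:

* **Polymer mechanics** (`mtweez.polymer`).  A tether is a series of
  elements under common force F: a dsDNA handle (extensible worm-like
  chain), folded domains (rigid rods with Langevin orientational
  averaging), and unfolded peptide (Marko–Siggia WLC, inverted
  numerically).  From these come predicted transition step sizes Δx(F) and
  the conformational free-energy difference
  Δφ(F) = ∫₀F (x_u(f) − x_f(f)) df between unfolded and folded states.
* **Rupture and looping kinetics** (`mtweez.kinetics`).  Bell/Arrhenius
  rates k(F) = k₀·exp(F·Δx/k_BT); the first-passage rupture-force
  distribution under a linear force ramp with modal force
  F* = (k_BT/Δx)·ln(r·Δx/(k₀·k_BT)); exponential dwell-time lifetimes
  τ ± τ/√(N−1); two-state looping-probability kinetics
  P(Δt) = k_p/(k_p+k_u)·(1 − e^−(k_p+k_u)Δt); and two-population Gaussian
  rupture-force mixtures.
* **Folding thermodynamics** (`mtweez.thermo`).  N independent tandem
  domains populate occupancy levels binomially,
  P_N(n) = C(N,n)·pⁿ(1−p)^(N−n); from the fitted single-domain unfolded
  probability p follow ΔG(F) = −k_BT·ln((1−p)/p), the zero-force folding
  energy ΔG₀ = ΔG(F) − Δφ(F), and the critical force solving
  ΔG₀ + Δφ(F_c) = 0.
* **Synthetic trajectories** (`mtweez.simulate`) with exact ground truth
  (Gillespie state dynamics, closed-form ramp first-passage sampling,
  force-jump looping cycles, additive bead noise), and **trace analysis**
  (`mtweez.traces`): change-point step detection, dwell and rupture-force
  extraction, and multi-peak Gaussian-ladder decomposition of bead-height
  histograms.

Fitting follows the model/results convention: build a model from data,
`fit()` it, read estimates, standard errors and `summary()` off the
results object (`BellRateModel`, `LoopingKineticsModel`,
`ExponentialLifetimeModel`, `RuptureMixtureModel`,
`BinomialOccupancyModel`, `HeightLadderModel`), with one-call function
wrappers (`fit_bell`, `fit_looping`, …) for scripts.

## Worked example

Recover the folding thermodynamics of four tandem I27 domains from a
synthetic equilibrium hopping trace at 4 pN, 37 °C:

```python
import mtweez as m
from mtweez.constructs import tandem_scheme

env = m.Environment(37.0)
scheme = tandem_scheme(4,
    unfold_rate=m.RateParams(k0=0.0212, delta_x=1.0),
    refold_rate=m.RateParams(k0=0.3717, delta_x=-1.0))
config = m.SimConfig(scheme=scheme, environment=env, seed=5)
traj = m.simulate_clamp(config, force=4.0, duration=3000.0)

ladder, occ = m.occupancy_from_heights(traj, N=4, expected_step=9.2, seed=5)
print(occ.summary())

res = m.thermo_from_measurement(
    force=4.0, temperature=37.0, p=occ.p, p_se=occ.p_se,
    unfolded=m.PeptideParams(n_residues=89),
    folded=m.FoldedDomainParams(rod_length=4.4))
print(res.summary())
```

Output:

```
Binomial occupancy fit
======================
N domains        4
total counts     300000
p (MLE)          0.2641 +/- 0.0004
p (LSQ check)    0.2611
boundary flag    False
Folding thermodynamics
======================
force (pN)       4
temperature (C)  37
p unfolded       0.2641 +/- 0.0004
dPhi(F) (kBT)    4.496 +/- 0.855
dG(F) (kBT)      -1.025 +/- 0.002
dG0 (kBT)        -5.520 +/- 0.855
Fc (pN)          4.459 +/- 0.367
```

Reading it: about 26% of the domains are unfolded at 4 pN, so unfolding
is still uphill by ΔG(F) ≈ −(−1.03) ≈ 1 k_BT there; removing the
force-dependent stretching term Δφ leaves a zero-force folding energy of
≈ −5.5 k_BT, and the two states would be equally populated near 4.5 pN.
(The bootstrap SE on p reflects counting statistics only; consecutive
samples of a hopping trace are correlated, so it is a lower bound.)

The command line mirrors the library (`mtweez simulate | detect |
lifetimes | looping | occupancy | thermo | table1 | report`); every run
writes a manifest with seed and config digest.  `mtweez table1`
recomputes the packaged reference stability measurements of SR4 and I27
(p, Δφ inputs → ΔG, ΔG₀, F_c) next to their published values.

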