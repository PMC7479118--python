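# Methods

This note records the models, the defaults and why they were chosen, the
numerical choices, and the limits of what the synthetic closure
demonstrates.  Units are fixed package-wide: force in pN, length in nm,
time in s, energy in pN·nm or k_BT as stated; temperature is Celsius at
every interface and enters the physics only through
k_BT = 0.0138065 pN·nm/K × (T + 273.15).

## Tether mechanics

A tethered construct is an ordered series of mechanical elements sharing
one tension; its extension is the sum of element extensions.

**Unfolded peptide** — inextensible worm-like chain with the Marko–Siggia
interpolation f̂ = x̂ + 1/(4(1−x̂)²) − 1/4, f̂ = F·L_p/k_BT, inverted by
bracketed Brent root-finding to machine precision (the round-trip
reproduces f̂ to better than 1e−8 relative up to f̂ = 10³).  Defaults:
contour 0.38 nm/residue, persistence length 0.8 nm — conventional
polypeptide values; both are parameters of `PeptideParams` because
supplementary-level constants of specific instruments differ.

**Folded domain** — a rigid rod of end-to-end length d with free thermal
orientation: x_f(F) = d·(coth(a) − 1/a), a = F·d/k_BT, with the series
a/3 − a³/45 below a = 1e−4 to avoid cancellation.  Default rod lengths:
I27 4.4 nm, SR4 5.0 nm, helix-hairpin and assembled a/b complex 4.0 nm.
These defaults were fixed once against the published observables they
feed: they reproduce the ~14.9 nm I27 unfolding step at 8 pN, the
~17.9 nm SR4 step at 7.9 pN, the ~70 nm looped/unlooped gap at 9.6 pN,
and — through the Δφ quadrature — the published Δφ(F) values within
~0.5 k_BT and their force-calibration error bars almost exactly.

**dsDNA handle** — 572 bp extensible WLC in the high-force form
x = L₀[1 − ½√(k_BT/(F·L_p)) + F/S] with L_p = 45 nm, S = 1200 pN, rise
0.338 nm/bp.  The approximation degrades at low tension, so forces below
0.5 pN raise an error instead of silently extrapolating.

**Δφ(F)** = (1/k_BT)∫₀F (x_u − x_f) df by adaptive quadrature
(`scipy.integrate.quad`), checked against a 10⁴-point trapezoid oracle to
1e−3 k_BT over random parameter draws.  Temperature dependence enters
only through k_BT; polymer parameters are treated as
temperature-independent.

## Rate laws and their fits

All force-dependent transitions use the single-barrier Bell form
k(F) = k₀·e^{FΔx/k_BT} with a signed transition distance — the minimal
law consistent with Arrhenius kinetics over the narrow force ranges
involved; Δx is an explicit parameter so richer laws can be layered
later.  `fit_bell` is least squares on ln k vs F, exact on noiseless
lines.  A worked internal example: the two printed looping rates
(0.58 s⁻¹ at 1.7 pN, 0.01 s⁻¹ at 2.9 pN, 23 °C) give the closed-form
two-point solution Δx ≈ −13.8 nm, k₀ ≈ 1.8×10² s⁻¹.  The large negative
Δx reflects the entropic cost of closing the long flexible linker.  A
zero-force extrapolation from only these two printed points is *not* the
same as one based on all four measured force points (the remaining two
are not printed), so no specific zero-force rate is asserted anywhere.

**Rupture under a ramp** — for loading rate r the survival function has
the closed-form Bell integral, p(F) = k(F)/r · e^{−(1/r)∫k}, evaluated in
log space because the hazard integral overwhelms the rate far above the
mode.  Modal force F* = (k_BT/Δx)ln(rΔx/(k₀k_BT)) when the argument
exceeds 1.

**Lifetimes** — τ by maximum likelihood (the sample mean; unbiased,
binning-free) with the conventional standard error τ/√(N−1).  A
histogram mode fits A·e^{−t/τ} to Doane-binned counts by Poisson
likelihood; unweighted least squares on the same histogram lets sparse
tail bins drag τ and disagrees with the MLE by >15% in roughly a quarter
of n = 100 samples, which is why the Poisson form is the one provided.

**Looping kinetics** — P(Δt) = k_p/(k_p+k_u)(1 − e^{−(k_p+k_u)Δt}) fitted
by weighted nonlinear least squares, weights from binomial standard
errors √(P(1−P)/n_cycles) when cycle counts are known.  A fit whose
longest Δt is below one relaxation time 1/(k_p+k_u) is flagged
ill-conditioned rather than extrapolated.  An identifiability caveat
documented here because it shapes what closure can show: when
k_u ≪ k_p the plateau sits near 1 and k_u is carried almost entirely by
the plateau deficit, whose binomial noise at 100 cycles/point is ~0.02.
A Cramér–Rao computation over rate regimes and optimized 6-point designs
bounds the relative SD of k̂_u below by ≈0.20 at 100 cycles/point — so no
6×100-cycle experiment measures k_u to 15%, and the closure suite reports
the measured recovery rate at face value instead of resizing the design.

**Rupture-force mixtures** — 1- or 2-component Gaussian mixture on the
force axis by EM with deterministic moment initialization (means at the
30th/70th percentiles), a 500-iteration cap and 1e−8 log-likelihood
tolerance; the higher-mean component is labeled "strong" and its weight
carries a bootstrap SE.  Permutation invariance is by construction.

## Occupancy thermodynamics

For N independent identical two-state domains the unfolded count is
binomial; p̂ is the closed-form MLE (count-weighted mean occupancy over
N), cross-checked by least squares against the normalized histogram, with
a bootstrap SE (1000 label resamples, implemented as the equivalent
multinomial redraw; seeded).  Boundary estimates (p̂ ∈ {0,1}) are flagged,
never clipped.  ΔG(F) = −ln((1−p)/p) k_BT diverges at the boundaries and
is refused there.  Error propagation is first-order throughout:
σ_ΔG = σ_p/(p(1−p)); σ_Δφ = (x_u−x_f)(F)·(0.10·F)/k_BT from the 10%
relative force-calibration uncertainty; σ_ΔG0 by quadrature sum; and
σ_Fc = σ_ΔG0·k_BT/(x_u−x_f)(F_c).  F_c is the bracketed Brent root of
ΔG₀ + Δφ(F) on [1e−3, 50] pN (unique because Δφ is monotone there);
ΔG₀ ≥ 0 or an out-of-bracket root returns a flagged value.

The packaged reference table carries the measured inputs (F, T, p ± SE,
Δφ ± SE) of six (domain, temperature) conditions; recomputation
reproduces every published ΔG(F) cell to 0.01 k_BT and every ΔG₀ cell to
0.1 k_BT, and the package's own Δφ quadrature independently lands within
~0.5 k_BT of the published integrals.

## Synthetic trajectories

The generator emulates force-clamp, constant-loading-rate and
force-jump-looping acquisitions of the tethered constructs with exact
ground truth:

* state dynamics are continuous-time Markov chains over a labeled
  transition graph (exact Gillespie waiting times); N tandem domains are
  independent two-state units, so the aggregate is a birth–death chain
  with multiplicity-scaled rates — the same independence the binomial
  occupancy model assumes;
* ramp rupture forces are drawn exactly by inverting the integrated Bell
  hazard in closed form (no time-stepping error); cycles without rupture
  before the force ceiling are flagged censored;
* bead noise is additive Gaussian white noise, default SD 6 nm per raw
  sample at 100 Hz, chosen so the default 20-point boxcar smoothing
  leaves ~1.3 nm of jitter, the level visible in published smoothed
  traces; an Ornstein–Uhlenbeck mode exists because real bead noise is
  temporally correlated.  The published acquisition rate and noise
  magnitude are not printed; these are calibrated stand-ins.
* smoothing is a centered moving average of the stated window — a
  transparent stand-in for the instrument software's "FFT smooth", whose
  exact dialect is unspecified; a width-w boxcar cuts white-noise SD by
  √w, which the tests verify.

Event logs carry the exact model step size at the event force — noise
applies to samples only — so detectors are scored against truth, not
against another estimate.  Identical (config, seed) gives bit-identical
trajectories.

Default kinetic parameters of the fixture constructs are **calibrated,
not measured**: the unlooping law (k₀ = 1.85e−3 s⁻¹, Δx = 1.88 nm)
reproduces the published modal rupture forces ~8/~12/~15 pN at 0.2/1/5
pN/s; the looping law is the two-point solution above; clamp fixtures use
faster unfolding rates than the real I27 (~10⁻³ s⁻¹) so that a 400 s
trace contains all four events — real experiments run over an hour per
trace, which a test suite cannot.

## Trace analysis

**Step detection** slides two adjacent w-sample windows (default 50) over
the analysis channel and flags local maxima of the mean difference, with
two gates: a minimum step (default 3× the noise SD of the channel) and a
Welch-type statistic threshold (default 5).  The statistic's white-noise
SE is the raw-noise SD times the exact l2 norm of the composed
(window-difference ∘ smoothing-boxcar) filter — naively dividing by the
smoothing factor again underestimates the SE several-fold once w exceeds
the smoothing window, which was measured to produce ~4–5 nm false
positives on 40 k-sample traces.  Candidate ties break toward the earlier
sample; sizes come from flanking medians over 2w samples with a guard
band of one smoothing window around the edge (the boxcar blurs the step
into adjacent flanks).  Times are reported on the raw time base.
Detection was chosen over HMMs for determinism and transparency.

**Rupture extraction** takes the largest detected step per ramp cycle
with a 20 nm floor: unlooping steps are ≥50 nm over the relevant force
range, while ramp traces also contain a steep low-force tether-stretching
baseline that the change-point statistic correctly flags but that is not
a rupture.  Censored cycles are counted and excluded.

**Height-ladder occupancy** decomposes an equilibrium hopping trace's
height distribution into N+1 Gaussians with means constrained to
base + n·spacing (spacing refined in the fit) and one shared SD
(state-independent bead noise to first order; a free-SD mode exists).
Estimation is EM with deterministic initialization (base at the 1st
percentile, spacing at the predicted step).  A fitted spacing not
exceeding the noise SD is flagged unresolvable.  Occupancy counts come
from posterior hard assignment of samples; because consecutive samples
are correlated, the bootstrap SE on p̂ from these counts is a lower
bound — a known limitation, acceptable here because the closure criteria
test point recovery of p, not its interval.

## What the closure suite shows — and does not

The acceptance surface (`scripts/acceptance.py`, `tests/test_acceptance.py`)
closes every loop the package claims: generator truth → detector → fits →
thermodynamics.  Problem sizes were fixed once at the scale of the
corresponding experiments: 2000 ramp cycles, 10⁴ looping cycles for the
plateau check and 100 replicates of the 6-point/100-cycle design for
recovery, one 3000 s hopping trace (3×10⁵ samples) for occupancy, 100
clamp traces for detector scoring, 1000 batches of 100 dwells for
lifetime coverage (1000 rather than 100 so the fraction's own binomial
noise, ~2.2% at 100 batches, does not mask the 95.0% exact coverage
against the 93% floor), and 500 forces for the mixture.

Passing closure demonstrates internal consistency under the generator's
assumptions — independent domains, memoryless two-state kinetics, white
(or OU) noise, drift-free baselines.  Real bead data add slow drift,
camera blur and aliasing, bead-size heterogeneity (the 10% force
uncertainty propagated into Δφ), and possible inter-domain coupling; none
of these are simulated, and the detector and ladder-fit defaults should
be revisited on instrument data.  Hidden-Markov dwell modeling,
free-energy-surface reconstruction beyond the Bell picture, and
loading-rate-dependent Δx are out of scope by design.
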