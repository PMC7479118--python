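"""Recovering events and occupancies from bead-height trajectories.

Turns (synthetic or real) trajectories into the quantities the kinetic and
thermodynamic fits consume: step events with signed sizes, rupture forces
from ramp cycles, dwell times per transition direction, and bead-height
occupancy histograms decomposed into an (N+1)-level Gaussian ladder.

The step detector is a sliding two-sample (Welch-type) mean-difference
statistic with non-maximum suppression — deterministic and transparent,
with a minimum-step threshold defaulting to 3x the local noise estimate.
Detectors operate on the smoothed channel when one is present but report
event times on the raw time base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import Trajectory
from .thermo import BinomialOccupancyModel, OccupancyFit

__all__ = [
    "StepEvent",
    "HeightHistogram",
    "estimate_noise_sd",
    "detect_steps",
    "extract_rupture_forces",
    "extract_dwell_times",
    "HeightLadderModel",
    "HeightLadderResults",
    "occupancy_from_heights",
]


@dataclass(frozen=True)
class StepEvent:
    """One detected stepwise extension change."""

    time: float
    force: float
    size: float       # nm, signed (positive = extension increase)
    tstat: float      # Welch mean-difference statistic at the change point
    index: int = -1   # sample index in the trace


def estimate_noise_sd(x: np.ndarray) -> float:
    """Robust per-sample noise SD from the MAD of first differences.

    For white noise, diff(x) has SD √2·σ; the median absolute deviation
    makes the estimate insensitive to the (rare) step discontinuities.
    """
    d = np.diff(np.asarray(x, dtype=float))
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def detect_steps(
    trajectory: Trajectory,
    min_step: float | None = None,
    window: int = 50,
    t_threshold: float = 5.0,
) -> list[StepEvent]:
    """Detect stepwise changes of the extension channel.

    Slides two adjacent windows of ``window`` samples along the analysis
    channel; candidate change points are local maxima (within ±window,
    ties broken toward the earlier sample) of the absolute mean difference
    exceeding both ``min_step`` and ``t_threshold`` noise units.  Sizes are
    re-estimated from flanking medians.  Adding a constant offset to the
    extension leaves the output unchanged.

    ``min_step`` defaults to 3x the raw-channel noise SD estimate divided
    by √(smoothing window) when a smoothed channel is analyzed.
    """
    x = np.asarray(trajectory.analysis_channel, dtype=float)
    n = len(x)
    if n <= 2 * window:
        raise ValueError(f"trace length {n} must exceed 2*window = {2 * window}")

    if min_step is None:
        raw_sd = estimate_noise_sd(trajectory.extension)
        w_smooth = trajectory.meta.get("smoothing_window", 1)
        channel_sd = raw_sd / np.sqrt(w_smooth) if trajectory.extension_smooth is not None else raw_sd
        min_step = 3.0 * channel_sd

    # mean difference between the windows after/before each boundary i
    c = np.concatenate([[0.0], np.cumsum(x)])
    i = np.arange(window, n - window + 1)
    mean_after = (c[i + window] - c[i]) / window
    mean_before = (c[i] - c[i - window]) / window
    d = mean_after - mean_before

    # Welch statistic with a single robust noise scale (state-independent
    # bead noise).  The mean difference is a linear filter on the raw
    # samples — the window difference composed with the smoothing boxcar —
    # so its white-noise SE is the raw SD times the filter's l2 norm.
    # (Averaging already-smoothed samples does NOT gain the smoothing
    # factor again once window >> smoothing window.)
    raw_sd = estimate_noise_sd(trajectory.extension)
    m = int(trajectory.meta.get("smoothing_window", 1)) \
        if trajectory.extension_smooth is not None else 1
    kern = np.convolve(
        np.concatenate([np.full(window, -1.0 / window),
                        np.full(window, 1.0 / window)]),
        np.ones(m) / m)
    se = max(raw_sd * float(np.sqrt((kern ** 2).sum())), 1e-12)
    t = d / se

    absd = np.abs(d)
    cand = np.flatnonzero((absd >= min_step) & (np.abs(t) >= t_threshold))
    events: list[StepEvent] = []
    taken = np.zeros(len(d), dtype=bool)
    # strongest first; suppress neighbors within one window
    for j in cand[np.lexsort((cand, -absd[cand]))]:
        if taken[j]:
            continue
        lo, hi = max(0, j - window), min(len(d), j + window + 1)
        if absd[lo:hi].max() > absd[j]:
            continue
        # tie-break toward the earlier sample
        j_eff = lo + int(np.flatnonzero(absd[lo:hi] == absd[j])[0])
        taken[lo:hi] = True
        idx = int(i[j_eff])
        # flanking medians skip a guard band where smoothing blurs the edge
        g = int(trajectory.meta.get("smoothing_window", 1)) \
            if trajectory.extension_smooth is not None else 1
        g = min(g, window - 1)
        flank = 2 * window  # wider than the detection window: steadier medians
        lo_f = max(idx - g - flank, 0)
        hi_f = min(idx + g + flank, n)
        size = float(np.median(x[idx + g:hi_f]) - np.median(x[lo_f:idx - g]))
        if abs(size) < min_step:
            continue
        events.append(StepEvent(
            time=float(trajectory.time[idx]),
            force=float(trajectory.force[idx]),
            size=size, tstat=float(t[j_eff]), index=idx,
        ))
    events.sort(key=lambda e: e.time)
    return events


def extract_rupture_forces(
    trajectories: Sequence[Trajectory],
    min_step: float = 20.0,
    window: int = 50,
) -> tuple[np.ndarray, int]:
    """Rupture force per ramp cycle: the force at the largest detected step.

    The unlooping step (tens of nm over the relevant force range) dwarfs
    both domain unfolding and the slow tether-stretching drift a ramp
    superimposes on the trace, so the default 20 nm floor isolates it.
    Cycles with no detectable step are counted as censored and excluded.
    Returns (forces, n_censored).
    """
    forces, censored = [], 0
    for traj in trajectories:
        if traj.meta.get("protocol") not in (None, "ramp"):
            raise ValueError("extract_rupture_forces expects ramp trajectories")
        events = detect_steps(traj, min_step=min_step, window=window)
        if not events:
            censored += 1
            continue
        biggest = max(events, key=lambda e: abs(e.size))
        forces.append(biggest.force)
    if not forces:
        warnings.warn("no rupture steps detected in any trajectory")
    return np.asarray(forces), censored


def extract_dwell_times(
    trajectory: Trajectory,
    events: Sequence[StepEvent],
) -> dict[str, np.ndarray]:
    """Dwell durations preceding each event, keyed by transition direction.

    The dwell before the first event is measured from force arrival (t of
    the first sample); subsequent dwells from the previous event.  Positive
    steps are labeled "unfold" (extension gain: unfolding/unlooping),
    negative ones "refold".  Zero events yields empty lists (censoring is
    the caller's record).
    """
    times = [e.time for e in events]
    if any(later <= earlier for earlier, later in zip(times, times[1:])):
        raise ValueError("events must be strictly increasing in time")
    t0 = float(trajectory.time[0])
    dwells: dict[str, list[float]] = {"unfold": [], "refold": []}
    prev = t0
    for e in events:
        key = "unfold" if e.size > 0 else "refold"
        dwells[key].append(e.time - prev)
        prev = e.time
    return {k: np.asarray(v) for k, v in dwells.items()}


# ---------------------------------------------------------------------------
# Gaussian ladder decomposition of the bead-height histogram
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeightHistogram:
    """Bead-height histogram with its fitted multi-peak decomposition.

    ``peaks`` are (mean nm, sd nm, weight) triples ordered by the number of
    unfolded domains; peak means form a strictly increasing ladder and the
    weights sum to 1.
    """

    bin_centers: np.ndarray
    densities: np.ndarray
    peaks: list[tuple[float, float, float]]

    def fitted_density(self, x=None) -> np.ndarray:
        x = self.bin_centers if x is None else np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for mean, sd, w in self.peaks:
            out += w * np.exp(-0.5 * ((x - mean) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
        return out


class HeightLadderModel:
    """(N+1)-component Gaussian ladder fit of an equilibrium hopping trace.

    Means are constrained to base + n·spacing with the spacing refined in
    the fit; a single shared SD models the state-independent bead noise
    (``shared_sd=False`` frees it per level).  Estimated by EM with
    deterministic initialization, so refits are reproducible.
    """

    MAX_ITER = 300
    TOL = 1e-9

    def __init__(self, heights: Sequence[float], N: int, expected_step: float,
                 shared_sd: bool = True) -> None:
        heights = np.asarray(heights, dtype=float)
        if N < 1:
            raise ValueError("N must be >= 1")
        if expected_step <= 0:
            raise ValueError("expected_step must be > 0")
        if heights.ndim != 1 or len(heights) < 10 * (N + 1):
            raise ValueError("need at least 10 samples per occupancy level")
        self.heights = heights
        self.N = N
        self.expected_step = expected_step
        self.shared_sd = shared_sd

    def fit(self) -> "HeightLadderResults":
        h, N, step = self.heights, self.N, self.expected_step
        levels = np.arange(N + 1)
        base = float(np.quantile(h, 0.01))
        spacing = step
        sd = np.full(N + 1, max(np.std(h) / (N + 1), 1e-3))
        w = np.full(N + 1, 1.0 / (N + 1))
        prev = -np.inf
        it = 0
        for it in range(1, self.MAX_ITER + 1):
            mu = base + levels * spacing
            dens = w * np.exp(-0.5 * ((h[:, None] - mu) / sd) ** 2) / (
                sd * np.sqrt(2 * np.pi))
            tot = np.maximum(dens.sum(axis=1), 1e-300)
            loglik = float(np.sum(np.log(tot)))
            resp = dens / tot[:, None]
            nk = resp.sum(axis=0)
            w = nk / len(h)
            # weighted LS of h on the level index: refit base and spacing
            sw = nk.sum()
            sn = (nk * levels).sum()
            snn = (nk * levels**2).sum()
            shn = (resp * h[:, None]).sum(axis=0)
            sh = float(shn.sum())
            snh = float((shn * levels).sum())
            det = sw * snn - sn * sn
            if det > 0:
                base = (snn * sh - sn * snh) / det
                spacing = (sw * snh - sn * sh) / det
            mu = base + levels * spacing
            var = (resp * (h[:, None] - mu) ** 2).sum(axis=0)
            if self.shared_sd:
                sd = np.full(N + 1, np.sqrt(max(var.sum() / len(h), 1e-12)))
            else:
                sd = np.sqrt(np.maximum(var / np.maximum(nk, 1e-12), 1e-12))
            if abs(loglik - prev) < self.TOL * (1 + abs(loglik)):
                break
            prev = loglik

        mu = base + levels * spacing
        resolved = spacing > float(np.max(sd))
        # hard per-sample assignment -> occupancy counts
        dens = w * np.exp(-0.5 * ((h[:, None] - mu) / sd) ** 2) / (
            sd * np.sqrt(2 * np.pi))
        assign = np.argmax(dens, axis=1)
        counts = np.bincount(assign, minlength=N + 1).astype(float)

        nbins = max(50, 4 * (N + 1))
        densities, edges = np.histogram(h, bins=nbins, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        hist = HeightHistogram(
            bin_centers=centers, densities=densities,
            peaks=[(float(m), float(s), float(wi))
                   for m, s, wi in zip(mu, sd, w)],
        )
        return HeightLadderResults(
            model=self, base=float(base), spacing=float(spacing),
            sd=sd.copy(), weights=w.copy(), counts=counts,
            histogram=hist, resolved=bool(resolved), n_iter=it,
        )


@dataclass(frozen=True)
class HeightLadderResults:
    model: HeightLadderModel
    base: float
    spacing: float
    sd: np.ndarray
    weights: np.ndarray
    counts: np.ndarray
    histogram: HeightHistogram
    resolved: bool
    n_iter: int

    def summary(self) -> str:
        lines = ["Gaussian ladder fit", "==================="]
        lines.append(f"levels          {self.model.N + 1}")
        lines.append(f"base (nm)       {self.base:.3f}")
        lines.append(f"spacing (nm)    {self.spacing:.3f}")
        lines.append(f"shared sd (nm)  {self.sd[0]:.3f}")
        lines.append(f"weights         {np.array2string(self.weights, precision=3)}")
        lines.append(f"resolved        {self.resolved}")
        return "\n".join(lines)


def occupancy_from_heights(
    trajectory: Trajectory,
    N: int,
    expected_step: float,
    shared_sd: bool = True,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> tuple[HeightLadderResults, OccupancyFit]:
    """Occupancy histogram and binomial p from an equilibrium hopping trace.

    Decomposes the bead-height distribution of the analysis channel into an
    (N+1)-level Gaussian ladder, integrates the per-level weights into an
    occupancy histogram, and fits the single-domain unfolded probability.
    Flags (rather than hides) an unresolvable ladder where the fitted
    spacing does not exceed the noise SD.
    """
    ladder = HeightLadderModel(trajectory.analysis_channel, N, expected_step,
                               shared_sd=shared_sd).fit()
    if not ladder.resolved:
        warnings.warn("height ladder spacing does not resolve above the noise "
                      "SD; occupancy weights may be unreliable")
    occ = BinomialOccupancyModel(ladder.counts, N).fit(
        n_bootstrap=n_bootstrap, seed=seed)
    return ladder, occ
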