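"""Synthetic bead-height trajectory generator.

Generates stochastic magnetic-tweezers trajectories of tethered constructs
with known ground truth, so every downstream analysis stage (step
detection, dwell extraction, occupancy fitting, kinetic fits) can be
validated end to end without instrument data.

Three acquisition protocols are emulated:

* force clamp — continuous-time Markov (Gillespie) dynamics over a
  transition graph of construct states with Bell rates at the clamp force;
* constant-loading-rate ramp — exact first-passage sampling of the rupture
  force by inversion of the integrated Bell hazard;
* force-jump looping cycles — repeated (high force → hold force → detection
  force) cycles scoring looped/unlooped outcomes after a waiting time Δt.

Bead noise is additive Gaussian white noise per sample (default SD 6 nm
raw, so that 20-point smoothing leaves ~1.3 nm of jitter); an optional
Ornstein-Uhlenbeck mode provides temporally correlated noise.  Noise
applies only to the sampled extension channel — the event log records the
exact model step sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
import numpy as np
import pandas as pd

from .kinetics import LoadingProtocol, RateParams, TwoStateRates, bell_rate
from .polymer import ConstructState, Environment, state_extension

__all__ = [
    "Transition",
    "KineticScheme",
    "SimConfig",
    "TransitionEvent",
    "Trajectory",
    "LoopingCycleResult",
    "simulate_clamp",
    "simulate_ramp",
    "sample_rupture_forces",
    "simulate_looping_cycles",
    "simulate_two_state_cycles",
    "apply_smoothing",
]


@dataclass(frozen=True)
class Transition:
    """Directed transition of the state graph with a Bell rate law.

    ``multiplicity`` scales the rate for aggregated states (e.g. with n of N
    identical domains still folded, the total unfolding rate is
    (N−n)·k(F)).
    """

    src: str
    dst: str
    rate: RateParams
    label: str = ""
    multiplicity: float = 1.0


@dataclass(frozen=True)
class KineticScheme:
    """Named construct states plus the transitions connecting them."""

    states: dict[str, ConstructState]
    transitions: list[Transition]
    initial: str

    def __post_init__(self) -> None:
        for t in self.transitions:
            if t.src not in self.states or t.dst not in self.states:
                raise ValueError(f"transition {t.label or t.src}->{t.dst} "
                                 "references unknown state")
        if self.initial not in self.states:
            raise ValueError(f"unknown initial state {self.initial!r}")

    def outgoing(self, label: str) -> list[Transition]:
        return [t for t in self.transitions if t.src == label]


@dataclass(frozen=True)
class SimConfig:
    """Simulation configuration: construct, environment, acquisition, seed."""

    scheme: KineticScheme
    environment: Environment
    sampling_rate: float = 100.0    # Hz
    noise_sd: float = 6.0           # nm, raw per-sample SD
    smoothing_window: int = 20      # samples
    noise_mode: str = "white"       # "white" | "ou"
    noise_tau: float = 0.05         # s, OU correlation time
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.noise_mode not in ("white", "ou"):
            raise ValueError("noise_mode must be 'white' or 'ou'")


@dataclass(frozen=True)
class TransitionEvent:
    """One logged state change: exact time, force, and model step size."""

    time: float
    label: str
    step_size: float
    force: float
    src: str = ""
    dst: str = ""


@dataclass
class Trajectory:
    """Sampled (time, force, extension) trace with hidden truth attached.

    ``extension`` is the noisy raw channel; ``extension_smooth`` is filled
    by :func:`apply_smoothing`.  ``hidden_state`` holds the generator's
    state label per sample and ``events`` the exact transition log — the
    ground truth downstream detectors are scored against.
    """

    time: np.ndarray
    force: np.ndarray
    extension: np.ndarray
    hidden_state: np.ndarray
    events: list[TransitionEvent]
    extension_smooth: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    @property
    def sampling_rate(self) -> float:
        return float(self.meta.get("sampling_rate",
                                   1.0 / np.median(np.diff(self.time))))

    @property
    def analysis_channel(self) -> np.ndarray:
        """Smoothed channel if present, else raw."""
        return (self.extension_smooth
                if self.extension_smooth is not None else self.extension)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({
            "time_s": self.time,
            "force_pN": self.force,
            "extension_nm": self.extension,
            "state": self.hidden_state,
        })
        if self.extension_smooth is not None:
            df.insert(3, "extension_smooth_nm", self.extension_smooth)
        with open(path, "w") as fh:
            fh.write(f"# mtweez trajectory\n# meta = {json.dumps(self.meta)}\n")
            ev = [[e.time, e.label, e.step_size, e.force] for e in self.events]
            fh.write(f"# events = {json.dumps(ev)}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "Trajectory":
        meta, events = {}, []
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                if line.startswith("# meta = "):
                    meta = json.loads(line[len("# meta = "):])
                elif line.startswith("# events = "):
                    events = [TransitionEvent(time=e[0], label=e[1],
                                              step_size=e[2], force=e[3])
                              for e in json.loads(line[len("# events = "):])]
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        smooth = (df["extension_smooth_nm"].to_numpy()
                  if "extension_smooth_nm" in df else None)
        return cls(
            time=df["time_s"].to_numpy(),
            force=df["force_pN"].to_numpy(),
            extension=df["extension_nm"].to_numpy(),
            hidden_state=df["state"].to_numpy(dtype=str),
            events=events, extension_smooth=smooth, meta=meta,
        )


@dataclass(frozen=True)
class LoopingCycleResult:
    """Outcome of one force-jump looping cycle."""

    cycle: int
    delta_t: float
    looped: bool


# ---------------------------------------------------------------------------
# noise
# ---------------------------------------------------------------------------

def _noise(config: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    if config.noise_sd == 0:
        return np.zeros(n)
    if config.noise_mode == "white":
        return rng.normal(0.0, config.noise_sd, size=n)
    # Ornstein-Uhlenbeck: stationary, per-sample SD noise_sd
    dt = 1.0 / config.sampling_rate
    a = np.exp(-dt / config.noise_tau)
    innov = rng.normal(0.0, config.noise_sd * np.sqrt(1 - a * a), size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, config.noise_sd)
    for i in range(1, n):
        out[i] = a * out[i - 1] + innov[i]
    return out


# ---------------------------------------------------------------------------
# force clamp
# ---------------------------------------------------------------------------

def simulate_clamp(config: SimConfig, force: float, duration: float) -> Trajectory:
    """Force-clamp trajectory by exact-waiting-time (Gillespie) simulation.

    State dynamics follow the scheme's transition graph with Bell rates
    evaluated at the clamp force; the sampled extension is the state
    extension plus bead noise.  Identical (config, seed) gives bit-identical
    output.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    env = config.environment
    scheme = config.scheme
    rng = np.random.default_rng(config.seed)

    level = {lbl: state_extension(s, force, env)
             for lbl, s in scheme.states.items()}

    t, current = 0.0, scheme.initial
    events: list[TransitionEvent] = []
    switch_times, switch_states = [0.0], [current]
    absorbing = not scheme.outgoing(current)
    while t < duration:
        outs = scheme.outgoing(current)
        if not outs:
            break
        rates = np.array([t_.multiplicity * bell_rate(force, t_.rate, env)
                          for t_ in outs])
        total = rates.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        chosen = outs[rng.choice(len(outs), p=rates / total)]
        events.append(TransitionEvent(
            time=t, label=chosen.label or f"{chosen.src}->{chosen.dst}",
            step_size=level[chosen.dst] - level[chosen.src],
            force=force, src=chosen.src, dst=chosen.dst,
        ))
        current = chosen.dst
        switch_times.append(t)
        switch_states.append(current)

    n = int(np.floor(duration * config.sampling_rate))
    time = np.arange(n) / config.sampling_rate
    idx = np.searchsorted(switch_times, time, side="right") - 1
    states = np.array(switch_states, dtype=object)[idx].astype(str)
    ext = np.array([level[s] for s in switch_states])[idx] + _noise(config, n, rng)

    traj = Trajectory(
        time=time, force=np.full(n, float(force)), extension=ext,
        hidden_state=states, events=events,
        meta={"protocol": "clamp", "force": force, "duration": duration,
              "seed": config.seed, "sampling_rate": config.sampling_rate,
              "noise_sd": config.noise_sd, "absorbing": absorbing,
              "temperature": env.temperature},
    )
    if config.smoothing_window > 1:
        traj = apply_smoothing(traj, config.smoothing_window)
    return traj


# ---------------------------------------------------------------------------
# force ramp
# ---------------------------------------------------------------------------

def _rupture_transition(scheme: KineticScheme) -> Transition:
    outs = [t for t in scheme.outgoing(scheme.initial) if t.rate.delta_x > 0]
    if len(outs) != 1:
        raise ValueError("ramp simulation needs exactly one force-accelerated "
                         "transition out of the initial state")
    return outs[0]


def sample_rupture_forces(protocol: LoadingProtocol, params: RateParams,
                          env: Environment, n: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Exact rupture-force samples under a linear ramp (NaN where censored).

    Inverts the integrated Bell hazard in closed form: with u ~ Exp(1),
    F = (kBT/Δx)·ln(e^{F₀Δx/kBT} + u·r·Δx/(k0·kBT)).
    """
    if params.delta_x <= 0:
        raise ValueError("rupture sampling requires delta_x > 0")
    a = params.delta_x / env.kBT
    u = rng.exponential(1.0, size=n)
    f = np.log(np.exp(a * protocol.f_start)
               + u * protocol.rate * a / params.k0) / a
    return np.where(f <= protocol.f_end, f, np.nan)


def simulate_ramp(config: SimConfig, protocol: LoadingProtocol
                  ) -> tuple[Trajectory, float | None]:
    """Constant-loading-rate ramp; returns (trajectory, rupture force).

    The rupture force is sampled exactly from the inverse integrated hazard
    of the initial state's force-accelerated transition; the trajectory's
    extension follows the construct state along the ramp (interpolated on a
    force grid) plus bead noise.  A cycle with no rupture before f_end is
    returned with rupture force None and flagged censored.
    """
    env = config.environment
    scheme = config.scheme
    rng = np.random.default_rng(config.seed)
    trans = _rupture_transition(scheme)
    trans_scaled = RateParams(k0=trans.rate.k0 * trans.multiplicity,
                              delta_x=trans.rate.delta_x)

    f_rupt = sample_rupture_forces(protocol, trans_scaled, env, 1, rng)[0]
    censored = bool(np.isnan(f_rupt))

    duration = (protocol.f_end - protocol.f_start) / protocol.rate
    n = int(np.floor(duration * config.sampling_rate))
    time = np.arange(n) / config.sampling_rate
    force = protocol.f_start + protocol.rate * time

    fgrid = np.linspace(protocol.f_start, protocol.f_end, 200)
    ext_of = {lbl: np.interp(force, fgrid,
                             [state_extension(s, f, env) for f in fgrid])
              for lbl, s in ((trans.src, scheme.states[trans.src]),
                             (trans.dst, scheme.states[trans.dst]))}
    ruptured = np.zeros(n, dtype=bool) if censored else force >= f_rupt
    ext = np.where(ruptured, ext_of[trans.dst], ext_of[trans.src])
    states = np.where(ruptured, trans.dst, trans.src)
    ext = ext + _noise(config, n, rng)

    events = []
    if not censored:
        s_before = state_extension(scheme.states[trans.src], f_rupt, env)
        s_after = state_extension(scheme.states[trans.dst], f_rupt, env)
        events.append(TransitionEvent(
            time=float((f_rupt - protocol.f_start) / protocol.rate),
            label=trans.label or "rupture",
            step_size=s_after - s_before, force=float(f_rupt),
            src=trans.src, dst=trans.dst,
        ))

    traj = Trajectory(
        time=time, force=force, extension=ext, hidden_state=states.astype(str),
        events=events,
        meta={"protocol": "ramp", "loading_rate": protocol.rate,
              "f_start": protocol.f_start, "f_end": protocol.f_end,
              "seed": config.seed, "sampling_rate": config.sampling_rate,
              "noise_sd": config.noise_sd, "censored": censored,
              "temperature": env.temperature},
    )
    if config.smoothing_window > 1:
        traj = apply_smoothing(traj, config.smoothing_window)
    return traj, (None if censored else float(f_rupt))


# ---------------------------------------------------------------------------
# force-jump looping cycles
# ---------------------------------------------------------------------------

def simulate_two_state_cycles(rates: TwoStateRates, delta_t: float,
                              n_cycles: int, rng: np.random.Generator
                              ) -> np.ndarray:
    """Terminal looped/unlooped outcome of n_cycles two-state evolutions.

    Each cycle starts unlooped and evolves the loop⇄unloop chain for Δt;
    returns a boolean array (True = looped at Δt).
    """
    out = np.empty(n_cycles, dtype=bool)
    k = (rates.k_p, rates.k_u)
    for c in range(n_cycles):
        t, looped = 0.0, False
        while True:
            rate = k[1] if looped else k[0]
            if rate == 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= delta_t:
                break
            looped = not looped
        out[c] = looped
    return out


def simulate_looping_cycles(config: SimConfig, hold_force: float,
                            delta_t: float, detect_force: float,
                            n_cycles: int) -> list[LoopingCycleResult]:
    """Force-jump looping assay: repeated cycles scored at the detect force.

    Per cycle the construct starts unlooped, evolves the two-state
    loop/unloop chain at the hold force for Δt, and the terminal state is
    read out (at the detection force, where the looped/unlooped extension
    gap is large).  The empirical looped fraction estimates P(Δt).
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    env = config.environment
    scheme = config.scheme
    loops = [t for t in scheme.transitions if t.rate.delta_x < 0]
    unloops = [t for t in scheme.transitions if t.rate.delta_x > 0]
    if len(loops) != 1 or len(unloops) != 1:
        raise ValueError("looping assay needs one loop (delta_x<0) and one "
                         "unloop (delta_x>0) transition")
    rates = TwoStateRates(
        k_p=bell_rate(hold_force, loops[0].rate, env),
        k_u=bell_rate(hold_force, unloops[0].rate, env),
    )
    rng = np.random.default_rng(config.seed)
    looped = simulate_two_state_cycles(rates, delta_t, n_cycles, rng)
    return [LoopingCycleResult(cycle=c, delta_t=delta_t, looped=bool(l))
            for c, l in enumerate(looped)]


# ---------------------------------------------------------------------------
# smoothing
# ---------------------------------------------------------------------------

def apply_smoothing(trajectory: Trajectory, window: int) -> Trajectory:
    """Low-pass the extension channel with a centered moving average.

    The raw channel is preserved; the smoothed one lands in
    ``extension_smooth``.  window = 1 is the identity.  A boxcar of width w
    reduces white-noise SD by √w.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(trajectory.extension)
    if window > n:
        raise ValueError(f"window {window} exceeds trace length {n}")
    if window == 1:
        smooth = trajectory.extension.copy()
    else:
        left = window // 2
        right = window - 1 - left
        padded = np.pad(trajectory.extension, (left, right), mode="edge")
        kernel = np.ones(window) / window
        smooth = np.convolve(padded, kernel, mode="valid")
    out = replace(trajectory)
    out.extension_smooth = smooth
    out.meta = {**trajectory.meta, "smoothing_window": window}
    return out
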