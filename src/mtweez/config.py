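"""Configuration files and run manifests.

Constructs, kinetic parameters and acquisition settings are described in a
single JSON-syntax configuration file.  ``load_config`` validates the
schema strictly — unknown keys are rejected and every type violation is
reported with its path — and fills documented defaults, so a round-tripped
config is self-contained.  ``build_sim_config`` turns a validated config
plus a seed into a ready :class:`mtweez.simulate.SimConfig`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib.metadata import version as _pkg_version
from pathlib import Path

from .kinetics import RateParams
from .polymer import Environment, FoldedDomainParams
from .simulate import SimConfig

__all__ = ["ConfigError", "load_config", "validate_config",
           "build_sim_config", "RunManifest"]

_DOMAINS = {"I27": (89, 4.4), "SR4": (104, 5.0)}

_DEFAULTS = {
    "temperature": 23.0,
    "simulation": {
        "sampling_rate": 100.0,
        "noise_sd": 6.0,
        "smoothing_window": 20,
        "noise_mode": "white",
        "noise_tau": 0.05,
    },
}


class ConfigError(ValueError):
    """Raised with an itemized list of schema violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n  " + "\n  ".join(errors))


def _check(errors, cond, path, msg):
    if not cond:
        errors.append(f"{path}: {msg}")
    return cond


def _check_rate(errors, obj, path) -> None:
    if not _check(errors, isinstance(obj, dict), path, "must be an object"):
        return
    for key in obj:
        if key not in ("k0", "delta_x"):
            errors.append(f"{path}.{key}: unknown key")
    for key in ("k0", "delta_x"):
        if _check(errors, key in obj, f"{path}.{key}", "missing"):
            _check(errors, isinstance(obj[key], (int, float)),
                   f"{path}.{key}", "must be a number")
    if "k0" in obj and isinstance(obj["k0"], (int, float)):
        _check(errors, obj["k0"] > 0, f"{path}.k0", "must be > 0")


def validate_config(raw: dict) -> dict:
    """Validate and normalize a configuration dict; defaults filled in.

    Raises :class:`ConfigError` listing every violation with its path.
    """
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError(["top level must be a JSON object"])
    known_top = {"temperature", "construct", "simulation"}
    for key in raw:
        if key not in known_top:
            errors.append(f"{key}: unknown key")

    cfg = {"temperature": raw.get("temperature", _DEFAULTS["temperature"])}
    _check(errors, isinstance(cfg["temperature"], (int, float)),
           "temperature", "must be a number")
    if isinstance(cfg["temperature"], (int, float)):
        _check(errors, cfg["temperature"] > -273.15, "temperature",
               "must exceed absolute zero")

    sim = {**_DEFAULTS["simulation"], **raw.get("simulation", {})}
    for key in raw.get("simulation", {}):
        if key not in _DEFAULTS["simulation"]:
            errors.append(f"simulation.{key}: unknown key")
    for key in ("sampling_rate", "noise_sd", "noise_tau"):
        _check(errors, isinstance(sim[key], (int, float)) and sim[key] >= 0,
               f"simulation.{key}", "must be a non-negative number")
    _check(errors, isinstance(sim["smoothing_window"], int)
           and sim["smoothing_window"] >= 1,
           "simulation.smoothing_window", "must be an integer >= 1")
    _check(errors, sim["noise_mode"] in ("white", "ou"),
           "simulation.noise_mode", "must be 'white' or 'ou'")
    cfg["simulation"] = sim

    con = raw.get("construct", {"type": "looping"})
    if _check(errors, isinstance(con, dict), "construct", "must be an object"):
        ctype = con.get("type")
        _check(errors, ctype in ("looping", "tandem"),
               "construct.type", "must be 'looping' or 'tandem'")
        if ctype == "looping":
            for key in con:
                if key not in ("type", "loop_rate", "unloop_rate"):
                    errors.append(f"construct.{key}: unknown key")
            for rk in ("loop_rate", "unloop_rate"):
                if rk in con:
                    _check_rate(errors, con[rk], f"construct.{rk}")
        elif ctype == "tandem":
            allowed = {"type", "n_domains", "domain", "n_residues",
                       "rod_length", "unfold_rate", "refold_rate"}
            for key in con:
                if key not in allowed:
                    errors.append(f"construct.{key}: unknown key")
            nd = con.get("n_domains", 4)
            _check(errors, isinstance(nd, int) and nd >= 1,
                   "construct.n_domains", "must be an integer >= 1")
            con.setdefault("n_domains", nd)
            if "domain" in con:
                _check(errors, con["domain"] in _DOMAINS,
                       "construct.domain", f"must be one of {sorted(_DOMAINS)}")
            else:
                for key in ("n_residues", "rod_length"):
                    ok = _check(errors, key in con, f"construct.{key}",
                                "required when no named domain is given")
                    if ok:
                        _check(errors, isinstance(con[key], (int, float))
                               and con[key] > 0,
                               f"construct.{key}", "must be a positive number")
            if "unfold_rate" in con:
                _check_rate(errors, con["unfold_rate"], "construct.unfold_rate")
            else:
                errors.append("construct.unfold_rate: missing")
            if con.get("refold_rate") is not None and "refold_rate" in con:
                _check_rate(errors, con["refold_rate"], "construct.refold_rate")
        cfg["construct"] = con
    if errors:
        raise ConfigError(errors)
    return cfg


def load_config(path) -> dict:
    """Read, validate and normalize a JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError([f"not valid JSON: {exc}"]) from exc
    return validate_config(raw)


def build_sim_config(cfg: dict, seed: int) -> SimConfig:
    """Assemble a SimConfig from a validated configuration and a seed."""
    from . import constructs  # deferred: constructs imports simulate

    env = Environment(cfg["temperature"])
    con = cfg["construct"]
    if con["type"] == "looping":
        scheme = constructs.looping_scheme(
            loop_rate=_rate(con.get("loop_rate"), constructs.LOOP_RATE),
            unloop_rate=_rate(con.get("unloop_rate"), constructs.UNLOOP_RATE),
        )
    else:
        if "domain" in con:
            n_res, rod = _DOMAINS[con["domain"]]
        else:
            n_res, rod = con["n_residues"], con["rod_length"]
        refold = con.get("refold_rate")
        scheme = constructs.tandem_scheme(
            con["n_domains"],
            residues_per_domain=int(n_res),
            folded=FoldedDomainParams(rod_length=float(rod)),
            unfold_rate=_rate(con["unfold_rate"], None),
            refold_rate=_rate(refold, None) if refold else None,
        )
    sim = cfg["simulation"]
    return SimConfig(scheme=scheme, environment=env, seed=seed,
                     sampling_rate=sim["sampling_rate"],
                     noise_sd=sim["noise_sd"],
                     smoothing_window=sim["smoothing_window"],
                     noise_mode=sim["noise_mode"],
                     noise_tau=sim["noise_tau"])


def _rate(obj: dict | None, default: RateParams | None) -> RateParams:
    if obj is None:
        if default is None:
            raise ValueError("rate parameters required")
        return default
    return RateParams(k0=float(obj["k0"]), delta_x=float(obj["delta_x"]))


@dataclass
class RunManifest:
    """Traceability record written alongside every CLI output."""

    command: str
    seed: int | None
    config_digest: str | None
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    timestamp: str = ""
    package_version: str = ""

    def __post_init__(self) -> None:
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        if not self.package_version:
            try:
                self.package_version = _pkg_version("mtweez")
            except Exception:
                self.package_version = "unknown"

    @staticmethod
    def digest(cfg: dict) -> str:
        return hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")
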