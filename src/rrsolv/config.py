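"""Run configuration: TOML sections mirroring each pipeline stage.

A config file has sections ``[run]``, ``[synthetic]``, ``[solvation]``,
``[fq]`` and ``[spectra]``; any subset may be present and every key has a
documented default.  Unknown sections or keys are rejected with a
nearest-key suggestion, and numeric values are validated against their
allowed ranges at load time.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable


class ConfigError(ValueError):
    pass


def _positive(x) -> bool:
    return isinstance(x, (int, float)) and x > 0


def _nonneg(x) -> bool:
    return isinstance(x, (int, float)) and x >= 0


def _count(x) -> bool:
    return isinstance(x, int) and x >= 1


def _any(x) -> bool:
    return True


# section -> key -> (default, validator, constraint description)
SCHEMA: dict[str, dict[str, tuple[Any, Callable[[Any], bool], str]]] = {
    "run": {
        "seed": (0, lambda x: isinstance(x, int) and x >= 0, "integer >= 0"),
        "outdir": ("runs/demo", lambda x: isinstance(x, str), "string path"),
        "log_level": ("INFO", lambda x: x in ("DEBUG", "INFO", "WARNING", "ERROR"),
                      "DEBUG|INFO|WARNING|ERROR"),
    },
    "synthetic": {
        "n_waters": (120, _count, "count >= 1"),
        "radius": (17.0, _positive, "> 0 Å"),
        "n_frames": (20, _count, "count >= 1"),
        "jitter": (0.05, _nonneg, ">= 0 Å"),
        "hb_bias": ({"N9": 2, "O10": 2, "O12": 1},
                    lambda x: isinstance(x, dict) and all(
                        isinstance(v, int) and v >= 0 for v in x.values()),
                    "map site -> count >= 0"),
        "min_dist": (2.4, _positive, "> 0 Å"),
        "n_snapshots": (20, _count, "count >= 1"),
        "sigma_energy": (500.0, _nonneg, ">= 0 cm-1"),
        "sigma_freq": (5.0, _nonneg, ">= 0 cm-1"),
        "gradient_jitter": (0.05, _nonneg, ">= 0 (fraction)"),
    },
    "solvation": {
        "r_max": (8.0, _positive, "> 0 Å"),
        "dr": (0.05, _positive, "> 0 Å"),
        "d_cut": (3.5, _positive, "> 0 Å"),
        "theta_cut": (30.0, _positive, "> 0 degrees"),
        "r_cut": (3.5, _positive, "> 0 Å (first-shell integration bound)"),
    },
    "fq": {
        "chi_O": (0.10914, _any, "hartree/e"),
        "chi_H": (0.0, _any, "hartree/e"),
        "eta_O": (0.59215, _positive, "> 0 hartree/e²"),
        "eta_H": (0.56251, _positive, "> 0 hartree/e²"),
        "kernel": ("ohno", lambda x: x in ("ohno", "coulomb"), "ohno|coulomb"),
        "water_charge": (0.0, _any, "e"),
    },
    "spectra": {
        "gamma": (200.0, _positive, "> 0 cm-1 (homogeneous damping)"),
        "fwhm_uvvis_ev": (0.6, _positive, "> 0 eV"),
        "fwhm_raman": (8.0, _positive, "> 0 cm-1"),
        "shape": ("lorentzian", lambda x: x in ("lorentzian", "gaussian"),
                  "lorentzian|gaussian"),
        "w0_raman_nm": (1064.0, _positive, "> 0 nm"),
        "w0_rr_nm": (266.0, _positive, "> 0 nm"),
        "rrep_min": (30000.0, _positive, "> 0 cm-1"),
        "rrep_max": (65000.0, _positive, "> 0 cm-1"),
        "rrep_points": (15, _count, "count >= 1"),
        "rrep_snapshots": (10, _count, "count >= 1 (ensemble subset for profiles)"),
        "max_quanta": (10, _count, "count >= 1"),
        "weight_cutoff": (1e-10, _positive, "> 0"),
    },
}


@dataclass(frozen=True)
class RunConfig:
    run: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)
    solvation: dict = field(default_factory=dict)
    fq: dict = field(default_factory=dict)
    spectra: dict = field(default_factory=dict)

    @property
    def seed(self) -> int:
        return self.run["seed"]

    @property
    def outdir(self) -> Path:
        return Path(self.run["outdir"])

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        doc = {s: dict(getattr(self, s)) for s in SCHEMA}
        doc["run"].pop("outdir", None)
        doc["run"].pop("log_level", None)
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _suggest(key: str, known) -> str:
    near = difflib.get_close_matches(key, list(known), n=1)
    return f" (did you mean {near[0]!r}?)" if near else ""


def validate_config(raw: dict) -> RunConfig:
    sections = {}
    for sec in raw:
        if sec not in SCHEMA:
            raise ConfigError(f"unknown section [{sec}]{_suggest(sec, SCHEMA)}")
    for sec, keys in SCHEMA.items():
        given = dict(raw.get(sec, {}))
        for key in given:
            if key not in keys:
                raise ConfigError(
                    f"unknown key {key!r} in [{sec}]{_suggest(key, keys)}")
        merged = {}
        for key, (default, check, bound) in keys.items():
            val = given.get(key, default)
            if isinstance(val, int) and isinstance(default, float):
                val = float(val)
            if not check(val):
                raise ConfigError(
                    f"[{sec}] {key} = {val!r} violates the bound: {bound}")
            merged[key] = val
        sections[sec] = merged
    if sections["spectra"]["rrep_min"] >= sections["spectra"]["rrep_max"]:
        raise ConfigError("[spectra] rrep_min must be below rrep_max")
    return RunConfig(**sections)


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a TOML config; ``None`` gives the full defaults."""
    if path is None:
        return validate_config({})
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file {p} does not exist")
    try:
        raw = tomllib.loads(p.read_text())
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{p}: {exc}") from exc
    return validate_config(raw)
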