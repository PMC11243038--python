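"""End-to-end orchestration: generate -> solvation -> FQ -> spectra -> RREP.

Every stage writes diff-friendly CSV (``#``-prefixed metadata header naming
units and the producing config hash) into the configured output directory,
and the run is summarized in a JSON manifest carrying the config hash,
package version, per-file checksums, the seeds actually used and wall-clock
timestamps.  Deterministic stages reproduce identical checksums under an
identical config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, load_config
from .fq import FQParameters, reaction_potential, solve_charges, solvatochromic_shift
from .solvation import (coordination_number, hbond_timeseries,
                        radial_distribution)
from .spectra import (average_sticks, convolve_sticks, enhancement_factors,
                      raman_spectrum, rr_stick_spectrum, rrep, uvvis_spectrum)
from .synthetic import (EnsembleSpec, FrameSpec, caffeine_like_chromophore,
                        default_solute, make_ensemble, make_trajectory)
from .units import nm_to_cm
from .xyzio import load_models, read_frames, save_models, write_frames

logger = logging.getLogger(__name__)

STAGES = ("generate", "solvation", "fq", "spectra", "rrep")


class MissingArtifactError(FileNotFoundError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seeds: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)
    completed: list = field(default_factory=list)
    failed: str | None = None

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with path.open("w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"stage {stage!r} needs missing input artifact {path}")
    return path


def run_pipeline(config: RunConfig | None = None,
                 only: str | None = None) -> RunManifest:
    """Execute the pipeline stages in order, honoring ``only`` stage skips."""
    cfg = config or load_config(None)
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    manifest = RunManifest(config_hash=chash, version=__version__,
                           seeds={"master": cfg.seed})
    stages = STAGES if only is None else (only,)
    if only is not None and only not in STAGES:
        raise ValueError(f"unknown stage {only!r}; choose from {STAGES}")
    meta = {"config_hash": chash, "package": f"rrsolv {__version__}"}
    try:
        for stage in stages:
            t0 = time.time()
            files = _STAGE_FNS[stage](cfg, out, meta)
            manifest.timestamps[stage] = {"start": t0, "end": time.time()}
            for f in files:
                manifest.checksums[f.name] = _sha256(f)
            manifest.completed.append(stage)
            logger.info("stage %s wrote %s", stage, [f.name for f in files])
    except Exception as exc:
        manifest.failed = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(manifest.to_json())
        raise
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

def _stage_generate(cfg: RunConfig, out: Path, meta: dict) -> list[Path]:
    s = cfg.synthetic
    solute = default_solute()
    frames = make_trajectory(
        FrameSpec(solute, s["n_waters"], s["radius"], s["hb_bias"], s["min_dist"]),
        n_frames=s["n_frames"], jitter=s["jitter"], seed=cfg.seed)
    fpath = out / "frames.xyz"
    write_frames(frames, fpath)
    base = caffeine_like_chromophore(seed=cfg.seed)
    ensemble = make_ensemble(base, EnsembleSpec(
        n_snapshots=s["n_snapshots"], sigma_energy_cm=s["sigma_energy"],
        sigma_freq_cm=s["sigma_freq"], gradient_jitter_frac=s["gradient_jitter"],
        seed=cfg.seed))
    epath = out / "ensemble.json"
    save_models(ensemble, epath)
    logger.info("generated %d frames (%d waters, %d planted H-bonds) and "
                "%d chromophore snapshots", len(frames), s["n_waters"],
                sum(s["hb_bias"].values()), len(ensemble))
    return [fpath, epath]


def _stage_solvation(cfg: RunConfig, out: Path, meta: dict) -> list[Path]:
    frames = read_frames(_require(out / "frames.xyz", "solvation"),
                         solute=default_solute())
    sv = cfg.solvation
    files = []
    for site in frames[0].solute.acceptors:
        rdf = radial_distribution(frames, site, "O", sv["r_max"], sv["dr"])
        prof = coordination_number(rdf, sv["r_cut"])
        df = pd.DataFrame({"r_ang": rdf.r, "g": rdf.g,
                           "n_running": np.interp(rdf.r, prof.r, prof.n)})
        p = out / f"rdf_{site}.csv"
        _write_csv(df, p, meta | {"units": "r in Å, g dimensionless",
                                  "rho_bulk_ang3": f"{rdf.rho_bulk:.6e}",
                                  "first_shell": f"{prof.first_shell:.4f}",
                                  "r_cut_ang": sv["r_cut"]})
        files.append(p)
    ts = hbond_timeseries(frames, d_cut=sv["d_cut"], theta_cut=sv["theta_cut"])
    df = pd.DataFrame({"frame": np.arange(len(ts.counts)), "count": ts.counts}
                      | {f"count_{k}": v for k, v in ts.per_site.items()})
    p = out / "hbonds.csv"
    _write_csv(df, p, meta | {"units": "counts per frame",
                              "mean": f"{ts.mean:.4f}", "std": f"{ts.std:.4f}"})
    logger.info("H-bond mean %.3f over %d frames", ts.mean, len(frames))
    return files + [p]


def _stage_fq(cfg: RunConfig, out: Path, meta: dict) -> list[Path]:
    frames = read_frames(_require(out / "frames.xyz", "fq"),
                         solute=default_solute())
    ensemble = load_models(_require(out / "ensemble.json", "fq"))
    params = FQParameters(
        chi={"O": cfg.fq["chi_O"], "H": cfg.fq["chi_H"]},
        eta={"O": cfg.fq["eta_O"], "H": cfg.fq["eta_H"]},
        kernel=cfg.fq["kernel"], water_charge=cfg.fq["water_charge"])
    rows, shift_rows = [], []
    for i, fr in enumerate(frames):
        sol = solve_charges(fr, params)
        for j, (t, q) in enumerate(zip(sol.site_types, sol.charges)):
            rows.append((fr.frame_index, j, t, q))
        pot = reaction_potential(sol, fr.solute.coords)
        model = ensemble[i % len(ensemble)]
        for st in model.states:
            shifted = solvatochromic_shift(
                st, fr.solute.charges, fr.solute.excited_charges, pot)
            shift_rows.append((fr.frame_index, st.index, st.energy_cm,
                               shifted.energy_cm,
                               shifted.energy_cm - st.energy_cm))
    p1 = out / "fq_charges.csv"
    _write_csv(pd.DataFrame(rows, columns=["frame", "site", "type", "q_e"]),
               p1, meta | {"units": "charges in e"})
    p2 = out / "fq_shifts.csv"
    _write_csv(pd.DataFrame(shift_rows, columns=[
        "frame", "state", "eps_cm", "eps_shifted_cm", "shift_cm"]),
        p2, meta | {"units": "energies in cm-1"})
    logger.info("FQ solved on %d frames (%d sites each)", len(frames),
                3 * frames[0].n_waters)
    return [p1, p2]


def _stage_spectra(cfg: RunConfig, out: Path, meta: dict) -> list[Path]:
    ensemble = load_models(_require(out / "ensemble.json", "spectra"))
    sp = cfg.spectra
    files = []

    uv = uvvis_spectrum(ensemble, fwhm_ev=sp["fwhm_uvvis_ev"])
    p = out / "uvvis.csv"
    _write_csv(pd.DataFrame({"wavenumber_cm": uv.axis, "intensity": uv.intensities}),
               p, meta | {"units": "cm-1, arb", "kind": "uvvis",
                          "fwhm_ev": sp["fwhm_uvvis_ev"],
                          "n_averaged": uv.n_averaged})
    files.append(p)

    w0_raman = nm_to_cm(sp["w0_raman_nm"])
    w0_rr = nm_to_cm(sp["w0_rr_nm"])
    raman_sticks = average_sticks([raman_spectrum(m, w0_raman) for m in ensemble])
    rr_sticks = average_sticks([
        rr_stick_spectrum(m, 1, w0_rr, sp["gamma"], sp["max_quanta"],
                          sp["weight_cutoff"]) for m in ensemble])
    for name, sticks in (("raman", raman_sticks), ("rr", rr_sticks)):
        conv = convolve_sticks(sticks, sp["shape"], sp["fwhm_raman"])
        p = out / f"{name}.csv"
        _write_csv(pd.DataFrame({"wavenumber_cm": conv.axis,
                                 "intensity": conv.intensities}),
                   p, meta | {"units": "cm-1, arb cross-section",
                              "kind": name, "w0_cm": f"{sticks.w0_cm:.2f}",
                              "fwhm_cm": sp["fwhm_raman"], "shape": sp["shape"],
                              "n_averaged": sticks.n_averaged})
        files.append(p)

    report = enhancement_factors(rr_sticks, raman_sticks)
    p = out / "enhancement.csv"
    _write_csv(report.to_frame(), p,
               meta | {"units": "cross-sections arb; factor dimensionless",
                       "w0_rr_cm": f"{w0_rr:.2f}", "w0_raman_cm": f"{w0_raman:.2f}"})
    files.append(p)
    logger.info("spectra stage: %d modes, %d snapshots averaged",
                len(report.labels), len(ensemble))
    return files


def _stage_rrep(cfg: RunConfig, out: Path, meta: dict) -> list[Path]:
    ensemble = load_models(_require(out / "ensemble.json", "rrep"))
    sp = cfg.spectra
    subset = ensemble[: sp["rrep_snapshots"]]
    grid = np.linspace(sp["rrep_min"], sp["rrep_max"], sp["rrep_points"])
    profile = rrep(subset, grid, sp["gamma"],
                   max_quanta=sp["max_quanta"],
                   weight_cutoff=sp["weight_cutoff"])
    p = out / "rrep.csv"
    _write_csv(profile.to_frame(), p,
               meta | {"units": "w0 in cm-1, cross-sections arb",
                       "gamma_cm": sp["gamma"],
                       "n_averaged": profile.n_averaged})
    logger.info("RREP on %d-point grid, %d snapshots", grid.size, len(subset))
    return [p]


_STAGE_FNS = {
    "generate": _stage_generate,
    "solvation": _stage_solvation,
    "fq": _stage_fq,
    "spectra": _stage_spectra,
    "rrep": _stage_rrep,
}
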