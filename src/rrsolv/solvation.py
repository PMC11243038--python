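"""Solvent structure around solute sites: RDFs, coordination numbers, H-bonds.

Works on finite solute-centered spheres of rigid waters (see
:mod:`rrsolv.synthetic`), not on periodic boxes.  Radial distribution
functions are therefore only defined out to half the sphere radius, where
spherical shells around a near-central site are still fully contained in
the solvated sphere, and the bulk density is estimated from the water count
inside that same half-radius ball.

Hydrogen bonds use the geometric criterion d(X···Ow) <= 3.5 Å and
theta(Hw-Ow-X) <= 30°, with X an acceptor site of the solute and the angle
measured at the water oxygen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .synthetic import SolvatedFrame

DEFAULT_DR_ANG = 0.05


@dataclass(frozen=True)
class RDFResult:
    """Radial distribution function between a solute site and a water site."""

    r: np.ndarray            # bin centers, Å
    g: np.ndarray            # dimensionless
    rho_bulk: float          # Å⁻³ number density used for normalization
    pair: tuple[str, str]    # (solute site label, solvent site label)
    dr: float                # bin width, Å
    n_frames: int = 1
    counts: np.ndarray | None = None  # raw pair counts per bin

    def __post_init__(self):
        r = np.asarray(self.r, float)
        g = np.asarray(self.g, float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "g", g)
        if np.any(np.diff(r) <= 0):
            raise ValueError("r grid must be strictly increasing")
        if np.any(g < 0):
            raise ValueError("g(r) must be non-negative")


@dataclass(frozen=True)
class CoordinationProfile:
    """Running coordination number n(r) from integrating an RDF."""

    r: np.ndarray
    n: np.ndarray
    r_cut: float
    first_shell: float

    def __post_init__(self):
        n = np.asarray(self.n, float)
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "r", np.asarray(self.r, float))
        if n[0] < -1e-12 or np.any(np.diff(n) < -1e-10):
            raise ValueError("running coordination number must be non-decreasing")


@dataclass(frozen=True)
class HBRecord:
    """One geometric hydrogen bond: acceptor X ... H-O water."""

    frame_index: int
    acceptor: str
    water_index: int
    h_index: int       # 0 or 1 within the water
    distance: float    # d(X···Ow), Å
    angle: float       # theta(Hw-Ow-X), degrees


@dataclass(frozen=True)
class HBTimeSeries:
    """Per-frame H-bond counts with mean/σ and per-acceptor breakdown."""

    counts: np.ndarray                       # (n_frames,) ints
    mean: float
    std: float
    per_site: Mapping[str, np.ndarray]       # label -> (n_frames,) ints

    def __post_init__(self):
        c = np.asarray(self.counts)
        object.__setattr__(self, "counts", c)
        if np.any(c < 0):
            raise ValueError("H-bond counts must be non-negative")
        if abs(float(c.mean()) - self.mean) > 1e-12:
            raise ValueError("stored mean inconsistent with counts")


def _solvent_sites(frame: SolvatedFrame, solvent_site: str) -> np.ndarray:
    if solvent_site == "O":
        return frame.oxygens
    if solvent_site == "H":
        return frame.hydrogens
    raise ValueError(f"solvent site must be 'O' or 'H', got {solvent_site!r}")


def radial_distribution(
    frames: Sequence[SolvatedFrame],
    solute_site: str,
    solvent_site: str = "O",
    r_max: float = 8.0,
    dr: float = DEFAULT_DR_ANG,
) -> RDFResult:
    """Site-site RDF averaged over frames, with finite-sphere normalization.

    The histogram of site-solvent distances is normalized by the ideal-gas
    shell count 4 pi r² dr rho_bulk per frame.  rho_bulk is the mean number
    of solvent sites found within radius/2 of the solute centroid divided by
    that ball's volume; g(r) is only valid (and only computed) for
    r_max <= radius/2.
    """
    if not frames:
        raise ValueError("empty frame list")
    if dr <= 0:
        raise ValueError("dr must be positive")
    radius = frames[0].radius
    if r_max > radius / 2 + 1e-9:
        raise ValueError(
            f"r_max={r_max} Å exceeds the finite-sphere validity margin "
            f"radius/2 = {radius / 2:.2f} Å"
        )
    edges = np.arange(0.0, r_max + dr / 2, dr)
    centers = 0.5 * (edges[1:] + edges[:-1])
    hist = np.zeros(centers.size)
    inner = 0.0
    half = radius / 2
    vol_half = 4.0 / 3.0 * np.pi * half**3
    for fr in frames:
        site = fr.solute.site(solute_site)
        pts = _solvent_sites(fr, solvent_site)
        if pts.size == 0:
            continue
        d = np.linalg.norm(pts - site, axis=1)
        hist += np.histogram(d, bins=edges)[0]
        inner += np.count_nonzero(
            np.linalg.norm(pts - fr.solute.centroid, axis=1) <= half)
    rho = inner / len(frames) / vol_half
    if rho == 0:
        raise ValueError("no solvent inside the normalization volume")
    shell = 4.0 * np.pi * centers**2 * dr * rho * len(frames)
    g = hist / shell
    return RDFResult(r=centers, g=g, rho_bulk=rho,
                     pair=(solute_site, solvent_site), dr=dr,
                     n_frames=len(frames), counts=hist)


def coordination_number(rdf: RDFResult, r_cut: float) -> CoordinationProfile:
    """n(r) = rho_bulk * integral_0^r 4 pi r'² g(r') dr' (trapezoidal)."""
    if not (rdf.r[0] - rdf.dr <= r_cut <= rdf.r[-1] + 1e-12):
        raise ValueError(f"r_cut={r_cut} outside the RDF grid "
                         f"[{rdf.r[0]:.3f}, {rdf.r[-1]:.3f}] Å")
    r = np.concatenate([[0.0], rdf.r])
    integrand = np.concatenate([[0.0], 4.0 * np.pi * rdf.r**2 * rdf.g])
    n = rdf.rho_bulk * cumulative_trapezoid(integrand, r, initial=0.0)
    first = float(np.interp(r_cut, r, n))
    return CoordinationProfile(r=r, n=n, r_cut=r_cut, first_shell=first)


def aggregate_first_shell(site_values: Mapping[str, float]) -> float:
    """Total first-shell solvent count from site-resolved coordination numbers.

    Site-resolved running coordination numbers (e.g. the joint carbonyl
    oxygens and the ring nitrogen) simply add: each counts distinct waters
    in its own shell.
    """
    return float(sum(site_values.values()))


def detect_hbonds(
    frame: SolvatedFrame,
    acceptors: Sequence[str] | None = None,
    d_cut: float = 3.5,
    theta_cut: float = 30.0,
) -> list[HBRecord]:
    """All (acceptor, water, H) triples satisfying the geometric criterion.

    A record is produced for every hydrogen that qualifies, so a water whose
    two hydrogens both point at the acceptor contributes two records; the
    de-duplicated water-contact count is handled by
    :func:`hbond_timeseries`.
    """
    if acceptors is None:
        acceptors = frame.solute.acceptors
    records: list[HBRecord] = []
    if frame.n_waters == 0:
        return records
    o = frame.oxygens
    for lbl in acceptors:
        x = frame.solute.site(lbl)  # KeyError on unknown label
        d = np.linalg.norm(o - x, axis=1)
        for w_idx in np.flatnonzero(d <= d_cut):
            v = (x - o[w_idx]) / d[w_idx]
            for h in (0, 1):
                u = frame.waters[w_idx, 1 + h] - o[w_idx]
                u = u / np.linalg.norm(u)
                theta = float(np.degrees(np.arccos(np.clip(u @ v, -1.0, 1.0))))
                if theta <= theta_cut:
                    records.append(HBRecord(
                        frame_index=frame.frame_index, acceptor=lbl,
                        water_index=int(w_idx), h_index=h,
                        distance=float(d[w_idx]), angle=theta))
    return records


def hbond_timeseries(
    frames: Sequence[SolvatedFrame],
    acceptors: Sequence[str] | None = None,
    d_cut: float = 3.5,
    theta_cut: float = 30.0,
    count_mode: str = "pair",
) -> HBTimeSeries:
    """Per-frame H-bond counts over a trajectory.

    ``count_mode='pair'`` (default) counts distinct (acceptor, water) pairs
    once even if both hydrogens qualify, matching a water-contact reading of
    the H-bond count; ``'record'`` counts every qualifying hydrogen.
    """
    if not frames:
        raise ValueError("need at least one frame")
    if count_mode not in ("pair", "record"):
        raise ValueError("count_mode must be 'pair' or 'record'")
    if acceptors is None:
        acceptors = frames[0].solute.acceptors
    counts = np.zeros(len(frames), dtype=int)
    per_site = {lbl: np.zeros(len(frames), dtype=int) for lbl in acceptors}
    for i, fr in enumerate(frames):
        recs = detect_hbonds(fr, acceptors, d_cut, theta_cut)
        if count_mode == "pair":
            seen = {(r.acceptor, r.water_index) for r in recs}
            for lbl, _ in seen:
                per_site[lbl][i] += 1
            counts[i] = len(seen)
        else:
            for r in recs:
                per_site[r.acceptor][i] += 1
            counts[i] = len(recs)
    return HBTimeSeries(counts=counts, mean=float(counts.mean()),
                        std=float(counts.std()), per_site=per_site)
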