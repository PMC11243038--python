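"""Synthetic solvated frames and chromophore ensembles with planted structure.

Every downstream stage of the pipeline (solvation analysis, fluctuating-charge
embedding, spectra) is exercised on data produced here, so each generator
plants a known statistical structure that the corresponding analysis must
recover exactly:

* :func:`make_solvated_frame` places a requested number of waters in
  hydrogen-bonding geometry at chosen acceptor sites of a rigid solute, and
  fills the rest of a solute-centered sphere with uniformly random waters
  kept outside the H-bond acceptance region, so the planted H-bond count is
  the exact ground truth.
* :func:`make_chromophore` builds a harmonic chromophore whose excited-state
  Cartesian gradients are constructed from caller-specified dimensionless
  mode displacements, so projecting the gradient back onto the normal modes
  recovers the planted displacements to round-off.

Frames emulate solute-centered solvated spheres (default radius 17 Å) of
rigid 3-site waters; chromophore ensembles emulate snapshot-to-snapshot
configurational variability with independent Gaussian jitter.  No molecular
dynamics is performed: frames are stochastic constructions, not trajectories
of any force field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .units import AMU_TO_AU, CM_TO_HARTREE

# Rigid 3-site water geometry (TIP3P-style), configurable per frame.
WATER_OH_ANG = 0.9572
WATER_HOH_DEG = 104.52

DEFAULT_RADIUS_ANG = 17.0
DEFAULT_EXCLUSION_ANG = 2.4
# Geometric H-bond criterion used throughout the package.
HB_DCUT_ANG = 3.5
HB_THETACUT_DEG = 30.0
# Planted H-bond placement stays safely inside the acceptance region.
PLANT_D_RANGE = (2.6, 3.4)
PLANT_THETA_RANGE = (0.0, 25.0)
# Random (non-planted) waters are kept strictly outside the acceptance
# sphere of every acceptor so they can never register as H-bonds.
HB_GUARD_ANG = 3.55
SOLUTE_CLASH_ANG = 2.0

DEFAULT_ENSEMBLE_SIZE = 200  # production ensemble size


class PackingError(RuntimeError):
    """Raised when waters cannot be placed under the geometric constraints."""


# --------------------------------------------------------------------------
# solute / frame containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SoluteTemplate:
    """A rigid multi-site solute with point charges and H-bond acceptor sites."""

    labels: tuple[str, ...]
    coords: np.ndarray          # (n, 3) Å
    charges: np.ndarray         # (n,) e
    acceptors: tuple[str, ...]  # subset of labels
    total_charge: float = 0.0
    excited_charges: np.ndarray | None = None  # (n,) e, optional ES charge set

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        charges = np.asarray(self.charges, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "charges", charges)
        if coords.shape != (len(self.labels), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("solute coordinates must be finite")
        if charges.shape != (len(self.labels),):
            raise ValueError("one charge per atom required")
        missing = set(self.acceptors) - set(self.labels)
        if missing:
            raise ValueError(f"acceptor sites not in solute: {sorted(missing)}")
        if abs(float(charges.sum()) - self.total_charge) > 1e-8:
            raise ValueError(
                f"net charge {charges.sum():.6f} != declared {self.total_charge}"
            )
        if self.excited_charges is not None:
            exq = np.asarray(self.excited_charges, dtype=float)
            object.__setattr__(self, "excited_charges", exq)
            if exq.shape != charges.shape:
                raise ValueError("excited charge set must match atom count")

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown solute site {label!r}") from None

    def site(self, label: str) -> np.ndarray:
        return self.coords[self.index(label)]

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)


def default_solute() -> SoluteTemplate:
    """A small planar purine-like solute with three H-bond acceptor sites.

    The acceptor roles mirror a caffeine-like chromophore: two carbonyl
    oxygens (O10, O12) and one imidazole-type nitrogen (N9), mutually
    separated by ~5 Å so planted H-bonds at different sites cannot overlap.
    Ground-state point charges are a crude polar pattern summing to zero;
    the excited-state set moves 0.05 e from each acceptor into the ring,
    giving a nonzero charge rearrangement for solvatochromic shifts.
    """
    labels = ("C1", "C3", "C4", "C5", "N9", "O10", "O12")
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [-1.3, 0.8, 0.0],
            [1.3, 0.8, 0.0],
            [0.0, -1.5, 0.0],
            [0.0, -2.8, 0.0],
            [-2.5, 1.5, 0.0],
            [2.5, 1.5, 0.0],
        ]
    )
    charges = np.array([0.15, 0.45, 0.45, 0.35, -0.40, -0.50, -0.50])
    excited = charges + np.array([0.05, 0.05, 0.05, 0.0, 0.05, 0.05, 0.05]) * np.array(
        [1, 1, 1, 0, -1, -1, -1]
    )
    return SoluteTemplate(
        labels=labels,
        coords=coords,
        charges=charges,
        acceptors=("N9", "O10", "O12"),
        total_charge=0.0,
        excited_charges=excited,
    )


@dataclass(frozen=True)
class SolvatedFrame:
    """A rigid solute plus rigid 3-site waters inside a solute-centered sphere."""

    solute: SoluteTemplate
    waters: np.ndarray  # (n_w, 3, 3): [O, H1, H2] positions in Å
    radius: float       # Å
    frame_index: int = 0
    time: float = 0.0   # arbitrary units
    exclusion: float = DEFAULT_EXCLUSION_ANG
    oh_length: float = WATER_OH_ANG
    hoh_angle: float = WATER_HOH_DEG
    planted: tuple[str, ...] = ()  # acceptor labels of the leading waters

    def __post_init__(self):
        waters = np.asarray(self.waters, dtype=float).reshape(-1, 3, 3)
        object.__setattr__(self, "waters", waters)
        self.validate()

    @property
    def n_waters(self) -> int:
        return self.waters.shape[0]

    @property
    def oxygens(self) -> np.ndarray:
        return self.waters[:, 0, :]

    @property
    def hydrogens(self) -> np.ndarray:
        return self.waters[:, 1:, :].reshape(-1, 3)

    def validate(self, dist_tol: float = 1e-8, angle_tol: float = 1e-6) -> None:
        """Check the frame invariants: containment, rigidity, exclusion."""
        if self.n_waters == 0:
            return
        o = self.oxygens
        center = self.solute.centroid
        rmax = np.linalg.norm(o - center, axis=1).max()
        if rmax > self.radius + 1e-9:
            raise ValueError(f"water oxygen outside sphere: {rmax:.3f} > {self.radius}")
        d1 = np.linalg.norm(self.waters[:, 1] - o, axis=1)
        d2 = np.linalg.norm(self.waters[:, 2] - o, axis=1)
        if np.abs(d1 - self.oh_length).max() > dist_tol or \
           np.abs(d2 - self.oh_length).max() > dist_tol:
            raise ValueError("water O-H distances violate the rigid geometry")
        u1 = (self.waters[:, 1] - o) / d1[:, None]
        u2 = (self.waters[:, 2] - o) / d2[:, None]
        ang = np.degrees(np.arccos(np.clip(np.sum(u1 * u2, axis=1), -1.0, 1.0)))
        if np.abs(ang - self.hoh_angle).max() > angle_tol:
            raise ValueError("water H-O-H angle violates the rigid geometry")
        if self.n_waters > 1 and self.exclusion > 0:
            dd = np.linalg.norm(o[:, None, :] - o[None, :, :], axis=-1)
            np.fill_diagonal(dd, np.inf)
            if dd.min() < self.exclusion - 1e-9:
                raise ValueError(
                    f"O-O distance {dd.min():.3f} Å below exclusion {self.exclusion} Å"
                )


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([1.0, 0.0, 0.0])
    if abs(u @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    p = np.cross(u, a)
    p /= np.linalg.norm(p)
    return p, np.cross(u, p)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about the unit vector axis."""
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * (axis @ v) * (1 - c)


def _build_water(o: np.ndarray, u1: np.ndarray, azimuth: float,
                 oh: float = WATER_OH_ANG, hoh: float = WATER_HOH_DEG) -> np.ndarray:
    """Water [O,H1,H2] with O->H1 along unit u1, H2 at the rigid angle."""
    p, q = _perp_basis(u1)
    theta = np.radians(hoh)
    u2 = np.cos(theta) * u1 + np.sin(theta) * (np.cos(azimuth) * p + np.sin(azimuth) * q)
    return np.stack([o, o + oh * u1, o + oh * u2])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _cone_direction(rng: np.random.Generator, axis: np.ndarray,
                    half_angle_deg: float) -> np.ndarray:
    """Uniform direction within a cone of given half-angle about axis."""
    cmin = np.cos(np.radians(half_angle_deg))
    c = rng.uniform(cmin, 1.0)
    s = np.sqrt(1.0 - c * c)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    p, q = _perp_basis(axis)
    return c * axis + s * (np.cos(phi) * p + np.sin(phi) * q)


def _hb_water(acceptor: np.ndarray, out_dir: np.ndarray, d: float,
              theta_deg: float, axis_phi: float, azimuth: float,
              oh: float, hoh: float) -> np.ndarray:
    """Water H-bonded to an acceptor: O at distance d, one H at angle theta.

    The angle is the H-bond criterion angle theta(Hw-Ow-X), measured at the
    water oxygen between Ow->Hw and Ow->X.
    """
    o = acceptor + d * out_dir
    v = -out_dir  # Ow -> acceptor
    p, q = _perp_basis(v)
    axis = np.cos(axis_phi) * p + np.sin(axis_phi) * q
    u1 = _rotate_about(v, axis, np.radians(theta_deg))
    return _build_water(o, u1, azimuth, oh, hoh)


# --------------------------------------------------------------------------
# frame generators
# --------------------------------------------------------------------------

def _clashes(o: np.ndarray, frame_os: list[np.ndarray], solute: SoluteTemplate,
             exclusion: float, center: np.ndarray, radius: float,
             guard_acceptors: Sequence[np.ndarray]) -> bool:
    if np.linalg.norm(o - center) > radius:
        return True
    for a in guard_acceptors:
        if np.linalg.norm(o - a) <= HB_GUARD_ANG:
            return True
    if len(frame_os) and np.linalg.norm(np.asarray(frame_os) - o, axis=1).min() < exclusion:
        return True
    if np.linalg.norm(solute.coords - o, axis=1).min() < SOLUTE_CLASH_ANG:
        return True
    return False


def make_solvated_frame(
    solute: SoluteTemplate,
    n_waters: int,
    radius: float = DEFAULT_RADIUS_ANG,
    hb_bias: Mapping[str, int] | None = None,
    min_dist: float = DEFAULT_EXCLUSION_ANG,
    seed: int = 0,
    *,
    frame_index: int = 0,
    time: float = 0.0,
    oh: float = WATER_OH_ANG,
    hoh: float = WATER_HOH_DEG,
    max_attempts: int = 20000,
) -> SolvatedFrame:
    """Build a solvated sphere with an exact planted H-bond count.

    ``hb_bias`` maps acceptor labels to the number of waters planted in
    H-bonding geometry at that site (distance in [2.6, 3.4] Å, angle in
    [0, 25]°, safely inside the d<=3.5 Å / theta<=30° criterion).  All
    remaining waters are uniformly random in the sphere but excluded from
    every acceptor's H-bond acceptance sphere, so the geometric H-bond
    detector recovers exactly the planted counts.
    """
    hb_bias = dict(hb_bias or {})
    for lbl in hb_bias:
        solute.index(lbl)  # raises KeyError on unknown site
    n_planted = sum(hb_bias.values())
    if n_waters < n_planted:
        raise ValueError(
            f"n_waters={n_waters} below planted H-bond count {n_planted}"
        )
    # crude capacity check: random-close-packing-ish bound on hard spheres
    if n_waters > 0 and min_dist > 0:
        capacity = 0.64 * (2.0 * radius / min_dist) ** 3 / 8.0
        if n_waters > capacity:
            raise PackingError(
                f"cannot hold {n_waters} waters at min_dist={min_dist} Å "
                f"in a {radius} Å sphere (capacity ~{int(capacity)})"
            )

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    center = solute.centroid
    acceptor_pos = {lbl: solute.site(lbl) for lbl in solute.acceptors}

    waters: list[np.ndarray] = []
    os_placed: list[np.ndarray] = []
    planted_labels: list[str] = []

    for lbl, count in hb_bias.items():
        x = solute.site(lbl)
        others = [p for l2, p in acceptor_pos.items() if l2 != lbl]
        base_dir = x - center
        nrm = np.linalg.norm(base_dir)
        base_dir = base_dir / nrm if nrm > 1e-6 else np.array([0.0, 0.0, 1.0])
        for _ in range(count):
            for attempt in range(max_attempts):
                d = rng.uniform(*PLANT_D_RANGE)
                theta = rng.uniform(*PLANT_THETA_RANGE)
                direction = _cone_direction(rng, base_dir, 60.0)
                w = _hb_water(x, direction, d, theta,
                              rng.uniform(0, 2 * np.pi), rng.uniform(0, 2 * np.pi),
                              oh, hoh)
                o = w[0]
                if np.linalg.norm(o - center) > radius:
                    continue
                if any(np.linalg.norm(o - a) <= HB_GUARD_ANG for a in others):
                    continue
                if os_placed and np.linalg.norm(
                        np.asarray(os_placed) - o, axis=1).min() < min_dist:
                    continue
                solute_d = np.linalg.norm(solute.coords - o, axis=1)
                solute_d[solute.index(lbl)] = np.inf
                if solute_d.min() < SOLUTE_CLASH_ANG:
                    continue
                waters.append(w)
                os_placed.append(o)
                planted_labels.append(lbl)
                break
            else:
                raise PackingError(
                    f"failed to plant H-bond water at {lbl} after "
                    f"{max_attempts} attempts (exclusion {min_dist} Å)"
                )

    guard = list(acceptor_pos.values())
    for _ in range(n_waters - n_planted):
        for attempt in range(max_attempts):
            o = center + radius * _random_unit(rng) * rng.uniform(0, 1) ** (1 / 3)
            if _clashes(o, os_placed, solute, min_dist, center, radius, guard):
                continue
            w = _build_water(o, _random_unit(rng), rng.uniform(0, 2 * np.pi), oh, hoh)
            waters.append(w)
            os_placed.append(o)
            break
        else:
            raise PackingError(
                f"failed to place bulk water {len(waters) + 1}/{n_waters} after "
                f"{max_attempts} attempts (min_dist={min_dist} Å, radius={radius} Å)"
            )

    arr = np.stack(waters) if waters else np.zeros((0, 3, 3))
    return SolvatedFrame(
        solute=solute, waters=arr, radius=radius, frame_index=frame_index,
        time=time, exclusion=min_dist, oh_length=oh, hoh_angle=hoh,
        planted=tuple(planted_labels),
    )


def make_ideal_gas_frame(
    n_waters: int,
    radius: float = DEFAULT_RADIUS_ANG,
    seed: int = 0,
    solute: SoluteTemplate | None = None,
    *,
    frame_index: int = 0,
) -> SolvatedFrame:
    """Waters uniformly random in the sphere with no exclusion or bias.

    The ideal-gas reference construction: oxygen positions are uniform in
    the solute-centered sphere and orientations are isotropic, so every
    site-site radial distribution function is 1 (within counting noise)
    at all distances.  Used as the analytic oracle for RDF normalization.
    """
    if solute is None:
        solute = SoluteTemplate(labels=("X",), coords=np.zeros((1, 3)),
                                charges=np.zeros(1), acceptors=())
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    center = solute.centroid
    v = rng.normal(size=(n_waters, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    o = center + radius * rng.uniform(0, 1, (n_waters, 1)) ** (1 / 3) * v
    u1 = rng.normal(size=(n_waters, 3))
    u1 /= np.linalg.norm(u1, axis=1, keepdims=True)
    ref = np.where(np.abs(u1 @ np.array([1.0, 0, 0]))[:, None] > 0.9,
                   np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0]))
    p = np.cross(u1, ref)
    p /= np.linalg.norm(p, axis=1, keepdims=True)
    q = np.cross(u1, p)
    az = rng.uniform(0, 2 * np.pi, (n_waters, 1))
    theta = np.radians(WATER_HOH_DEG)
    u2 = np.cos(theta) * u1 + np.sin(theta) * (np.cos(az) * p + np.sin(az) * q)
    waters = np.stack([o, o + WATER_OH_ANG * u1, o + WATER_OH_ANG * u2], axis=1)
    return SolvatedFrame(solute=solute, waters=waters, radius=radius,
                         frame_index=frame_index, exclusion=0.0)


@dataclass(frozen=True)
class FrameSpec:
    """Arguments bundle for :func:`make_solvated_frame` used by trajectories."""

    solute: SoluteTemplate
    n_waters: int
    radius: float = DEFAULT_RADIUS_ANG
    hb_bias: Mapping[str, int] | None = None
    min_dist: float = DEFAULT_EXCLUSION_ANG


def make_trajectory(
    frame_spec: FrameSpec,
    n_frames: int,
    jitter: float = 0.0,
    seed: int = 0,
    *,
    dt: float = 1.0,
) -> list[SolvatedFrame]:
    """A sequence of frames: rigid-body perturbations of a common base frame.

    Each water of the base frame is rigidly translated by a Gaussian step of
    scale ``jitter`` (Å) and rotated about its oxygen by a Gaussian angle of
    scale ``jitter`` rad; moves that would break the sphere/exclusion
    constraints, or take a planted water outside the H-bond acceptance
    region, or let a bulk water enter it, are rejected and redrawn (the
    unperturbed position is kept after bounded retries).  ``jitter=0``
    reproduces the base frame exactly in every frame.  Frame ``i`` draws
    from the substream ``SeedSequence(seed, spawn_key=(i,))`` so it is
    reproducible in isolation.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    base = make_solvated_frame(
        frame_spec.solute, frame_spec.n_waters, frame_spec.radius,
        frame_spec.hb_bias, frame_spec.min_dist,
        seed=int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31)),
    )
    frames = []
    for i in range(n_frames):
        if jitter == 0:
            frames.append(dataclasses.replace(base, frame_index=i, time=i * dt))
            continue
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        frames.append(_perturb_frame(base, jitter, rng, i, i * dt))
    return frames


def _perturb_frame(base: SolvatedFrame, jitter: float, rng: np.random.Generator,
                   frame_index: int, time: float, retries: int = 50) -> SolvatedFrame:
    solute = base.solute
    center = solute.centroid
    acceptor_pos = {lbl: solute.site(lbl) for lbl in solute.acceptors}
    n_planted = len(base.planted)
    new_waters = base.waters.copy()

    for w_idx in range(base.n_waters):
        planted_lbl = base.planted[w_idx] if w_idx < n_planted else None
        accepted = None
        for _ in range(retries):
            shift = rng.normal(scale=jitter, size=3)
            axis = _random_unit(rng)
            angle = rng.normal(scale=jitter)
            w = base.waters[w_idx]
            o = w[0] + shift
            cand = np.empty_like(w)
            cand[0] = o
            for h in (1, 2):
                cand[h] = o + _rotate_about(w[h] - w[0], axis, angle)
            if not _perturb_ok(cand, w_idx, new_waters, base, center,
                               acceptor_pos, planted_lbl):
                continue
            accepted = cand
            break
        if accepted is not None:
            new_waters[w_idx] = accepted
        # else: keep the base placement, which satisfies all constraints

    return dataclasses.replace(base, waters=new_waters,
                               frame_index=frame_index, time=time)


def _perturb_ok(cand: np.ndarray, w_idx: int, waters: np.ndarray,
                base: SolvatedFrame, center: np.ndarray,
                acceptor_pos: Mapping[str, np.ndarray],
                planted_lbl: str | None) -> bool:
    o = cand[0]
    if np.linalg.norm(o - center) > base.radius:
        return False
    others = np.delete(waters[:, 0, :], w_idx, axis=0)
    if others.size and np.linalg.norm(others - o, axis=1).min() < base.exclusion:
        return False
    solute_d = np.linalg.norm(base.solute.coords - o, axis=1)
    if planted_lbl is not None:
        x = acceptor_pos[planted_lbl]
        d = np.linalg.norm(o - x)
        if not (PLANT_D_RANGE[0] <= d <= PLANT_D_RANGE[1]):
            return False
        v = (x - o) / d
        best = np.inf
        for h in (1, 2):
            u = cand[h] - o
            u /= np.linalg.norm(u)
            best = min(best, np.degrees(np.arccos(np.clip(u @ v, -1, 1))))
        if best > PLANT_THETA_RANGE[1]:
            return False
        for lbl, a in acceptor_pos.items():
            if lbl != planted_lbl and np.linalg.norm(o - a) <= HB_GUARD_ANG:
                return False
        solute_d[base.solute.index(planted_lbl)] = np.inf
        if solute_d.min() < SOLUTE_CLASH_ANG:
            return False
    else:
        for a in acceptor_pos.values():
            if np.linalg.norm(o - a) <= HB_GUARD_ANG:
                return False
        if solute_d.min() < SOLUTE_CLASH_ANG:
            return False
    return True


# --------------------------------------------------------------------------
# chromophore models
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExcitedState:
    """One electronic excited state of the chromophore.

    energy_cm        vertical excitation energy epsilon (cm⁻¹)
    osc_strength     dimensionless oscillator strength f
    trans_dipole_au  transition dipole magnitude mu (a.u.)
    gradient_au      Cartesian excited-state energy gradient at the
                     ground-state geometry (hartree/bohr, length 3N)
    index            1-based state index (S1, S2, ...)
    """

    energy_cm: float
    osc_strength: float
    trans_dipole_au: float
    gradient_au: np.ndarray
    index: int = 1

    def __post_init__(self):
        g = np.asarray(self.gradient_au, dtype=float)
        object.__setattr__(self, "gradient_au", g)
        if self.energy_cm <= 0:
            raise ValueError("excitation energy must be positive")
        if self.osc_strength < 0:
            raise ValueError("oscillator strength must be >= 0")
        if g.ndim != 1:
            raise ValueError("gradient must be a flat 3N vector")


@dataclass(frozen=True)
class ChromophoreModel:
    """Per-snapshot harmonic chromophore: modes, frequencies, excited states.

    ``modes`` holds mass-weighted Cartesian displacement vectors as columns
    of a (3N, n_modes) matrix, orthonormal to 1e-8.  Frequencies are in
    cm⁻¹.  ``alpha_deriv`` / ``gamma_deriv`` are the isotropic and
    anisotropic polarizability-derivative invariants a'_k, gamma'_k (a.u.)
    entering the spontaneous-Raman activity 45 a'² + 7 gamma'².
    """

    masses_amu: np.ndarray           # (N,)
    modes: np.ndarray                # (3N, n_modes)
    freqs_cm: np.ndarray             # (n_modes,)
    alpha_deriv: np.ndarray          # (n_modes,)
    gamma_deriv: np.ndarray          # (n_modes,)
    states: tuple[ExcitedState, ...]
    snapshot_index: int = 0
    mode_labels: tuple[str, ...] = ()

    def __post_init__(self):
        m = np.asarray(self.masses_amu, float)
        L = np.asarray(self.modes, float)
        w = np.asarray(self.freqs_cm, float)
        a = np.asarray(self.alpha_deriv, float)
        g = np.asarray(self.gamma_deriv, float)
        for name, val in (("masses_amu", m), ("modes", L), ("freqs_cm", w),
                          ("alpha_deriv", a), ("gamma_deriv", g)):
            object.__setattr__(self, name, val)
        n = m.size
        if L.shape[0] != 3 * n:
            raise ValueError("modes must have 3N rows")
        if L.shape[1] > max(3 * n - 6, 0):
            raise ValueError(f"at most 3N-6={3*n-6} modes allowed, got {L.shape[1]}")
        if w.shape != (L.shape[1],):
            raise ValueError("one frequency per mode required")
        if np.any(w <= 0):
            raise ValueError("vibrational frequencies must be positive")
        dev = np.abs(L.T @ L - np.eye(L.shape[1])).max()
        if dev > 1e-8:
            raise ValueError(f"mode vectors not orthonormal (max dev {dev:.2e})")
        if not self.mode_labels:
            object.__setattr__(
                self, "mode_labels",
                tuple(f"mode{k+1}" for k in range(L.shape[1])))
        for s in self.states:
            if s.gradient_au.size != 3 * n:
                raise ValueError("state gradient length must be 3N")

    @property
    def n_atoms(self) -> int:
        return self.masses_amu.size

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    def state(self, index: int) -> ExcitedState:
        for s in self.states:
            if s.index == index:
                return s
        raise KeyError(f"no excited state with index {index}")


def _mu_from_f(eps_cm: float, f: float) -> float:
    """Transition dipole (a.u.) from oscillator strength: f = (2/3) eps mu^2."""
    eps_au = eps_cm * CM_TO_HARTREE
    return float(np.sqrt(max(3.0 * f / (2.0 * eps_au), 0.0)))


def gradient_from_displacements(
    masses_amu: np.ndarray, modes: np.ndarray, freqs_cm: np.ndarray,
    deltas: np.ndarray,
) -> np.ndarray:
    """Cartesian gradient (hartree/bohr) whose mode projections plant ``deltas``.

    Inverts the projection used by the spectra engine: the mass-weighted
    projection is g_k = L_k^T M^{-1/2} grad, and the dimensionless
    displacement Delta_k = -g_k / omega_k^{3/2} (atomic units, hbar = 1).
    """
    w_au = np.asarray(freqs_cm, float) * CM_TO_HARTREE
    g_k = -np.asarray(deltas, float) * w_au ** 1.5
    m_au = np.repeat(np.asarray(masses_amu, float) * AMU_TO_AU, 3)
    return np.sqrt(m_au) * (modes @ g_k)


def make_chromophore(
    n_atoms: int,
    n_modes: int,
    freq_range: tuple[float, float] = (1000.0, 1700.0),
    displacement_scale: float = 0.3,
    n_states: int = 1,
    seed: int = 0,
    *,
    freqs_cm: Sequence[float] | None = None,
    displacements: np.ndarray | None = None,
    state_energies_cm: Sequence[float] | None = None,
    osc_strengths: Sequence[float] | None = None,
    mode_labels: Sequence[str] | None = None,
) -> ChromophoreModel:
    """Random harmonic chromophore with planted mode displacements.

    ``displacements`` (n_states, n_modes) fixes the dimensionless
    displacements Delta each excited-state gradient projects onto; when
    omitted they are drawn from N(0, displacement_scale²).  The round trip
    through the spectra engine's gradient projection recovers them to
    round-off, which is the central testability hook of the generator.
    """
    if n_modes > 3 * n_atoms - 6:
        raise ValueError(f"n_modes={n_modes} exceeds 3N-6={3*n_atoms-6}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    masses = rng.uniform(12.0, 16.0, size=n_atoms)
    q, _ = np.linalg.qr(rng.normal(size=(3 * n_atoms, n_modes)))
    modes = q * np.sign(q[0, :])  # fix gauge so output is seed-stable
    if freqs_cm is None:
        w = np.sort(rng.uniform(*freq_range, size=n_modes))
    else:
        w = np.asarray(freqs_cm, float)
        if w.shape != (n_modes,):
            raise ValueError("freqs_cm must have n_modes entries")
    alpha = rng.uniform(0.2, 1.0, size=n_modes)
    gamma = rng.uniform(0.2, 1.0, size=n_modes)

    if displacements is None:
        deltas = rng.normal(scale=displacement_scale, size=(n_states, n_modes))
    else:
        deltas = np.atleast_2d(np.asarray(displacements, float))
        if deltas.shape == (1, n_modes) and n_states > 1:
            deltas = np.repeat(deltas, n_states, axis=0)
        if deltas.shape != (n_states, n_modes):
            raise ValueError("displacements must be (n_states, n_modes)")
    if state_energies_cm is None:
        eps = np.sort(rng.uniform(35000.0, 60000.0, size=n_states))
    else:
        eps = np.asarray(state_energies_cm, float)
    if osc_strengths is None:
        fosc = rng.uniform(0.05, 0.5, size=n_states)
    else:
        fosc = np.asarray(osc_strengths, float)

    states = []
    for s in range(n_states):
        grad = gradient_from_displacements(masses, modes, w, deltas[s])
        states.append(ExcitedState(
            energy_cm=float(eps[s]), osc_strength=float(fosc[s]),
            trans_dipole_au=_mu_from_f(float(eps[s]), float(fosc[s])),
            gradient_au=grad, index=s + 1,
        ))
    return ChromophoreModel(
        masses_amu=masses, modes=modes, freqs_cm=w, alpha_deriv=alpha,
        gamma_deriv=gamma, states=tuple(states),
        mode_labels=tuple(mode_labels) if mode_labels else (),
    )


# Mode positions (ensemble-averaged, cm⁻¹) and labels of the nine vibrations
# tracked by the enhancement analysis of a caffeine-like chromophore.
CAFFEINE_LIKE_MODES = (
    ("rho_CH3_M1", 1049.0),
    ("rho_CH3_M3", 1097.0),
    ("nu_rings", 1313.0),
    ("nu_i-ring_2", 1362.0),
    ("nu_i-ring_1", 1394.0),
    ("delta_C8-H", 1469.0),
    ("delta_CM", 1536.0),
    ("nu_C-C", 1583.0),
    ("nu_C=C+C=N", 1624.0),
)


def caffeine_like_chromophore(seed: int = 0) -> ChromophoreModel:
    """Toy chromophore emulating solvated caffeine's spectroscopic skeleton.

    Nine in-plane ring/methyl modes at the caffeine-like frequencies, an S1
    state placed so the lowest absorption band peaks at 267 nm, and a
    cluster of higher states producing a stronger band near 206 nm.  The
    mode displacements are synthetic (drawn once from a fixed-scale normal);
    only band positions and mode frequencies are calibrated to the real
    system, not intensities.
    """
    labels, freqs = zip(*CAFFEINE_LIKE_MODES)
    return make_chromophore(
        n_atoms=12, n_modes=9, n_states=4, seed=seed,
        freqs_cm=freqs, displacement_scale=0.35,
        state_energies_cm=(37453.2, 46500.0, 48543.7, 50500.0),
        osc_strengths=(0.28, 0.10, 0.65, 0.20),
        mode_labels=labels,
    )


@dataclass(frozen=True)
class EnsembleSpec:
    """Noise model for a snapshot ensemble of chromophore models."""

    n_snapshots: int = DEFAULT_ENSEMBLE_SIZE
    sigma_energy_cm: float = 500.0
    sigma_freq_cm: float = 5.0
    gradient_jitter_frac: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_snapshots < 1:
            raise ValueError("need at least one snapshot")
        for v in (self.sigma_energy_cm, self.sigma_freq_cm,
                  self.gradient_jitter_frac):
            if v < 0:
                raise ValueError("noise standard deviations must be >= 0")


def make_ensemble(base: ChromophoreModel, spec: EnsembleSpec) -> list[ChromophoreModel]:
    """Independent Gaussian jitter of energies, frequencies and gradients.

    Snapshot ``i`` draws from ``SeedSequence(spec.seed, spawn_key=(i,))``.
    Frequencies are clipped to stay positive (floor 1 cm⁻¹); transition
    dipoles are recomputed from the jittered energy at fixed oscillator
    strength.
    """
    out = []
    for i in range(spec.n_snapshots):
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(i,)))
        w = base.freqs_cm + rng.normal(scale=spec.sigma_freq_cm,
                                       size=base.n_modes) if spec.sigma_freq_cm else base.freqs_cm.copy()
        w = np.maximum(w, 1.0)
        states = []
        for s in base.states:
            eps = s.energy_cm + (rng.normal(scale=spec.sigma_energy_cm)
                                 if spec.sigma_energy_cm else 0.0)
            eps = max(eps, 1.0)
            grad = s.gradient_au * (
                1.0 + rng.normal(scale=spec.gradient_jitter_frac,
                                 size=s.gradient_au.size)
                if spec.gradient_jitter_frac else 1.0)
            states.append(ExcitedState(
                energy_cm=float(eps), osc_strength=s.osc_strength,
                trans_dipole_au=_mu_from_f(float(eps), s.osc_strength),
                gradient_au=np.asarray(grad, float), index=s.index,
            ))
        out.append(dataclasses.replace(
            base, freqs_cm=w, states=tuple(states), snapshot_index=i))
    return out
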