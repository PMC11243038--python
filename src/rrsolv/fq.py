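"""Fluctuating-charge (FQ) polarizable embedding for rigid waters.

Electronegativity-equalization model: every water site carries a charge
q_i that minimizes

    E(q) = sum_i chi_i q_i + 1/2 sum_ij J_ij q_i q_j + sum_i q_i V_ext(r_i)

subject to one total-charge constraint per water molecule.  The stationary
point is obtained from the bordered symmetric linear system (interaction
matrix plus one Lagrange row per molecule).  The diagonal of J is twice the
site hardness (J_ii = 2 eta_i), so the self-energy term is eta_i q_i².

Off-diagonal interactions use either the bare Coulomb kernel 1/r or an
Ohno-damped kernel 1/sqrt(r² + c_ij²) with c_ij = 2/(eta_i + eta_j), which
removes the polarization catastrophe at hydrogen-bonding distances and
reduces to the hardness scale at r -> 0.

Only the solvent is polarizable; the solute enters through fixed point
charges that generate the external potential V_ext.  All quantities are in
atomic units internally (Å at the interface).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .units import ANG_TO_BOHR, HARTREE_TO_CM, KCALMOL_TO_HARTREE
from .synthetic import SolvatedFrame, ExcitedState
import dataclasses

# Rick-style water parametrization (user-verifiable against the cited
# source); values in hartree/e and hartree/e², converted from kcal/mol.
# These are configuration defaults, never asserted as ground truth.
DEFAULT_CHI = {"O": 68.49 * KCALMOL_TO_HARTREE, "H": 0.0}
DEFAULT_ETA = {"O": 371.6 * KCALMOL_TO_HARTREE, "H": 353.0 * KCALMOL_TO_HARTREE}


class FQSolveError(RuntimeError):
    """Raised when the bordered FQ system is singular or ill-conditioned."""


@dataclass(frozen=True)
class FQParameters:
    """Electronegativities, hardnesses and interaction kernel for FQ water."""

    chi: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CHI))
    eta: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ETA))
    kernel: str = "ohno"          # "ohno" | "coulomb"
    water_charge: float = 0.0     # constrained total charge per water

    def __post_init__(self):
        if self.kernel not in ("ohno", "coulomb"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        for t in ("O", "H"):
            if t not in self.chi or t not in self.eta:
                raise ValueError(f"missing FQ parameters for site type {t!r}")
            if self.eta[t] <= 0:
                raise ValueError("hardness must be positive for every site type")


@dataclass(frozen=True)
class ChargeSolution:
    """Solved FQ charges for one frame."""

    charges: np.ndarray      # (3W,) e, site order O,H,H per water
    multipliers: np.ndarray  # (W,) hartree/e
    energy: float            # hartree
    residual: float          # norm of the bordered linear system residual
    site_types: tuple[str, ...]
    positions_bohr: np.ndarray  # (3W, 3)
    params: FQParameters

    def per_molecule_totals(self) -> np.ndarray:
        return self.charges.reshape(-1, 3).sum(axis=1)


@dataclass(frozen=True)
class ReactionPotential:
    """Electrostatic potential and field of the FQ charges at probe points."""

    probes_bohr: np.ndarray   # (P, 3)
    potential: np.ndarray     # (P,) hartree/e
    field: np.ndarray         # (P, 3) hartree/(e·bohr)


def _site_arrays(frame: SolvatedFrame) -> tuple[np.ndarray, tuple[str, ...]]:
    pos = frame.waters.reshape(-1, 3) * ANG_TO_BOHR
    types = ("O", "H", "H") * frame.n_waters
    return pos, types


def _kernel_matrix(pos: np.ndarray, eta: np.ndarray, kernel: str) -> np.ndarray:
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    n = pos.shape[0]
    off = ~np.eye(n, dtype=bool)
    if kernel == "coulomb":
        if d[off].min() < 1e-10:
            raise FQSolveError("coincident sites make the bare-Coulomb kernel singular")
        J = np.zeros((n, n))
        J[off] = 1.0 / d[off]
    else:  # ohno
        c = 2.0 / (eta[:, None] + eta[None, :])
        J = 1.0 / np.sqrt(d**2 + c**2)
    J[np.diag_indices(n)] = 2.0 * eta
    return J


def external_potential(frame: SolvatedFrame, sites_bohr: np.ndarray) -> np.ndarray:
    """Bare-Coulomb potential of the solute point charges at water sites."""
    sol = frame.solute.coords * ANG_TO_BOHR
    q = frame.solute.charges
    d = np.linalg.norm(sites_bohr[:, None, :] - sol[None, :, :], axis=-1)
    if d.min() < 1e-10:
        raise FQSolveError("water site coincides with a solute charge")
    return (q[None, :] / d).sum(axis=1)


def solve_charges(
    frame: SolvatedFrame,
    params: FQParameters | None = None,
    external_sources: bool | np.ndarray = True,
) -> ChargeSolution:
    """Minimize the FQ energy under per-molecule charge constraints.

    ``external_sources`` may be True (use the solute's point charges),
    False/None (isolated solvent), or an explicit per-site external
    potential array (hartree/e).
    """
    params = params or FQParameters()
    if frame.n_waters < 1:
        raise ValueError("frame has no waters to polarize")
    pos, types = _site_arrays(frame)
    n = pos.shape[0]
    w = frame.n_waters
    chi = np.array([params.chi[t] for t in types])
    eta = np.array([params.eta[t] for t in types])
    J = _kernel_matrix(pos, eta, params.kernel)

    if external_sources is True:
        v_ext = external_potential(frame, pos)
    elif external_sources is False or external_sources is None:
        v_ext = np.zeros(n)
    else:
        v_ext = np.asarray(external_sources, float)
        if v_ext.shape != (n,):
            raise ValueError("external potential must have one value per site")

    C = np.zeros((w, n))
    for m in range(w):
        C[m, 3 * m: 3 * m + 3] = 1.0
    A = np.block([[J, C.T], [C, np.zeros((w, w))]])
    b = np.concatenate([-chi - v_ext, np.full(w, params.water_charge)])
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise FQSolveError(
            f"singular FQ system (condition estimate {np.linalg.cond(A):.3e})"
        ) from exc
    residual = float(np.linalg.norm(A @ sol - b))
    if residual > 1e-8 * max(1.0, float(np.linalg.norm(b))):
        raise FQSolveError(
            f"ill-conditioned FQ system: residual {residual:.3e}, "
            f"condition estimate {np.linalg.cond(A):.3e}")
    q, lam = sol[:n], sol[n:]
    energy = float(chi @ q + 0.5 * q @ J @ q + q @ v_ext)
    return ChargeSolution(charges=q, multipliers=lam, energy=energy,
                          residual=residual, site_types=tuple(types),
                          positions_bohr=pos, params=params)


def fq_energy(solution: ChargeSolution, q: np.ndarray,
              v_ext: np.ndarray | None = None) -> float:
    """FQ energy functional evaluated at an arbitrary charge vector."""
    chi = np.array([solution.params.chi[t] for t in solution.site_types])
    eta = np.array([solution.params.eta[t] for t in solution.site_types])
    J = _kernel_matrix(solution.positions_bohr, eta, solution.params.kernel)
    e = float(chi @ q + 0.5 * q @ J @ q)
    if v_ext is not None:
        e += float(q @ v_ext)
    return e


def reaction_potential(
    solution: ChargeSolution,
    probes_ang: np.ndarray,
    kernel: str = "coulomb",
) -> ReactionPotential:
    """Potential and field of the solved charges at probe points (Å input).

    The probe kernel defaults to bare Coulomb — the reaction potential a
    QM-region solute would feel from classical point charges.  With
    ``kernel='ohno'`` the site's self-damping length 1/eta_i is used (the
    probe carries no hardness of its own).
    """
    probes = np.atleast_2d(np.asarray(probes_ang, float)) * ANG_TO_BOHR
    q = solution.charges
    d = np.linalg.norm(probes[:, None, :] - solution.positions_bohr[None, :, :],
                       axis=-1)
    rvec = probes[:, None, :] - solution.positions_bohr[None, :, :]
    if kernel == "coulomb":
        if d.min() < 1e-9:
            raise ValueError("probe coincides with a charge site (bare kernel)")
        v = (q[None, :] / d).sum(axis=1)
        f = (q[None, :, None] * rvec / d[:, :, None] ** 3).sum(axis=1)
    elif kernel == "ohno":
        eta = np.array([solution.params.eta[t] for t in solution.site_types])
        c = 1.0 / eta
        den = np.sqrt(d**2 + c[None, :] ** 2)
        v = (q[None, :] / den).sum(axis=1)
        f = (q[None, :, None] * rvec / den[:, :, None] ** 3).sum(axis=1)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return ReactionPotential(probes_bohr=probes, potential=v, field=f)


def solvatochromic_shift(
    state: ExcitedState,
    gs_charges: np.ndarray,
    ex_charges: np.ndarray,
    potential: ReactionPotential,
) -> ExcitedState:
    """Linear-response shift of an excitation energy in the FQ potential.

    Delta eps = sum_a (q_a^ex - q_a^gs) V(r_a) with the reaction potential
    evaluated at the solute atoms; the shifted state is returned with its
    transition dipole and gradient unchanged (Franck-Condon picture).
    """
    gs = np.asarray(gs_charges, float)
    ex = np.asarray(ex_charges, float)
    if gs.shape != ex.shape or gs.size != potential.potential.size:
        raise ValueError("charge sets and probe potentials must be atom-matched")
    shift_cm = float((ex - gs) @ potential.potential) * HARTREE_TO_CM
    return dataclasses.replace(state, energy_cm=state.energy_cm + shift_cm)
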