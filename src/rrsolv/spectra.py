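"""UV-Vis, spontaneous Raman and resonance-Raman (RR) spectra.

The RR engine implements the independent-mode displaced harmonic oscillator
(IMDHO) model in the vertical-gradient Franck-Condon (VG|FC) picture:

* the excited-state surface is the ground-state harmonic surface displaced
  along the excited-state gradient; frequencies and normal modes are shared
  between the states and Duschinsky rotation is absent by construction;
* per-mode dimensionless displacements Delta_k come from projecting the
  excited-state Cartesian gradient onto the mass-weighted normal modes,
  Delta_k = -g_k / omega_k^(3/2) (atomic units), with Huang-Rhys factors
  S_k = Delta_k²/2;
* the transition dipole is taken geometry-independent (Franck-Condon only,
  no Herzberg-Teller terms).

RR amplitudes are evaluated two independent ways: a time-independent
sum over vibronic states built from Franck-Condon overlap recursions
(:func:`rr_polarizability`), and a time-dependent half-Fourier transform of
the closed-form IMDHO correlation function (:func:`td_oracle_polarizability`)
which serves as the numerical oracle for the former.

Cross-sections follow sigma ~ omega0 * omega_s^3 |alpha|² with a single
package-wide proportionality constant; all reported enhancement factors are
ratios and therefore prefactor-free.  The absolute experimental
normalization (cm² cm mol⁻¹ sr⁻¹) is not reconstructed.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import simpson
from scipy.stats import spearmanr

from .synthetic import ChromophoreModel, ExcitedState
from .units import (AMU_TO_AU, CM_TO_HARTREE, EV_TO_CM, FWHM_TO_SIGMA,
                    nm_to_cm)

logger = logging.getLogger(__name__)

# Defaults of the RR engine: homogeneous damping (imaginary term of the
# resonance denominators), stick-broadening FWHM, UV-Vis Gaussian FWHM,
# and the incident frequencies of the spontaneous-Raman / RR calculations.
GAMMA_CM = 200.0
RAMAN_FWHM_CM = 8.0
UVVIS_FWHM_EV = 0.6
W0_RAMAN_CM = nm_to_cm(1064.0)   # 9398.50 cm-1
W0_RR_CM = nm_to_cm(266.0)       # 37593.98 cm-1
W0_RR_UV_CM = nm_to_cm(210.0)    # 47619.05 cm-1
RREP_RANGE_CM = (30000.0, 65000.0)
RREP_POINTS = 15
MAX_QUANTA = 10
WEIGHT_CUTOFF = 1e-10

CROSS_SECTION_PREFACTOR = 1.0  # arbitrary units, shared by all outputs


class TruncationWarning(UserWarning):
    """Vibronic sum truncated with a non-negligible tail estimate."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DisplacementVector:
    """Per-mode displacements of an excited state along the normal modes."""

    delta: np.ndarray        # dimensionless Delta_k
    huang_rhys: np.ndarray   # S_k = Delta_k²/2
    g_k: np.ndarray          # mass-weighted gradient projections (a.u.)
    state_index: int = 1

    def __post_init__(self):
        d = np.asarray(self.delta, float)
        s = np.asarray(self.huang_rhys, float)
        object.__setattr__(self, "delta", d)
        object.__setattr__(self, "huang_rhys", s)
        object.__setattr__(self, "g_k", np.asarray(self.g_k, float))
        if np.any(np.abs(s - d**2 / 2) > 1e-12 * np.maximum(1, np.abs(s))):
            raise ValueError("Huang-Rhys factors must equal Delta²/2")


@dataclass(frozen=True)
class Spectrum:
    """Axis/intensity pairs with metadata; the unit of all spectral outputs."""

    axis: np.ndarray
    intensities: np.ndarray
    kind: str                      # uvvis | raman | rr | absorption
    axis_unit: str = "cm-1"
    intensity_unit: str = "arb"
    w0_cm: float | None = None
    broadening: dict | None = None  # {"shape": ..., "fwhm": ...}
    n_averaged: int = 1
    is_sticks: bool = False
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        ax = np.asarray(self.axis, float)
        it = np.asarray(self.intensities, float)
        object.__setattr__(self, "axis", ax)
        object.__setattr__(self, "intensities", it)
        if ax.shape != it.shape:
            raise ValueError("axis and intensities must have matching shapes")
        if ax.size > 1:
            d = np.diff(ax)
            # stick lists may carry degenerate positions; convolved spectra
            # must have a strictly monotone axis
            if np.any(d < 0) or (not self.is_sticks and np.any(d == 0)):
                raise ValueError("spectral axis must be strictly monotone")
        if not self.is_sticks and np.any(it < -1e-12):
            raise ValueError("convolved intensities must be non-negative")


@dataclass(frozen=True)
class RREPGrid:
    """Per-mode RR cross-sections over a grid of excitation frequencies."""

    grid_cm: np.ndarray          # (n_w0,)
    cross_sections: np.ndarray   # (n_modes, n_w0)
    mode_labels: tuple[str, ...]
    mode_freqs_cm: np.ndarray
    gamma_cm: float
    n_averaged: int = 1

    def __post_init__(self):
        g = np.asarray(self.grid_cm, float)
        cs = np.asarray(self.cross_sections, float)
        object.__setattr__(self, "grid_cm", g)
        object.__setattr__(self, "cross_sections", cs)
        object.__setattr__(self, "mode_freqs_cm", np.asarray(self.mode_freqs_cm, float))
        if cs.shape != (len(self.mode_labels), g.size):
            raise ValueError("cross_sections must be (n_modes, n_grid)")
        if np.any(cs < 0):
            raise ValueError("cross-sections must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.cross_sections.T, columns=list(self.mode_labels))
        df.insert(0, "w0_cm", self.grid_cm)
        return df


@dataclass(frozen=True)
class EnhancementReport:
    """Per-mode RR/Raman cross-section ratios (dimensionless factors)."""

    labels: tuple[str, ...]
    freqs_cm: np.ndarray
    raman: np.ndarray
    rr: np.ndarray
    factors: np.ndarray          # NaN where the Raman cross-section is zero
    w0_rr_cm: float | None = None
    w0_raman_cm: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.labels, "freq_cm": self.freqs_cm,
            "raman": self.raman, "rr": self.rr, "factor": self.factors,
        })


# --------------------------------------------------------------------------
# gradient projection and Franck-Condon machinery
# --------------------------------------------------------------------------

def project_gradient(state: ExcitedState, model: ChromophoreModel) -> DisplacementVector:
    """Dimensionless displacements from the excited-state gradient.

    g_k = L_k^T M^(-1/2) grad(E) in atomic units, then
    Delta_k = -g_k / omega_k^(3/2) (hbar = 1) and S_k = Delta_k²/2.
    """
    if state.gradient_au.size != model.modes.shape[0]:
        raise ValueError("gradient and modes are dimensionally inconsistent")
    if np.any(model.freqs_cm <= 0):
        raise ValueError("all mode frequencies must be positive")
    m_au = np.repeat(model.masses_amu * AMU_TO_AU, 3)
    g_k = model.modes.T @ (state.gradient_au / np.sqrt(m_au))
    w_au = model.freqs_cm * CM_TO_HARTREE
    delta = -g_k / w_au**1.5
    return DisplacementVector(delta=delta, huang_rhys=delta**2 / 2,
                              g_k=g_k, state_index=state.index)


def fc_matrix(delta: float, m_max: int, n_max: int) -> np.ndarray:
    """Overlap matrix <m|n> of two equal-frequency oscillators displaced by delta.

    Row index m labels the undisplaced (ground) oscillator, column index n
    the displaced (excited) one.  Built by the stable two-term recursion
    with base <0|0> = exp(-S/2), S = delta²/2.
    """
    if m_max < 0 or n_max < 0:
        raise ValueError("quantum numbers must be >= 0")
    d = delta / np.sqrt(2.0)
    S = delta**2 / 2.0
    F = np.zeros((m_max + 1, n_max + 1))
    F[0, 0] = np.exp(-S / 2.0)
    for n in range(1, n_max + 1):
        F[0, n] = d / np.sqrt(n) * F[0, n - 1]
    for m in range(1, m_max + 1):
        for n in range(n_max + 1):
            t = -d * F[m - 1, n]
            if n > 0:
                t += np.sqrt(n) * F[m - 1, n - 1]
            F[m, n] = t / np.sqrt(m)
    return F


def fc_overlap(S: float, m: int, n: int) -> float:
    """Single displaced-oscillator overlap <m|n> for Huang-Rhys factor S >= 0.

    Uses the recursion for moderate quanta and a log-domain closed form for
    the overflow-prone single-column cases at large quanta.
    """
    if S < 0 or m < 0 or n < 0:
        raise ValueError("S, m, n must be non-negative")
    delta = np.sqrt(2.0 * S)
    big = 170
    if (m == 0 or n == 0) and max(m, n) > big:
        k = max(m, n)
        from scipy.special import gammaln
        log_abs = -S / 2 + k * np.log(max(np.sqrt(S), 1e-300)) - 0.5 * gammaln(k + 1)
        sign = (-1.0) ** k if n == 0 else 1.0  # <m|0> carries (-d)^m
        return float(sign * np.exp(log_abs)) if S > 0 else float(m == n)
    return float(fc_matrix(delta, m, n)[m, n])


def _per_mode_fc_arrays(deltas: np.ndarray, max_quanta: int):
    """A0_k[v] = <0|v><v|0> and A1_k[v] = <1|v><v|0> for each mode."""
    A0, A1 = [], []
    for d in deltas:
        F = fc_matrix(float(d), 1, max_quanta)
        A0.append(F[0, :] ** 2)
        A1.append(F[1, :] * F[0, :])
    return A0, A1


def band_origin_cm(model: ChromophoreModel, state: ExcitedState) -> float:
    """Adiabatic 0-0 energy under VG|FC: eps00 = eps - sum_k S_k omega_k."""
    disp = project_gradient(state, model)
    return float(state.energy_cm - np.sum(disp.huang_rhys * model.freqs_cm))


def _sos_terms(model: ChromophoreModel, state: ExcitedState, mode_j: int | None,
               max_quanta: int, weight_cutoff: float):
    """Enumerate vibronic terms (energies above eps00, FC weights, tail bound).

    ``mode_j`` selects the fundamental whose <1|v><v|0> column replaces the
    diagonal <0|v><v|0> column; ``None`` gives the absorption weights.
    Depth-first enumeration prunes on the partial weight product, which is a
    valid bound because every per-mode factor has magnitude <= 1.
    """
    disp = project_gradient(state, model)
    w = model.freqs_cm
    A0, A1 = _per_mode_fc_arrays(disp.delta, max_quanta)
    K = model.n_modes
    energies: list[float] = []
    weights: list[float] = []

    def dfs(k: int, e_acc: float, w_acc: float, quanta_left: int):
        if k == K:
            energies.append(e_acc)
            weights.append(w_acc)
            return
        col = A1[k] if k == mode_j else A0[k]
        for v in range(min(quanta_left, max_quanta) + 1):
            wv = w_acc * col[v]
            if abs(wv) < weight_cutoff:
                # column magnitudes are unimodal-decaying past the Poisson
                # peak; keep scanning small v but stop once past the peak
                if v > np.argmax(np.abs(col)):
                    break
                continue
            dfs(k + 1, e_acc + v * w[k], wv, quanta_left - v)

    dfs(0, 0.0, 1.0, max_quanta)
    # tail estimate: per-mode completeness deficit of the diagonal columns
    tail = float(sum(1.0 - a.sum() for a in A0))
    return (np.asarray(energies), np.asarray(weights), disp, tail)


# --------------------------------------------------------------------------
# RR amplitudes: TI sum-over-states and TD half-Fourier oracle
# --------------------------------------------------------------------------

def rr_polarizability(
    model: ChromophoreModel,
    state: ExcitedState,
    mode_j: int,
    w0_cm: float | np.ndarray,
    gamma_cm: float = GAMMA_CM,
    max_quanta: int = MAX_QUANTA,
    weight_cutoff: float = WEIGHT_CUTOFF,
    tail_tol: float = 1e-8,
) -> complex | np.ndarray:
    """RR transition polarizability of fundamental ``mode_j`` (TI sum over states).

    alpha_j(w0) = mu² sum_v <1_j|v_j><v_j|0> prod_{k!=j} <0|v_k><v_k|0>
                  / (eps00 + sum_k v_k omega_k - w0 - i Gamma)

    with eps00 the VG|FC adiabatic origin.  Accepts a scalar or an array of
    excitation frequencies; truncation is bounded by ``max_quanta`` total
    vibrational quanta plus a per-term weight cutoff, and a completeness
    tail estimate triggers a :class:`TruncationWarning` when above
    ``tail_tol``.
    """
    if gamma_cm <= 0:
        raise ValueError("damping Gamma must be positive")
    E, W, disp, tail = _sos_terms(model, state, mode_j, max_quanta, weight_cutoff)
    if tail > tail_tol:
        warnings.warn(
            f"vibronic sum truncated: completeness tail estimate {tail:.2e} "
            f"exceeds {tail_tol:.0e}; increase max_quanta",
            TruncationWarning, stacklevel=2)
    eps00 = state.energy_cm - float(np.sum(disp.huang_rhys * model.freqs_cm))
    mu2 = state.trans_dipole_au**2
    w0 = np.asarray(w0_cm, float)
    scalar = w0.ndim == 0
    w0 = np.atleast_1d(w0)
    if E.size == 0:
        alpha = np.zeros(w0.shape, complex)
    else:
        denom = (eps00 + E)[:, None] - w0[None, :] - 1j * gamma_cm
        alpha = mu2 * np.sum(W[:, None] / denom, axis=0)
    return complex(alpha[0]) if scalar else alpha


class QuadratureError(RuntimeError):
    """Half-Fourier quadrature failed to converge."""


def td_oracle_polarizability(
    model: ChromophoreModel,
    state: ExcitedState,
    mode_j: int,
    w0_cm: float,
    gamma_cm: float = GAMMA_CM,
    tol: float = 1e-8,
    max_points: int = 2**22,
) -> complex:
    """Same IMDHO amplitude as a damped half-Fourier integral (independent oracle).

    alpha_j(w0) = i mu² int_0^inf dt e^{i(w0-eps00)t - Gamma t}
                  d_j (e^{-i w_j t} - 1) prod_k exp[S_k (e^{-i w_k t} - 1)]

    with d_j = Delta_j/sqrt(2); evaluated by composite Simpson quadrature,
    refined until the relative change is below ``tol``.
    """
    if gamma_cm <= 0:
        raise ValueError("damping Gamma must be positive")
    disp = project_gradient(state, model)
    S = disp.huang_rhys
    w = model.freqs_cm
    eps00 = state.energy_cm - float(np.sum(S * w))
    mu2 = state.trans_dipole_au**2
    d_j = disp.delta[mode_j] / np.sqrt(2.0)
    if d_j == 0.0 and np.all(S == 0):
        return 0.0 + 0.0j

    T = 32.2 / gamma_cm  # exp(-Gamma T) ~ 1e-14
    fmax = abs(w0_cm - eps00) + (MAX_QUANTA + 2) * float(w.max()) + gamma_cm
    n = int(max(4096, 8 * T * fmax / (2 * np.pi)))
    n = 2 ** int(np.ceil(np.log2(n)))

    def evaluate(npts: int) -> complex:
        t = np.linspace(0.0, T, npts + 1)
        z = np.exp(-1j * np.outer(w, t))
        corr = np.exp(np.sum(S[:, None] * (z - 1.0), axis=0))
        integrand = (1j * mu2 * np.exp(1j * (w0_cm - eps00) * t - gamma_cm * t)
                     * d_j * (z[mode_j] - 1.0) * corr)
        return complex(simpson(integrand.real, x=t) + 1j * simpson(integrand.imag, x=t))

    prev = evaluate(n)
    while True:
        n *= 2
        if n > max_points:
            raise QuadratureError(
                f"half-Fourier quadrature not converged at {n//2} points "
                f"(T={T:.3e}, last value {prev:.6e})")
        cur = evaluate(n)
        if abs(cur - prev) <= tol * max(abs(cur), 1e-30):
            return cur
        prev = cur


# --------------------------------------------------------------------------
# cross-sections and stick spectra
# --------------------------------------------------------------------------

def rr_cross_section(alpha: complex | np.ndarray, w0_cm: float,
                     w_mode_cm: float) -> float | np.ndarray:
    """sigma_j ~ w0 * ws³ |alpha_j|², ws = w0 - w_j (package-consistent units)."""
    ws = w0_cm - w_mode_cm
    if np.any(np.asarray(ws) <= 0):
        raise ValueError("scattered frequency w0 - w_mode must be positive")
    out = CROSS_SECTION_PREFACTOR * w0_cm * ws**3 * np.abs(alpha) ** 2
    return float(out) if np.isscalar(alpha) or np.asarray(alpha).ndim == 0 else out


def rr_stick_spectrum(
    model: ChromophoreModel,
    state: ExcitedState | int = 1,
    w0_cm: float = W0_RR_CM,
    gamma_cm: float = GAMMA_CM,
    max_quanta: int = MAX_QUANTA,
    weight_cutoff: float = WEIGHT_CUTOFF,
) -> Spectrum:
    """Per-mode RR cross-section sticks at a single excitation frequency."""
    if isinstance(state, int):
        state = model.state(state)
    sticks = np.empty(model.n_modes)
    for j in range(model.n_modes):
        alpha = rr_polarizability(model, state, j, w0_cm, gamma_cm,
                                  max_quanta, weight_cutoff)
        sticks[j] = rr_cross_section(alpha, w0_cm, float(model.freqs_cm[j]))
    return Spectrum(axis=model.freqs_cm, intensities=sticks, kind="rr",
                    w0_cm=w0_cm, is_sticks=True, labels=model.mode_labels,
                    intensity_unit="arb-cross-section",
                    broadening={"gamma_cm": gamma_cm})


def raman_spectrum(model: ChromophoreModel, w0_cm: float = W0_RAMAN_CM) -> Spectrum:
    """Spontaneous (off-resonance) Raman sticks from polarizability derivatives.

    Activity per mode is the invariant combination 45 a'_k² + 7 gamma'_k²;
    the stick intensity is w0 * ws³ * activity / omega_k (the 1/omega
    harmonic amplitude factor), with the same global prefactor as the RR
    cross-sections so enhancement ratios are meaningful.
    """
    if model.alpha_deriv.size != model.n_modes or model.gamma_deriv.size != model.n_modes:
        raise ValueError("polarizability-derivative invariants missing")
    ws = w0_cm - model.freqs_cm
    if np.any(ws <= 0):
        raise ValueError("scattered frequency must stay positive")
    activity = 45.0 * model.alpha_deriv**2 + 7.0 * model.gamma_deriv**2
    sticks = CROSS_SECTION_PREFACTOR * w0_cm * ws**3 * activity / model.freqs_cm
    return Spectrum(axis=model.freqs_cm, intensities=sticks, kind="raman",
                    w0_cm=w0_cm, is_sticks=True, labels=model.mode_labels,
                    intensity_unit="arb-cross-section")


def raman_activity_from_tensors(alpha_tensor_deriv: np.ndarray) -> tuple[float, float]:
    """Placzek invariants (a', gamma'²) of a 3x3 polarizability derivative."""
    t = np.asarray(alpha_tensor_deriv, float)
    a = np.trace(t) / 3.0
    sym = 0.5 * (t + t.T)
    g2 = 1.5 * np.sum((sym - a * np.eye(3)) ** 2)
    return float(a), float(g2)


# --------------------------------------------------------------------------
# UV-Vis and broadening
# --------------------------------------------------------------------------

def uvvis_spectrum(
    snapshots: Sequence[Sequence[tuple[float, float]]] | Sequence[ChromophoreModel],
    fwhm_ev: float = UVVIS_FWHM_EV,
    grid_cm: np.ndarray | None = None,
    return_members: bool = False,
):
    """Ensemble-averaged UV-Vis band from per-snapshot (energy, f) sticks.

    Each snapshot's sticks are convolved with unit-height-at-center
    Gaussians of the given FWHM, weighted by oscillator strength; the
    ensemble mean spectrum is returned (per-snapshot spectra on request).
    Accepts either lists of (eps_cm, f) pairs or :class:`ChromophoreModel`s.
    """
    if fwhm_ev <= 0:
        raise ValueError("FWHM must be positive")
    if len(snapshots) == 0:
        raise ValueError("empty ensemble")
    stick_lists = []
    for snap in snapshots:
        if isinstance(snap, ChromophoreModel):
            stick_lists.append([(s.energy_cm, s.osc_strength) for s in snap.states])
        else:
            stick_lists.append([(float(e), float(f)) for e, f in snap])
    fwhm_cm = fwhm_ev * EV_TO_CM
    sigma = fwhm_cm * FWHM_TO_SIGMA
    if grid_cm is None:
        all_e = np.array([e for sl in stick_lists for e, _ in sl])
        lo = max(all_e.min() - 3 * fwhm_cm, 0.0)
        hi = all_e.max() + 3 * fwhm_cm
        grid_cm = np.linspace(lo, hi, 2000)
    members = []
    acc = np.zeros_like(grid_cm)
    for sl in stick_lists:
        y = np.zeros_like(grid_cm)
        for e, f in sl:
            y += f * np.exp(-0.5 * ((grid_cm - e) / sigma) ** 2)
        acc += y
        if return_members:
            members.append(Spectrum(axis=grid_cm, intensities=y, kind="uvvis",
                                    broadening={"shape": "gaussian",
                                                "fwhm_ev": fwhm_ev}))
    avg = Spectrum(axis=grid_cm, intensities=acc / len(stick_lists), kind="uvvis",
                   broadening={"shape": "gaussian", "fwhm_ev": fwhm_ev},
                   n_averaged=len(stick_lists))
    return (avg, members) if return_members else avg


def convolve_sticks(
    sticks: Spectrum,
    shape: str = "lorentzian",
    fwhm_cm: float = RAMAN_FWHM_CM,
    grid_cm: np.ndarray | None = None,
    points: int = 4000,
) -> Spectrum:
    """Sum of unit-area line shapes scaled by stick intensities.

    The grid is auto-extended (with a log notice) when it does not cover
    every stick ± 10 FWHM.
    """
    if fwhm_cm <= 0:
        raise ValueError("FWHM must be positive")
    if shape not in ("lorentzian", "gaussian"):
        raise ValueError(f"unknown line shape {shape!r}")
    lo_need = sticks.axis.min() - 10 * fwhm_cm
    hi_need = sticks.axis.max() + 10 * fwhm_cm
    if grid_cm is None:
        grid_cm = np.linspace(lo_need, hi_need, points)
    elif grid_cm.min() > lo_need or grid_cm.max() < hi_need:
        logger.info("convolution grid does not cover sticks ± 10 FWHM; extending")
        step = float(np.median(np.diff(grid_cm)))
        grid_cm = np.arange(min(grid_cm.min(), lo_need),
                            max(grid_cm.max(), hi_need) + step, step)
    y = np.zeros_like(grid_cm)
    if shape == "lorentzian":
        hwhm = fwhm_cm / 2.0
        for x0, inten in zip(sticks.axis, sticks.intensities):
            y += inten * (hwhm / np.pi) / ((grid_cm - x0) ** 2 + hwhm**2)
    else:
        sig = fwhm_cm * FWHM_TO_SIGMA
        for x0, inten in zip(sticks.axis, sticks.intensities):
            y += inten * np.exp(-0.5 * ((grid_cm - x0) / sig) ** 2) / (
                sig * np.sqrt(2 * np.pi))
    return Spectrum(axis=grid_cm, intensities=y, kind=sticks.kind,
                    w0_cm=sticks.w0_cm,
                    broadening={"shape": shape, "fwhm_cm": fwhm_cm},
                    n_averaged=sticks.n_averaged)


def ensemble_average(spectra: Sequence[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of spectra sharing a common axis."""
    if not spectra:
        raise ValueError("nothing to average")
    ax = spectra[0].axis
    for s in spectra[1:]:
        if s.axis.shape != ax.shape or not np.allclose(s.axis, ax):
            raise ValueError("spectra do not share a common axis")
    mean = np.mean([s.intensities for s in spectra], axis=0)
    return dataclasses.replace(spectra[0], intensities=mean,
                               n_averaged=len(spectra))


def average_sticks(spectra: Sequence[Spectrum]) -> Spectrum:
    """Mode-matched average of stick spectra with jittered positions.

    Snapshot stick spectra share mode labels but not positions (frequencies
    fluctuate snapshot to snapshot); the ensemble stick spectrum averages
    position and intensity per mode.  Use :func:`ensemble_average` for
    common-axis convolved spectra instead.
    """
    if not spectra:
        raise ValueError("nothing to average")
    labels = spectra[0].labels
    for s in spectra[1:]:
        if s.labels != labels:
            raise ValueError("stick spectra are not mode-matched")
    axis = np.mean([s.axis for s in spectra], axis=0)
    inten = np.mean([s.intensities for s in spectra], axis=0)
    order = np.argsort(axis)
    return dataclasses.replace(
        spectra[0], axis=axis[order], intensities=inten[order],
        labels=tuple(np.asarray(labels, object)[order]),
        n_averaged=len(spectra))


def convergence_curve(spectra: Sequence[Spectrum]) -> pd.DataFrame:
    """Similarity of prefix averages to the full-ensemble average.

    The metric is the normalized overlap integral
    <S_n, F> / sqrt(<S_n,S_n><F,F>) in [0, 1] for non-negative spectra;
    it equals 1 at n = N by construction.
    """
    if len(spectra) < 2:
        raise ValueError("need at least two spectra")
    full = ensemble_average(spectra).intensities
    x = spectra[0].axis
    rows = []
    acc = np.zeros_like(full)
    denom_full = simpson(full * full, x=x)
    for n, s in enumerate(spectra, start=1):
        acc += s.intensities
        mean_n = acc / n
        num = simpson(mean_n * full, x=x)
        den = np.sqrt(simpson(mean_n * mean_n, x=x) * denom_full)
        rows.append((n, num / den if den > 0 else 1.0))
    return pd.DataFrame(rows, columns=["n", "similarity"])


# --------------------------------------------------------------------------
# excitation profiles, absorption lineshape, enhancement analysis
# --------------------------------------------------------------------------

def rrep(
    ensemble: Sequence[ChromophoreModel],
    grid_cm: np.ndarray | None = None,
    gamma_cm: float = GAMMA_CM,
    state_index: int = 1,
    max_quanta: int = MAX_QUANTA,
    weight_cutoff: float = WEIGHT_CUTOFF,
) -> RREPGrid:
    """Ensemble-averaged RR excitation profile on a grid of w0 values.

    Default grid: 15 points uniform in wavenumber over 30,000-65,000 cm⁻¹.
    """
    if grid_cm is None:
        grid_cm = np.linspace(*RREP_RANGE_CM, RREP_POINTS)
    grid_cm = np.asarray(grid_cm, float)
    base = ensemble[0]
    if grid_cm.min() <= base.freqs_cm.max():
        raise ValueError("excitation grid must keep w0 - w_mode positive")
    acc = np.zeros((base.n_modes, grid_cm.size))
    for model in ensemble:
        state = model.state(state_index)
        for j in range(model.n_modes):
            alpha = rr_polarizability(model, state, j, grid_cm, gamma_cm,
                                      max_quanta, weight_cutoff)
            ws = grid_cm - model.freqs_cm[j]
            acc[j] += CROSS_SECTION_PREFACTOR * grid_cm * ws**3 * np.abs(alpha) ** 2
    acc /= len(ensemble)
    return RREPGrid(grid_cm=grid_cm, cross_sections=acc,
                    mode_labels=base.mode_labels, mode_freqs_cm=base.freqs_cm,
                    gamma_cm=gamma_cm, n_averaged=len(ensemble))


def absorption_lineshape(
    model: ChromophoreModel,
    state: ExcitedState | int = 1,
    gamma_cm: float = GAMMA_CM,
    grid_cm: np.ndarray | None = None,
    max_quanta: int = MAX_QUANTA,
    weight_cutoff: float = WEIGHT_CUTOFF,
) -> Spectrum:
    """IMDHO vibronic absorption band of one state (Lorentzian lines, HWHM Gamma).

    sigma_abs(w) ~ w * sum_v prod_k |<v_k|0>|² L(eps00 + sum v_k w_k - w)
    from the same displacements and origin as the RR engine; this is the
    consistency partner of :func:`rrep` (enhancement maxima should track
    absorption maxima).
    """
    if gamma_cm <= 0:
        raise ValueError("damping Gamma must be positive")
    if isinstance(state, int):
        state = model.state(state)
    E, W, disp, tail = _sos_terms(model, state, None, max_quanta, weight_cutoff)
    if tail > 1e-8:
        warnings.warn(f"vibronic sum truncated (tail {tail:.2e})",
                      TruncationWarning, stacklevel=2)
    eps00 = state.energy_cm - float(np.sum(disp.huang_rhys * model.freqs_cm))
    if grid_cm is None:
        lo = max(eps00 - 10 * gamma_cm, 1.0)
        hi = eps00 + E.max() + 10 * gamma_cm if E.size else eps00 + 10 * gamma_cm
        grid_cm = np.linspace(lo, hi, 3000)
    pos = eps00 + E
    lor = (gamma_cm / np.pi) / ((grid_cm[:, None] - pos[None, :]) ** 2 + gamma_cm**2)
    y = state.trans_dipole_au**2 * grid_cm * (lor @ W)
    return Spectrum(axis=grid_cm, intensities=np.maximum(y, 0.0),
                    kind="absorption",
                    broadening={"shape": "lorentzian", "gamma_cm": gamma_cm})


def enhancement_factors(rr_sticks: Spectrum, raman_sticks: Spectrum) -> EnhancementReport:
    """Per-mode RR/Raman cross-section ratio, sorted by mode frequency.

    Sticks are matched by label when both spectra carry labels, otherwise
    positionally.  Modes with zero Raman cross-section get a NaN factor
    (undefined, not infinite).
    """
    if rr_sticks.labels and raman_sticks.labels:
        if set(rr_sticks.labels) != set(raman_sticks.labels):
            raise ValueError("mode labels of the two stick spectra do not match")
        order = [raman_sticks.labels.index(lbl) for lbl in rr_sticks.labels]
        raman_i = raman_sticks.intensities[order]
        raman_f = raman_sticks.axis[order]
        labels = rr_sticks.labels
    else:
        if rr_sticks.axis.size != raman_sticks.axis.size:
            raise ValueError("stick lists are not mode-matched")
        raman_i, raman_f = raman_sticks.intensities, raman_sticks.axis
        labels = rr_sticks.labels or tuple(
            f"mode{k+1}" for k in range(rr_sticks.axis.size))
    rr_i = rr_sticks.intensities
    with np.errstate(divide="ignore", invalid="ignore"):
        factors = np.where(raman_i > 0, rr_i / raman_i, np.nan)
    order = np.argsort(rr_sticks.axis)
    return EnhancementReport(
        labels=tuple(np.asarray(labels, object)[order]),
        freqs_cm=rr_sticks.axis[order], raman=raman_i[order],
        rr=rr_i[order], factors=factors[order],
        w0_rr_cm=rr_sticks.w0_cm, w0_raman_cm=raman_sticks.w0_cm)


@dataclass(frozen=True)
class ShiftIntensityReport:
    """Rank correlation between short-time-limit weights and RR intensities."""

    spearman_rho: float          # NaN when undefined by ties
    undefined_by_ties: bool
    pre_resonance: bool
    weights: np.ndarray          # omega_k² Delta_k²
    intensities: np.ndarray


def shift_intensity_check(
    displacements: DisplacementVector,
    rr_sticks: Spectrum,
    band_origin: float | None = None,
    gamma_cm: float = GAMMA_CM,
) -> ShiftIntensityReport:
    """Do the largest-displacement modes carry the strongest RR sticks?

    In the short-time limit relative RR intensities follow omega_k² Delta_k²;
    the report gives the Spearman rank correlation of that weight against the
    stick intensities.  ``pre_resonance`` flags excitation more than 5 Gamma
    below the band origin, where the short-time ordering is expected to hold
    tightly; at strict resonance multimode interference can break it.
    """
    w = rr_sticks.axis
    if w.size < 3:
        raise ValueError("need at least 3 modes for a rank correlation")
    if displacements.delta.size != w.size:
        raise ValueError("displacements and sticks are not mode-matched")
    weights = w**2 * displacements.delta**2
    ties = (np.unique(weights).size == 1) or (np.unique(rr_sticks.intensities).size == 1)
    if ties:
        rho = float("nan")
    else:
        rho = float(spearmanr(weights, rr_sticks.intensities).statistic)
    pre = False
    if band_origin is not None and rr_sticks.w0_cm is not None:
        pre = rr_sticks.w0_cm < band_origin - 5 * gamma_cm
    return ShiftIntensityReport(spearman_rho=rho, undefined_by_ties=ties,
                                pre_resonance=pre, weights=weights,
                                intensities=rr_sticks.intensities)
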