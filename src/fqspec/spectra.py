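"""Stick spectra, Gaussian broadening, ensemble averaging and shifts.

Each snapshot contributes a stick spectrum (excitation energies with
oscillator strengths); the ensemble line shape is built by convolving
every stick with a Gaussian of fixed full width at half maximum (default
0.3 eV) and averaging the per-snapshot curves point by point.  The
solvatochromic shift is Delta E = E_vac - E_solv, positive for a red
shift (solution band below the gas-phase band).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .units import ev_to_nm, nm_to_ev  # noqa: F401  (re-exported conversions)

__all__ = [
    "StickSpectrum",
    "SpectrumCurve",
    "ShiftResult",
    "convolve_gaussian",
    "ensemble_average",
    "band_maximum",
    "band_width",
    "solvatochromic_shift",
    "nm_to_ev",
    "ev_to_nm",
    "DEFAULT_FWHM",
    "DEFAULT_GRID",
]

#: Default Gaussian broadening, eV (full width at half maximum).
DEFAULT_FWHM = 0.3

#: Default energy grid (min, max, step), eV.
DEFAULT_GRID = (1.5, 8.0, 0.01)

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class StickSpectrum:
    """Raw transitions of one snapshot: (energy eV, oscillator strength)."""

    transitions: list[tuple[float, float]]
    snapshot_id: int = 0

    def __post_init__(self):
        for e, f in self.transitions:
            if e <= 0:
                raise ValueError(f"transition energy must be positive, got {e}")
            if f < 0:
                raise ValueError(f"oscillator strength must be nonnegative, got {f}")

    @property
    def energies(self) -> np.ndarray:
        return np.array([e for e, _ in self.transitions])

    @property
    def strengths(self) -> np.ndarray:
        return np.array([f for _, f in self.transitions])

    def first_energy(self) -> float:
        """Energy of the lowest transition, eV."""
        if not self.transitions:
            raise ValueError("empty stick spectrum")
        return float(min(e for e, _ in self.transitions))


@dataclass
class SpectrumCurve:
    """Broadened spectrum on a uniform energy grid (arbitrary units)."""

    energies: np.ndarray
    intensity: np.ndarray
    fwhm: float
    n_snapshots: int = 1

    def __post_init__(self):
        self.energies = np.asarray(self.energies, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        steps = np.diff(self.energies)
        if self.energies.size < 2 or np.any(steps <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-8):
            raise ValueError("energy grid must be uniform")
        if np.any(self.intensity < -1e-12):
            raise ValueError("intensity must be nonnegative")

    @property
    def step(self) -> float:
        return float(self.energies[1] - self.energies[0])

    def area(self) -> float:
        return float(np.trapezoid(self.intensity, self.energies))


@dataclass
class ShiftResult:
    """Gas-phase and solution band energies with their difference (eV)."""

    e_vac: float
    e_solv: float
    delta_e: float


def convolve_gaussian(
    sticks: StickSpectrum,
    fwhm: float = DEFAULT_FWHM,
    grid: tuple[float, float, float] = DEFAULT_GRID,
) -> SpectrumCurve:
    """Broaden a stick spectrum with Gaussians of the given FWHM.

    intensity(E) = sum_k f_k exp(-(E - E_k)^2 / (2 sigma^2)) with
    sigma = fwhm / (2 sqrt(2 ln 2)); each stick contributes area
    f_k * sigma * sqrt(2 pi).  Sticks whose +-3 sigma support falls
    partly outside the grid trigger a truncation warning reporting the
    clipped fraction.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    lo, hi, step = grid
    if step <= 0 or hi <= lo:
        raise ValueError(f"bad grid {grid}")
    energies = np.arange(lo, hi + 0.5 * step, step)
    sigma = fwhm * _SIGMA_PER_FWHM

    if not sticks.transitions:
        return SpectrumCurve(energies=energies, intensity=np.zeros_like(energies),
                             fwhm=fwhm)

    e_k = sticks.energies
    f_k = sticks.strengths
    outside = (e_k - 3 * sigma < lo) | (e_k + 3 * sigma > hi)
    if outside.any():
        clipped = float(f_k[outside].sum() / max(f_k.sum(), 1e-300))
        warnings.warn(
            f"grid {grid} clips {outside.sum()} stick(s) "
            f"({100 * clipped:.1f}% of total strength)",
            stacklevel=2,
        )
    intensity = np.sum(
        f_k[:, None] * np.exp(-((energies[None, :] - e_k[:, None]) ** 2)
                              / (2.0 * sigma**2)),
        axis=0,
    )
    return SpectrumCurve(energies=energies, intensity=intensity, fwhm=fwhm)


def ensemble_average(curves: list[SpectrumCurve]) -> SpectrumCurve:
    """Pointwise arithmetic mean of per-snapshot curves (identical grids)."""
    if not curves:
        raise ValueError("need at least one curve")
    ref = curves[0]
    for c in curves[1:]:
        if c.energies.shape != ref.energies.shape or not np.allclose(
            c.energies, ref.energies
        ):
            raise ValueError("curves must share an identical energy grid")
        if c.fwhm != ref.fwhm:
            raise ValueError("curves must share the same broadening")
    mean = np.mean([c.intensity for c in curves], axis=0)
    return SpectrumCurve(energies=ref.energies.copy(), intensity=mean,
                         fwhm=ref.fwhm, n_snapshots=len(curves))


def band_maximum(curve: SpectrumCurve, window: tuple[float, float] | None = None) -> float:
    """Energy (eV) of the intensity maximum inside *window*.

    The discrete argmax is refined by a three-point parabolic fit, the
    standard sub-grid read-out for a smooth band.  A flat window (no
    intensity above numerical noise) raises a no-band error.
    """
    e, y = curve.energies, curve.intensity
    global_max = float(y.max()) if y.size else 0.0
    if window is not None:
        lo, hi = window
        if lo < e[0] - 1e-9 or hi > e[-1] + 1e-9:
            raise ValueError("window extends beyond the grid")
        mask = (e >= lo) & (e <= hi)
        e, y = e[mask], y[mask]
    # a band must carry non-negligible intensity relative to the whole curve
    if e.size == 0 or y.max() <= max(1e-300, 1e-8 * global_max):
        raise ValueError("no band found: curve is flat in the window")
    i = int(np.argmax(y))
    if 0 < i < y.size - 1:
        denom = y[i - 1] - 2 * y[i] + y[i + 1]
        if denom < 0:
            return float(e[i] + 0.5 * curve.step * (y[i - 1] - y[i + 1]) / denom)
    return float(e[i])


def band_width(sticks: list[StickSpectrum]) -> float:
    """Inhomogeneous band width: std-dev (eV) of the first-transition
    energies across snapshots."""
    e1 = np.array([s.first_energy() for s in sticks])
    return float(np.std(e1))


def solvatochromic_shift(e_vac: float, e_solv: float) -> ShiftResult:
    """Delta E = E_vac - E_solv (eV); positive for a red shift."""
    if e_vac <= 0 or e_solv <= 0:
        raise ValueError("band energies must be positive")
    return ShiftResult(e_vac=e_vac, e_solv=e_solv, delta_e=e_vac - e_solv)
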