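"""Absorption-spectrum machinery: broadening, thermal averaging, peak finding.

Excitation "sticks" (energy, oscillator strength) are broadened with a
Lorentzian lineshape of half-width-at-half-maximum equal to the intrinsic
bandwidth (default 0.003 Ry ~ 0.0408 eV); room-temperature spectra are
uniform averages over frames sampled from a trajectory; peak positions are
read off the smoothed second derivative of the intensity, which resolves
shoulders the direct curve hides.  Energy/wavelength conversions use
lambda(nm) = 1239.84193 / E(eV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import argrelmin, savgol_filter

from .constants import HC_EV_NM, RYDBERG_EV
from .errors import InputError

__all__ = [
    "SpectrumModel", "DEFAULT_BANDWIDTH_EV", "broaden", "thermal_average",
    "second_derivative_peaks", "ev_to_nm", "nm_to_ev", "ry_to_ev",
    "sticks_from_trajectory",
]

#: 0.003 Ry, the intrinsic broadening used for all reported spectra (eV).
DEFAULT_BANDWIDTH_EV = 0.003 * RYDBERG_EV


@dataclass
class SpectrumModel:
    """A broadened absorption spectrum on a fixed energy grid.

    ``sticks`` are (energy eV, oscillator strength) pairs; ``intensity`` is
    the broadened oscillator-strength density (1/eV) so each stick
    integrates to its oscillator strength.
    """

    sticks: list[tuple[float, float]]
    grid: np.ndarray
    intensity: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.intensity, self.grid))


def ev_to_nm(energy_ev) -> float | np.ndarray:
    """Photon wavelength in nm for an energy in eV."""
    energy_ev = np.asarray(energy_ev, dtype=float)
    if np.any(energy_ev <= 0):
        raise InputError("energy must be > 0")
    out = HC_EV_NM / energy_ev
    return float(out) if out.ndim == 0 else out


def nm_to_ev(wavelength_nm) -> float | np.ndarray:
    """Photon energy in eV for a wavelength in nm."""
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    if np.any(wavelength_nm <= 0):
        raise InputError("wavelength must be > 0")
    out = HC_EV_NM / wavelength_nm
    return float(out) if out.ndim == 0 else out


def ry_to_ev(energy_ry) -> float | np.ndarray:
    """Convert Rydberg to eV (1 Ry = 13.605693 eV)."""
    energy_ry = np.asarray(energy_ry, dtype=float)
    if np.any(energy_ry <= 0):
        raise InputError("energy must be > 0")
    out = RYDBERG_EV * energy_ry
    return float(out) if out.ndim == 0 else out


def _lorentzian(grid, center, hwhm):
    return (hwhm / np.pi) / ((grid - center) ** 2 + hwhm**2)


def _gaussian(grid, center, hwhm):
    s = hwhm / np.sqrt(2.0 * np.log(2.0))
    return np.exp(-0.5 * ((grid - center) / s) ** 2) / (s * np.sqrt(2.0 * np.pi))


def broaden(sticks, bandwidth: float = DEFAULT_BANDWIDTH_EV, grid=None, *,
            lineshape: str = "lorentzian") -> SpectrumModel:
    """Broaden excitation sticks into a continuous spectrum.

    Parameters
    ----------
    sticks : iterable of (energy_eV, oscillator_strength)
    bandwidth : float
        HWHM of the lineshape in eV (default the intrinsic 0.003 Ry).
    grid : array, optional
        Energy axis; default spans the sticks +/- 25 bandwidths at
        bandwidth/20 spacing.
    lineshape : {"lorentzian", "gaussian"}

    Each stick contributes a unit-area lineshape scaled by its oscillator
    strength, so the spectrum integrates to the total oscillator strength
    (up to lineshape tails outside the grid).
    """
    if bandwidth <= 0:
        raise InputError("bandwidth must be > 0")
    sticks = [(float(e), float(f)) for e, f in sticks]
    if any(e <= 0 for e, _ in sticks):
        raise InputError("stick energies must be > 0")
    if grid is None:
        if sticks:
            lo = min(e for e, _ in sticks) - 25 * bandwidth
            hi = max(e for e, _ in sticks) + 25 * bandwidth
            grid = np.arange(max(lo, bandwidth / 20), hi, bandwidth / 20)
        else:
            grid = np.linspace(1.0, 10.0, 1001)
    grid = np.asarray(grid, dtype=float)
    shape = _lorentzian if lineshape == "lorentzian" else _gaussian
    intensity = np.zeros_like(grid)
    if not sticks:
        warnings.warn("no sticks supplied; returning an empty spectrum")
    for e, f in sticks:
        intensity += f * shape(grid, e, bandwidth)
    return SpectrumModel(sticks=sticks, grid=grid, intensity=intensity,
                         bandwidth=bandwidth)


def thermal_average(frame_spectra, n_sample: int = 25,
                    seed: int | None = None) -> SpectrumModel:
    """Average spectra of frames sampled from a thermal trajectory.

    Draws ``n_sample`` frames uniformly at random without replacement
    (default 25) and returns their pointwise mean intensity on the shared
    grid.  Frames are weighted uniformly: a thermostatted trajectory already
    visits configurations with Boltzmann frequency.
    """
    frame_spectra = list(frame_spectra)
    if not frame_spectra:
        raise InputError("no frame spectra supplied")
    grid = frame_spectra[0].grid
    for s in frame_spectra[1:]:
        if s.grid.shape != grid.shape or not np.allclose(s.grid, grid):
            raise InputError("frame spectra must share one energy grid")
    if n_sample > len(frame_spectra):
        raise InputError(f"n_sample {n_sample} exceeds available frames "
                         f"({len(frame_spectra)})")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(frame_spectra), size=n_sample, replace=False)
    intensity = np.mean([frame_spectra[i].intensity for i in pick], axis=0)
    sticks = [s for i in pick for s in frame_spectra[i].sticks]
    return SpectrumModel(sticks=sticks, grid=grid, intensity=intensity,
                         bandwidth=frame_spectra[0].bandwidth)


def second_derivative_peaks(spectrum: SpectrumModel, *, window: int = 7,
                            polyorder: int = 3,
                            prominence: float | None = None):
    """Locate peaks as minima of the smoothed second derivative.

    The intensity is smoothed with a Savitzky-Golay filter (default window
    7, order 3) and differentiated twice analytically; peaks are local
    minima of the second derivative more negative than a prominence
    threshold (default 1% of the deepest minimum).  Returns a list of
    ``(energy_eV, wavelength_nm)`` pairs sorted by energy.
    """
    grid, intensity = spectrum.grid, spectrum.intensity
    if grid.size < window:
        raise InputError(f"grid shorter than smoothing window ({window})")
    h = np.diff(grid)
    if not np.allclose(h, h[0], rtol=1e-6):
        raise InputError("second_derivative_peaks requires a uniform grid")
    d2 = savgol_filter(intensity, window_length=window, polyorder=polyorder,
                       deriv=2, delta=h[0])
    if not np.any(d2 < 0):
        return []
    if prominence is None:
        prominence = 0.01 * abs(d2.min())
    idx = argrelmin(d2)[0]
    idx = idx[d2[idx] < -prominence]
    return [(float(grid[i]), float(ev_to_nm(grid[i]))) for i in sorted(idx)]


def sticks_from_trajectory(traj, frame_indices=None):
    """One (gap, oscillator strength) stick per selected trajectory frame."""
    idx = range(len(traj)) if frame_indices is None else frame_indices
    return [[(float(traj.e_s1[i] - traj.e_s0[i]), float(traj.osc_strength[i]))]
            for i in idx]
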