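"""Franck-Condon factors for displaced (optionally frequency-changed)
harmonic oscillators.

For two harmonic potentials with equal frequency, displaced by a
dimensionless mass-weighted shift d, the vibrational overlap from the
excited-state ground level follows the Poisson distribution in the
Huang-Rhys factor S = d^2/2:

    FC(0 -> n) = e^(-S) S^n / n!

so FC(0 -> 0) = e^(-S) and S = -ln FC00 inverts it.  A 0-0 factor near 1
(small S) means emission barely changes the geometry: the transition is
dominated by the v'=0 -> v''=0 line.  For unequal frequencies the 0-0
overlap has the closed form

    FC(0 -> 0) = [2 sqrt(w' w'') / (w' + w'')] * exp(-w' w'' d^2 / (w' + w'')) ,

with d in the dimensionless coordinate of the mean frequency; general
(0 -> n) overlaps are evaluated by quadrature of the harmonic
eigenfunctions.  Frequencies may be given in eV or cm^-1 (tagged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import EV_TO_WAVENUMBER
from .errors import InputError

__all__ = ["HarmonicMode", "fc_factor", "fc_table", "infer_huang_rhys",
           "classify_00_dominance", "multimode_fc00"]


def _to_ev(value: float, units: str) -> float:
    if units == "eV":
        return value
    if units in ("cm-1", "cm^-1", "wavenumber"):
        return value / EV_TO_WAVENUMBER
    raise InputError(f"unknown frequency units {units!r}; use 'eV' or 'cm-1'")


@dataclass(frozen=True)
class HarmonicMode:
    """One effective vibrational mode of the two electronic states.

    ``displacement`` is the dimensionless (mass- and frequency-weighted)
    shift between the minima; for equal frequencies the Huang-Rhys factor
    is S = displacement^2 / 2.
    """

    freq_ground: float
    freq_excited: float
    displacement: float
    units: str = "eV"

    def __post_init__(self):
        if self.freq_ground <= 0 or self.freq_excited <= 0:
            raise InputError("mode frequencies must be > 0")

    @property
    def freq_ground_ev(self) -> float:
        return _to_ev(self.freq_ground, self.units)

    @property
    def freq_excited_ev(self) -> float:
        return _to_ev(self.freq_excited, self.units)

    @property
    def huang_rhys(self) -> float:
        """S = d^2/2 (exact for equal frequencies)."""
        return 0.5 * self.displacement**2

    @classmethod
    def from_huang_rhys(cls, s: float, freq: float = 0.2,
                        units: str = "eV") -> "HarmonicMode":
        if s < 0:
            raise InputError("Huang-Rhys factor must be >= 0")
        return cls(freq_ground=freq, freq_excited=freq,
                   displacement=math.sqrt(2.0 * s), units=units)


def _hermite_overlap(mode: HarmonicMode, n_excited: int, n_ground: int,
                     n_grid: int = 4001, span: float = 12.0) -> float:
    """Quadrature overlap <v'|v''> of the two harmonic eigenfunctions."""
    from numpy.polynomial.hermite import hermval

    wg = mode.freq_ground_ev
    we = mode.freq_excited_ev
    # dimensionless coordinate of the mean frequency; scale each state by
    # sqrt(w_state / w_mean)
    wm = 0.5 * (wg + we)
    x = np.linspace(-span, span, n_grid)

    def psi(n, w, center):
        a = np.sqrt(w / wm)
        xi = a * (x - center)
        coeff = np.zeros(n + 1)
        coeff[n] = 1.0
        h = hermval(xi, coeff)
        norm = np.sqrt(a / (np.sqrt(np.pi) * (2.0**n) * math.factorial(n)))
        return norm * h * np.exp(-0.5 * xi**2)

    # excited-state minimum displaced by d in the mean-frequency coordinate
    integrand = psi(n_excited, we, mode.displacement) * psi(n_ground, wg, 0.0)
    return float(np.trapezoid(integrand, x))


def fc_factor(mode: HarmonicMode, v_excited: int, v_ground: int) -> float:
    """Franck-Condon factor |<v'|v''>|^2 between the two states' levels.

    Equal frequencies with v'=0 use the Poisson closed form
    e^(-S) S^n / n!; every other case is evaluated by quadrature of the
    harmonic-oscillator eigenfunctions.
    """
    if v_excited < 0 or v_ground < 0:
        raise InputError("vibrational quantum numbers must be >= 0")
    wg, we = mode.freq_ground_ev, mode.freq_excited_ev
    if v_excited == 0 and abs(wg - we) < 1e-12 * max(wg, we):
        s = mode.huang_rhys
        return math.exp(-s) * s**v_ground / math.factorial(v_ground)
    if v_excited == 0 and v_ground == 0:
        # closed form for unequal frequencies; displacement d lives in the
        # dimensionless coordinate of the mean frequency (wg + we)/2
        d = mode.displacement
        pref = 2.0 * math.sqrt(wg * we) / (wg + we)
        return pref * math.exp(-2.0 * wg * we * d**2 / (wg + we) ** 2)
    return _hermite_overlap(mode, v_excited, v_ground) ** 2


def fc_table(mode: HarmonicMode, n_max: int = 10) -> np.ndarray:
    """FC factors 0 -> n for n = 0..n_max."""
    return np.array([fc_factor(mode, 0, n) for n in range(n_max + 1)])


def infer_huang_rhys(fc_00: float) -> float:
    """Huang-Rhys factor from a 0-0 Franck-Condon factor, S = -ln FC00.

    Valid for the equal-frequency displaced-oscillator model, where
    FC(0->0) = e^(-S).
    """
    if not (0.0 < fc_00 <= 1.0):
        raise InputError("fc_00 must lie in (0, 1]")
    return -math.log(fc_00)


def classify_00_dominance(mode: HarmonicMode, threshold: float = 0.5,
                          n_max: int = 10) -> bool:
    """Whether the 0-0 line dominates the vibronic progression.

    True iff FC(0->0) exceeds ``threshold`` and every FC(0->n) up to
    ``n_max``.  A dominant 0-0 line is the signature of emission with
    minimal geometric relaxation.
    """
    if not (0.0 < threshold <= 1.0):
        raise InputError("threshold must lie in (0, 1]")
    table = fc_table(mode, n_max)
    return bool(table[0] > threshold and table[0] >= table[1:].max())


def multimode_fc00(modes) -> float:
    """0-0 factor of independent modes: the product of per-mode factors."""
    out = 1.0
    for m in modes:
        out *= fc_factor(m, 0, 0)
    return out
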