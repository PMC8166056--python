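"""Geometric and thermodynamic descriptors of trajectories and geometries.

Covers the observables used to characterise hydrogen-bonded dimers:

- the proton-transfer coordinate delta = d(O1-H) - d(O2-H), whose sampled
  free-energy profile -k_B T ln rho(delta) distinguishes a single-well
  (proton locked on the donor) from a double-well (low-barrier shuttling
  across a short hydrogen bond);
- carbonyl C=O bond-length histograms and ring deplanarization (sum of the
  absolute intra-ring torsions of a five-membered ring), the vibrational
  distortions whose activation opens nonradiative decay channels;
- donor-acceptor heavy-atom distance enumeration with a short-hydrogen-bond
  flag at <= 2.6 A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB_EV_K
from .errors import GeometryError, InputError

__all__ = [
    "Geometry", "FreeEnergyProfile", "DistortionSummary",
    "proton_transfer_coordinate", "free_energy_profile", "classify_wells",
    "dihedral_angle", "ring_deplanarization", "bond_length_series",
    "hb_distances",
]

SHB_CUTOFF = 2.6  # A; donor-acceptor separations at or below this are "short"


@dataclass(frozen=True)
class Geometry:
    """A static molecular geometry: element symbols and Cartesian A coords."""

    elements: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise InputError("coords must have shape (n_atoms, 3)")
        if len(self.elements) != coords.shape[0]:
            raise InputError("elements and coords length mismatch")
        object.__setattr__(self, "coords", coords)

    def __len__(self):
        return len(self.elements)

    def distance(self, i: int, j: int) -> float:
        return float(np.linalg.norm(self.coords[i] - self.coords[j]))


def _check_indices(n: int, *indices: int):
    if len(set(indices)) != len(indices):
        raise InputError(f"duplicate atom indices {indices}")
    for i in indices:
        if not (0 <= i < n):
            raise InputError(f"atom index {i} out of range for {n} atoms")


def _coords_of(geometry) -> np.ndarray:
    if isinstance(geometry, Geometry):
        return geometry.coords
    coords = np.asarray(geometry, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise InputError("geometry must be a Geometry or an (n, 3) array")
    return coords


def proton_transfer_coordinate(geometry, o1: int, h: int, o2: int) -> float:
    """delta = d(O1, H) - d(O2, H) in A.

    Negative values place the proton nearer O1; the coordinate is
    antisymmetric under exchange of the two oxygens.
    """
    coords = _coords_of(geometry)
    _check_indices(len(coords), o1, h, o2)
    d1 = float(np.linalg.norm(coords[o1] - coords[h]))
    d2 = float(np.linalg.norm(coords[o2] - coords[h]))
    return d1 - d2


@dataclass
class FreeEnergyProfile:
    """Binned free energy -k_B T ln rho over a sampled coordinate.

    ``free_energy`` is in eV, shifted so its minimum is 0; bins with no
    samples are NaN (undefined), never 0.  ``well_count`` and ``barrier``
    (eV, maximum between the wells relative to the global minimum) are
    filled by :func:`classify_wells`.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    temperature: float
    n_samples: np.ndarray
    well_count: int | None = None
    barrier: float | None = None

    @property
    def kt(self) -> float:
        return KB_EV_K * self.temperature

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.free_energy)


def free_energy_profile(samples, temperature: float = 300.0,
                        n_bins: int = 50, *, padding: float = 0.05,
                        classify: bool = True,
                        noise_threshold: float | None = None) -> FreeEnergyProfile:
    """Free-energy profile F(x) = -k_B T ln rho(x) from sampled values.

    The histogram spans the sampled range padded by ``padding`` (fraction of
    the range) on each side.  Empty bins are marked NaN.  The profile is
    shifted so min F = 0 and, unless ``classify=False``, well count and
    barrier are attached via :func:`classify_wells`.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        raise InputError("empty sample series")
    if temperature <= 0:
        raise InputError("temperature must be > 0")
    lo, hi = samples.min(), samples.max()
    span = hi - lo if hi > lo else max(abs(hi), 1.0)
    edges = np.linspace(lo - padding * span, hi + padding * span, n_bins + 1)
    counts, _ = np.histogram(samples, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    kt = KB_EV_K * temperature
    with np.errstate(divide="ignore"):
        f = np.where(counts > 0, -kt * np.log(counts / counts.sum()), np.nan)
    f = f - np.nanmin(f)
    profile = FreeEnergyProfile(bin_centers=centers, free_energy=f,
                                temperature=temperature, n_samples=counts)
    if classify:
        classify_wells(profile, noise_threshold=noise_threshold)
    return profile


def classify_wells(profile: FreeEnergyProfile,
                   noise_threshold: float | None = None,
                   min_count: int = 25) -> str:
    """Classify a free-energy profile as ``"single"`` or ``"double"`` well.

    The profile is double-well iff its two deepest local minima are
    separated by a maximum exceeding both by more than the noise threshold
    (default 0.4 k_B T -- low enough to detect the thermal-scale barrier of
    a low-barrier hydrogen bond, well above the bin noise of a profile with
    >= 1000 samples).  Sets ``profile.well_count`` and ``profile.barrier``
    (the separating maximum relative to the global minimum; 0 for a single
    well) and returns the classification.

    Candidate minima must sit in bins with at least ``min_count`` samples:
    a bin visited once or twice differs from its neighbours by ~k_B T ln 2
    of pure counting noise, which would otherwise fake shallow wells in the
    profile tails.
    """
    f = profile.free_energy
    if not np.any(np.isfinite(f)):
        raise InputError("free-energy profile has no defined bins")
    if profile.bin_centers.size < 20:
        raise InputError("profile needs >= 20 bins for well classification")
    thr = 0.4 * profile.kt if noise_threshold is None else noise_threshold

    # work on the largest contiguous run of defined bins
    defined = np.isfinite(f)
    runs, start = [], None
    for i, d in enumerate(defined):
        if d and start is None:
            start = i
        elif not d and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(f)))
    s, e = max(runs, key=lambda r: r[1] - r[0])
    seg = f[s:e]

    # local minima (plateau-tolerant at segment ends), statistically supported
    counts = profile.n_samples[s:e]
    minima = []
    for i in range(len(seg)):
        left = seg[i - 1] if i > 0 else np.inf
        right = seg[i + 1] if i < len(seg) - 1 else np.inf
        if seg[i] <= left and seg[i] < right and counts[i] >= min_count:
            minima.append(i)

    well_count, barrier = 1, 0.0
    if len(minima) >= 2:
        order = sorted(minima, key=lambda i: seg[i])
        best = None
        for a in order[:4]:
            for b in order[:4]:
                if a >= b:
                    continue
                sep = seg[a + 1:b].max() if b - a > 1 else -np.inf
                depth = sep - max(seg[a], seg[b])
                if best is None or depth > best[0]:
                    best = (depth, sep)
        if best is not None and best[0] > thr:
            well_count = 2
            barrier = float(best[1] - seg.min())
    profile.well_count = well_count
    profile.barrier = barrier
    return "double" if well_count == 2 else "single"


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10 or b1n < 1e-10:
        raise GeometryError("collinear atoms: torsion undefined")
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b1 / b1n)
    return float(np.degrees(np.arctan2(y, x)))


def ring_deplanarization(geometry, ring_atoms, *, signed: bool = False) -> float:
    """Deplanarization of a five-membered ring, degrees.

    Sum over the five intra-ring torsions tau(i, i+1, i+2, i+3 mod 5); by
    default the absolute values are summed (signed contributions cancel for
    symmetric puckers), so a planar ring gives exactly 0.
    """
    coords = _coords_of(geometry)
    ring = list(ring_atoms)
    if len(ring) != 5:
        raise InputError("ring_atoms must list exactly 5 atoms")
    _check_indices(len(coords), *ring)
    total = 0.0
    for k in range(5):
        idx = [ring[(k + m) % 5] for m in range(4)]
        try:
            tau = dihedral_angle(*(coords[i] for i in idx))
        except GeometryError:
            raise GeometryError("collinear triple in ring torsion",
                                atoms=tuple(idx)) from None
        total += abs(tau) if not signed else tau
    return float(total)


@dataclass
class DistortionSummary:
    """Histograms of the distortion observables (each with unit mass)."""

    co_hist: np.ndarray
    co_edges: np.ndarray
    ring_hist: np.ndarray
    ring_edges: np.ndarray


def bond_length_series(traj, i: int, j: int, n_bins: int = 50):
    """Per-frame distance between atoms i and j of a Cartesian trajectory.

    Returns ``(series, hist, edges)`` where the histogram is normalized to
    unit mass (sum of bin masses = 1).  ``traj`` may be a TrajectoryRecord
    with (n_frames, n_atoms, 3) coords or a bare coordinate array.
    """
    coords = traj.coords if hasattr(traj, "coords") else np.asarray(traj, dtype=float)
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise InputError("expected Cartesian trajectory with shape (n_frames, n_atoms, 3)")
    _check_indices(coords.shape[1], i, j)
    series = np.linalg.norm(coords[:, i] - coords[:, j], axis=1)
    lo, hi = series.min(), series.max()
    if hi == lo:
        lo, hi = lo - 0.01, hi + 0.01
    hist, edges = np.histogram(series, bins=n_bins, range=(lo, hi))
    hist = hist / hist.sum()
    return series, hist, edges


def hb_distances(geometry: Geometry, donor_acceptor=("O", "N"),
                 cutoff: float = 3.2, shb_cutoff: float = SHB_CUTOFF):
    """Enumerate candidate hydrogen-bond donor-acceptor pairs.

    All pairs of heavy atoms whose elements are in ``donor_acceptor``
    (default O and N) with separation <= ``cutoff`` (default 3.2 A), sorted
    by distance ascending.  Each entry is ``((i, j), distance, is_shb)``
    with the short-hydrogen-bond flag set for distances <= ``shb_cutoff``.
    """
    if not isinstance(geometry, Geometry):
        raise InputError("hb_distances needs a Geometry with element labels")
    wanted = {e.capitalize() for e in donor_acceptor}
    heavy = [i for i, e in enumerate(geometry.elements) if e.capitalize() in wanted]
    if not heavy:
        raise InputError(f"no atoms with elements {sorted(wanted)} in geometry")
    out = []
    for a, i in enumerate(heavy):
        for j in heavy[a + 1:]:
            d = geometry.distance(i, j)
            if d <= cutoff:
                out.append(((i, j), d, d <= shb_cutoff))
    out.sort(key=lambda t: t[1])
    return out
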