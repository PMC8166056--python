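"""Two-state model surfaces and classical trajectory sampling.

This module is the synthetic stand-in for ab initio excited-state molecular
dynamics on a hydrogen-bonded dimer.  The model has two nuclear degrees of
freedom:

``delta``
    the proton-transfer coordinate d(O1-H) - d(O2-H) along the hydrogen
    bond (A).  On the ground diabat it moves in a symmetric quartic double
    well whose barrier grows steeply with the donor-acceptor distance
    ``hb_length``: a short hydrogen bond (~2.5 A) has a barrier at or below
    thermal energy, so the proton shuttles freely, while at 3.0-4.5 A the
    proton is locked on one side.

``q``
    a collective distortion coordinate (carbonyl stretch plus ring
    deplanarization, A).  On the excited diabat a linear term pulls ``q``
    away from the Franck-Condon region toward a region where the S1-S0 gap
    closes; this pull is opposed by a harmonic "stiffening" whose force
    constant decreases with ``hb_length``.  A short hydrogen bond therefore
    keeps the excited system far from the gap-closing region, while a long
    one lets it distort toward a near-degeneracy.

The two diabats are mixed by a constant coupling ``c > 0``, so the adiabats
never cross (minimum gap ``2c``).  Nuclei are propagated classically with
velocity Verlet on one adiabat; the canonical ensemble is sampled with the
stochastic velocity-rescaling thermostat.  Every frame carries the adiabatic
energies, the analytic nonadiabatic coupling sigma = d(theta)/dt obtained by
chain rule from the diabatic-to-adiabatic mixing angle, and a surrogate
oscillator strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import AMU_A2_FS2_TO_EV, KB_EV_K
from .errors import ConfigurationError, ParameterError, PropagationError

__all__ = [
    "SurfaceParams",
    "ModelSurface",
    "Restraint",
    "TrajectoryRecord",
    "build_surface",
    "sample_ground_trajectory",
    "run_excited_trajectory",
    "analytic_nac",
]

HB_RANGE = (2.4, 5.0)
HB_REF = 2.5  # A, the natural short-hydrogen-bond donor-acceptor distance

COORD_LABELS = ("delta", "q")


@dataclass(frozen=True)
class SurfaceParams:
    """Configuration of the two-diabat model surface.

    Energies in eV, lengths in A, force constants in eV/A^2.  The defaults
    place the natural short hydrogen bond (hb_length 2.5 A) in the regime
    the study describes: proton-transfer barrier of order k_B T at 300 K,
    vertical gap near 3 eV, and an excited-state distortion minimum far
    from the gap-closing region.
    """

    #: double-well minima at delta = +/- well_position
    well_position: float = 0.35
    #: ground-state proton-transfer barrier at hb_length = HB_REF (eV)
    barrier_shb: float = 0.020
    #: saturation barrier for long hydrogen bonds (eV); the barrier rises
    #: from barrier_shb toward barrier_shb + barrier_saturation
    barrier_saturation: float = 1.0
    #: length scale of the barrier rise with hb_length (A)
    barrier_width: float = 0.4
    #: ground-state distortion force constant (eV/A^2)
    k_ground_q: float = 1.0
    #: vertical excitation energy at the Franck-Condon point (eV)
    vertical_gap: float = 3.0
    #: excited-diabat curvature along delta (eV/A^2)
    k_excited_delta: float = 1.0
    #: linear gap-closing pull on q in the excited diabat (eV/A)
    gap_slope: float = 1.3
    #: excited-state stiffening force constant at hb_length = HB_REF (eV/A^2)
    stiffening_shb: float = 3.6
    #: exponential decay rate of the stiffening with hb_length (1/A)
    stiffening_rate: float = 0.75
    #: constant diabatic coupling (eV); must be > 0
    coupling: float = 0.02
    #: peak oscillator strength of the S0->S1 transition (dimensionless)
    osc_strength_0: float = 0.10
    #: effective masses of (delta, q) in amu
    masses: tuple[float, float] = (1.0, 1.0)


@dataclass(frozen=True)
class ModelSurface:
    """Two-diabat Hamiltonian at a fixed donor-acceptor distance.

    Diabat 1 (ground character):  a*delta^4 - b*delta^2 + k_q/2 * q^2
    Diabat 2 (excited character): E_v + k_e/2 * delta^2 - g*q + s/2 * q^2

    with constant off-diagonal coupling c.  ``a``/``b`` are set from the
    barrier height and well position, the barrier growing exponentially in
    ``hb_length``; the stiffening ``s`` decays exponentially in
    ``hb_length``.
    """

    hb_length: float
    params: SurfaceParams
    coordinate_labels: tuple[str, str] = COORD_LABELS

    # -- hb-dependent coefficients ------------------------------------
    @property
    def barrier_height_target(self) -> float:
        """Designed diabatic double-well barrier (eV) at this hb_length.

        Thermal (~k_B T) at the natural short bond, rising steeply and
        saturating near 1 eV for stretched bonds where the proton is locked
        on the donor -- the qualitative shape of proton-transfer barriers
        versus donor-acceptor distance.
        """
        p = self.params
        x = (self.hb_length - HB_REF) / p.barrier_width
        return p.barrier_shb + p.barrier_saturation * (1.0 - np.exp(-x * x))

    @property
    def stiffening(self) -> float:
        """Excited-state distortion force constant s(hb_length), eV/A^2."""
        p = self.params
        return p.stiffening_shb * np.exp(-p.stiffening_rate * (self.hb_length - HB_REF))

    @property
    def coupling(self) -> float:
        return self.params.coupling

    @property
    def masses(self) -> np.ndarray:
        return np.asarray(self.params.masses, dtype=float)

    def _quartic_coeffs(self) -> tuple[float, float]:
        # V = a d^4 - b d^2 with minima at +/-d0 and depth b^2/(4a) = B
        B = self.barrier_height_target
        d0 = self.params.well_position
        b = 2.0 * B / d0**2
        a = B / d0**4
        return a, b

    # -- diabats and their gradients ----------------------------------
    def diabat_1(self, delta, q):
        a, b = self._quartic_coeffs()
        return a * np.asarray(delta) ** 4 - b * np.asarray(delta) ** 2 \
            + 0.5 * self.params.k_ground_q * np.asarray(q) ** 2

    def diabat_2(self, delta, q):
        p = self.params
        return (p.vertical_gap + 0.5 * p.k_excited_delta * np.asarray(delta) ** 2
                - p.gap_slope * np.asarray(q) + 0.5 * self.stiffening * np.asarray(q) ** 2)

    def grad_diabat_1(self, delta, q):
        a, b = self._quartic_coeffs()
        return np.stack([4 * a * np.asarray(delta) ** 3 - 2 * b * np.asarray(delta),
                         self.params.k_ground_q * np.asarray(q)], axis=-1)

    def grad_diabat_2(self, delta, q):
        p = self.params
        return np.stack([p.k_excited_delta * np.asarray(delta),
                         -p.gap_slope + self.stiffening * np.asarray(q)], axis=-1)

    # -- adiabats -------------------------------------------------------
    def gap(self, delta, q):
        """Adiabatic S1-S0 gap, >= 2c everywhere."""
        dv = self.diabat_1(delta, q) - self.diabat_2(delta, q)
        return np.sqrt(dv**2 + 4.0 * self.coupling**2)

    def adiabatic_energies(self, delta, q):
        """(E_S0, E_S1) at the given geometry."""
        v1 = self.diabat_1(delta, q)
        v2 = self.diabat_2(delta, q)
        mean = 0.5 * (v1 + v2)
        half_gap = 0.5 * np.sqrt((v1 - v2) ** 2 + 4.0 * self.coupling**2)
        return mean - half_gap, mean + half_gap

    def adiabatic_gradient(self, delta, q, state: int):
        """Gradient of adiabat ``state`` (0 or 1) wrt (delta, q), eV/A."""
        v1 = self.diabat_1(delta, q)
        v2 = self.diabat_2(delta, q)
        g1 = self.grad_diabat_1(delta, q)
        g2 = self.grad_diabat_2(delta, q)
        dv = v1 - v2
        gap = np.sqrt(dv**2 + 4.0 * self.coupling**2)
        sign = -1.0 if state == 0 else 1.0
        return 0.5 * (g1 + g2) + sign * 0.5 * dv[..., None] * (g1 - g2) / gap[..., None]

    def mixing_angle(self, delta, q):
        """Diabatic->adiabatic mixing angle theta = atan2(2c, V1-V2)/2."""
        dv = self.diabat_1(delta, q) - self.diabat_2(delta, q)
        return 0.5 * np.arctan2(2.0 * self.coupling, dv)

    def grad_mixing_angle(self, delta, q):
        """Chain-rule gradient of theta wrt (delta, q), rad/A."""
        dv = self.diabat_1(delta, q) - self.diabat_2(delta, q)
        ddv = self.grad_diabat_1(delta, q) - self.grad_diabat_2(delta, q)
        # d/dDV [atan2(2c, DV)/2] = -c / (DV^2 + 4c^2)
        return -self.coupling * ddv / (dv**2 + 4.0 * self.coupling**2)[..., None]

    def oscillator_strength(self, delta, q):
        """Surrogate oscillator strength: largest at the vertical gap, fading
        as the gap closes (the transition borrows ground-state character near
        the degeneracy)."""
        g = self.gap(delta, q)
        p = self.params
        return p.osc_strength_0 * np.clip(g / p.vertical_gap, 0.0, None)

    # -- scans ----------------------------------------------------------
    def ground_barrier(self, n_grid: int = 2001) -> float:
        """Proton-transfer barrier of the ground adiabat along delta at q=0,
        from a dense grid scan: max between the minima minus the minimum."""
        d0 = self.params.well_position
        grid = np.linspace(-1.6 * d0, 1.6 * d0, n_grid)
        e0, _ = self.adiabatic_energies(grid, np.zeros_like(grid))
        i_min = int(np.argmin(e0))
        # the scan is symmetric; barrier = central max relative to minimum
        inner = e0[min(i_min, n_grid - 1 - i_min): max(i_min, n_grid - 1 - i_min) + 1]
        return float(inner.max() - e0[i_min])

    def min_excited_gap(self, q_max: float = 4.0, n_grid: int = 4001) -> float:
        """Minimum S1-S0 gap along q at delta=0 (grid scan over [0, q_max])."""
        grid = np.linspace(0.0, q_max, n_grid)
        return float(np.min(self.gap(np.zeros_like(grid), grid)))


def build_surface(hb_length: float, params: SurfaceParams | None = None) -> ModelSurface:
    """Build the two-state model surface for a donor-acceptor distance.

    Parameters
    ----------
    hb_length : float
        O...O donor-acceptor distance in A, within [2.4, 5.0].
    params : SurfaceParams, optional
        Surface coefficients; defaults reproduce the designed short-bond
        regime (thermal barrier at 2.5 A, ~3 eV vertical gap).

    Raises
    ------
    ParameterError
        If ``hb_length`` is outside the supported range or the diabatic
        coupling is not strictly positive.
    """
    if not (HB_RANGE[0] <= hb_length <= HB_RANGE[1]):
        raise ParameterError(
            f"hb_length {hb_length} A outside supported range {HB_RANGE}")
    params = params or SurfaceParams()
    if params.coupling <= 0:
        raise ParameterError("diabatic coupling must be > 0 (true crossings unsupported)")
    return ModelSurface(hb_length=float(hb_length), params=params)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Restraint:
    """Harmonic restraint k/2 (x - target)^2 on one model coordinate."""

    coordinate: str
    target: float
    force_constant: float = 10.0  # eV/A^2

    def index(self, labels=COORD_LABELS) -> int:
        try:
            return labels.index(self.coordinate)
        except ValueError:
            raise ConfigurationError(
                f"unknown restraint coordinate {self.coordinate!r}; "
                f"known: {list(labels)}") from None


@dataclass
class TrajectoryRecord:
    """Time-ordered nuclear/electronic frames at a fixed step.

    ``coords``/``velocities`` have shape (n_frames, n_dof) for model
    trajectories (n_dof = 2: delta, q) or (n_frames, n_atoms, 3) for
    Cartesian trajectories.  Electronic quantities are per frame: adiabatic
    energies ``e_s0``/``e_s1`` (eV), scalar nonadiabatic coupling ``sigma``
    (1/fs), and oscillator strength ``osc_strength``.
    """

    dt: float
    times: np.ndarray
    coords: np.ndarray
    velocities: np.ndarray
    e_s0: np.ndarray
    e_s1: np.ndarray
    sigma: np.ndarray
    osc_strength: np.ndarray
    active_state: str = "S0"
    seed: int | None = None
    restraints: tuple[Restraint, ...] = ()
    labels: tuple[str, ...] = COORD_LABELS

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        for name in ("e_s0", "e_s1", "sigma", "osc_strength"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def __len__(self) -> int:
        return len(self.times)

    @property
    def gap(self) -> np.ndarray:
        return self.e_s1 - self.e_s0

    def frame(self, i: int) -> dict:
        return {
            "time": self.times[i], "coords": self.coords[i],
            "velocities": self.velocities[i], "e_s0": self.e_s0[i],
            "e_s1": self.e_s1[i], "sigma": self.sigma[i],
            "osc_strength": self.osc_strength[i],
        }


def _maxwell_boltzmann_velocities(rng, masses, temperature):
    sigma_v = np.sqrt(KB_EV_K * temperature / (masses * AMU_A2_FS2_TO_EV))
    return rng.normal(0.0, sigma_v)


def _svr_rescale(rng, kinetic, n_dof, temperature, dt, tau):
    """Stochastic velocity-rescaling factor (canonical sampling thermostat).

    Returns alpha such that v <- alpha*v keeps the kinetic energy on the
    canonical chi^2 distribution with relaxation time tau.
    """
    if kinetic <= 0.0:
        # degenerate start: draw a fresh canonical kinetic energy next step
        return 1.0
    kt = KB_EV_K * temperature
    c = np.exp(-dt / tau)
    r1 = rng.normal()
    # sum of squares of (n_dof - 1) further Gaussians
    rest = rng.chisquare(n_dof - 1) if n_dof > 1 else 0.0
    target = kt / 2.0
    alpha2 = (c + (1.0 - c) * target * (r1**2 + rest) / kinetic
              + 2.0 * r1 * np.sqrt(c * (1.0 - c) * target / kinetic))
    return np.sqrt(max(alpha2, 0.0))


def _total_gradient(surface, pos, state, restraints):
    grad = surface.adiabatic_gradient(pos[0], pos[1], state)
    for r in restraints:
        i = r.index(surface.coordinate_labels)
        grad = grad.copy()
        grad[i] += r.force_constant * (pos[i] - r.target)
    return grad


def _propagate(surface, pos, vel, *, state, n_steps, dt, temperature, seed,
               thermostat="svr", tau=50.0, restraints=(), active_label="S0"):
    """Velocity-Verlet propagation on one adiabat with optional thermostat."""
    restraints = tuple(restraints)
    for r in restraints:
        r.index(surface.coordinate_labels)  # validate early
    rng = np.random.default_rng(seed)
    masses = surface.masses
    n_dof = masses.size

    pos = np.array(pos, dtype=float)
    vel = np.array(vel, dtype=float)
    n_frames = n_steps + 1
    coords = np.empty((n_frames, n_dof))
    vels = np.empty((n_frames, n_dof))

    grad = _total_gradient(surface, pos, state, restraints)
    acc = -grad / (masses * AMU_A2_FS2_TO_EV)
    coords[0], vels[0] = pos, vel

    for step in range(1, n_frames):
        pos = pos + vel * dt + 0.5 * acc * dt * dt
        grad = _total_gradient(surface, pos, state, restraints)
        if not np.all(np.isfinite(grad)):
            raise PropagationError("non-finite forces", frame_index=step)
        new_acc = -grad / (masses * AMU_A2_FS2_TO_EV)
        vel = vel + 0.5 * (acc + new_acc) * dt
        acc = new_acc
        if thermostat == "svr" and temperature > 0:
            kinetic = 0.5 * float(np.sum(masses * vel**2)) * AMU_A2_FS2_TO_EV
            vel = vel * _svr_rescale(rng, kinetic, n_dof, temperature, dt, tau)
        elif thermostat == "langevin" and temperature > 0:
            gamma = 1.0 / tau
            sig = np.sqrt(2.0 * gamma * KB_EV_K * temperature * dt
                          / (masses * AMU_A2_FS2_TO_EV))
            vel = vel - gamma * vel * dt + rng.normal(0.0, sig)
        coords[step], vels[step] = pos, vel

    times = np.arange(n_frames) * dt
    delta, q = coords[:, 0], coords[:, 1]
    e0, e1 = surface.adiabatic_energies(delta, q)
    grad_theta = surface.grad_mixing_angle(delta, q)
    sigma = np.einsum("ij,ij->i", grad_theta, vels)
    osc = surface.oscillator_strength(delta, q)
    return TrajectoryRecord(
        dt=dt, times=times, coords=coords, velocities=vels,
        e_s0=e0, e_s1=e1, sigma=sigma, osc_strength=osc,
        active_state=active_label, seed=seed, restraints=restraints,
        labels=surface.coordinate_labels)


def sample_ground_trajectory(surface: ModelSurface, temperature: float, dt: float,
                             n_steps: int, seed: int, *,
                             init_coords=None, init_velocities=None,
                             thermostat: str | None = "svr", tau: float = 50.0,
                             restraints=()) -> TrajectoryRecord:
    """Thermostatted sampling of the ground adiabat.

    Starts (by default) at one double-well minimum with Maxwell-Boltzmann
    velocities and propagates ``n_steps`` velocity-Verlet steps under the
    stochastic velocity-rescaling thermostat, so long runs sample the
    canonical ensemble at ``temperature``.
    """
    if temperature <= 0:
        raise ParameterError("temperature must be > 0")
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    rng = np.random.default_rng(seed)
    if init_coords is None:
        init_coords = np.array([surface.params.well_position, 0.0])
    if init_velocities is None:
        init_velocities = _maxwell_boltzmann_velocities(rng, surface.masses, temperature)
    return _propagate(surface, init_coords, init_velocities, state=0,
                      n_steps=n_steps, dt=dt, temperature=temperature,
                      seed=int(rng.integers(2**31)), thermostat=thermostat,
                      tau=tau, restraints=restraints, active_label="S0")


def run_excited_trajectory(surface: ModelSurface, init: dict, duration: float,
                           dt: float, *, restraints=(), seed: int = 0,
                           temperature: float = 300.0,
                           thermostat: str | None = "svr",
                           tau: float = 50.0) -> TrajectoryRecord:
    """Propagate nuclei on the S1 adiabat after a vertical excitation.

    ``init`` is a frame dict from a ground trajectory (``TrajectoryRecord
    .frame``); positions and velocities are carried over unchanged (vertical
    excitation).  The system stays on S1 for the full duration -- no surface
    switches -- and every frame carries the adiabatic energies, the analytic
    nonadiabatic coupling and the surrogate oscillator strength, which is
    what the decay-probability accumulation consumes.
    """
    n_steps = duration / dt
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ConfigurationError(f"duration {duration} not an integral number of steps of {dt}")
    return _propagate(surface, init["coords"], init["velocities"], state=1,
                      n_steps=int(round(n_steps)), dt=dt, temperature=temperature,
                      seed=seed, thermostat=thermostat, tau=tau,
                      restraints=restraints, active_label="S1")


def analytic_nac(surface: ModelSurface, frame: dict) -> float:
    """Scalar nonadiabatic coupling sigma_S0,S1 = d(theta)/dt (1/fs).

    theta is the diabatic->adiabatic mixing angle atan2(2c, V1-V2)/2;
    the time derivative is evaluated by chain rule grad(theta) . dR/dt, so
    the coupling vanishes for frozen nuclei and is linear in the velocity.
    sigma_S1,S0 = -sigma_S0,S1.
    """
    pos = np.asarray(frame["coords"], dtype=float)
    vel = np.asarray(frame["velocities"], dtype=float)
    grad_theta = surface.grad_mixing_angle(pos[0], pos[1])
    return float(np.dot(grad_theta, vel))
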