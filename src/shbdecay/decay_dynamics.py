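"""Electronic amplitudes, per-step hopping probabilities and accumulated decay.

Along a classical trajectory that stays on S1, the two-state electronic
amplitudes C_S0, C_S1 obey

    i hbar dC_i/dt = C_i w_i - i hbar sum_j C_j sigma_ij,

with w_i the adiabatic state energies and sigma the scalar nonadiabatic
coupling (sigma_10 = -sigma_01, sigma_ii = 0).  The generator is
anti-Hermitian, so the propagation conserves |C_S0|^2 + |C_S1|^2 exactly;
we integrate it with a norm-preserving fourth-order Magnus scheme on the
linearly interpolated frame data, in closed form for the 2x2 exponentials.

From the amplitudes, the fewest-switches per-step hopping probability out
of the occupied S1 state is

    NRP(t) = clamp( -2 int_t^{t+dt} Re[C_S1 C_S0* sigma_S0,S1] dt' / |C_S1|^2 ),

and the survival-weighted hazard and its accumulation follow the discrete
recursion

    P(t_n)   = (1 - ANRP_n) * NRP_n
    ANRP_{n+1} = ANRP_n + P(t_n),     ANRP_0 = 0,

equivalently ANRP_n = 1 - prod_k (1 - NRP_k): the total probability that a
surface hop would have occurred by time t had hops been allowed.  A small
ANRP at 1 ps means a long-lived S1 state and a high fluorescence likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import HBAR_EV_FS
from .errors import InputError, PropagationError
from .model_system import (ModelSurface, SurfaceParams, TrajectoryRecord,
                           build_surface, run_excited_trajectory,
                           sample_ground_trajectory)

__all__ = [
    "AmplitudeState", "AmplitudeSeries", "DecayProfile", "EnsembleDecay",
    "propagate_amplitudes", "step_nrp", "nrp_series", "accumulate_decay",
    "decay_profile_for_trajectory", "run_condition",
    "linear_sweep_trajectory", "landau_zener_probability",
]

_NORM_TOL = 1e-8
_POP_FLOOR = 1e-12


@dataclass(frozen=True)
class AmplitudeState:
    """Complex electronic amplitudes (C_S0, C_S1); must be normalized."""

    c_s0: complex = 0.0 + 0.0j
    c_s1: complex = 1.0 + 0.0j

    def as_vector(self) -> np.ndarray:
        return np.array([self.c_s0, self.c_s1], dtype=complex)

    def validate(self):
        norm = abs(self.c_s0) ** 2 + abs(self.c_s1) ** 2
        if abs(norm - 1.0) > 1e-10:
            raise InputError(f"initial amplitudes not normalized: |C|^2 = {norm}")


@dataclass
class AmplitudeSeries:
    """Amplitudes on the electronic substep grid of one trajectory.

    ``times`` has (n_frames-1)*substeps + 1 points; ``c`` is the complex
    (n_times, 2) amplitude array; ``sigma`` the coupling interpolated on the
    same grid; ``substeps`` the number of electronic substeps per nuclear step.
    """

    times: np.ndarray
    c: np.ndarray
    sigma: np.ndarray
    substeps: int

    @property
    def populations(self) -> np.ndarray:
        return np.abs(self.c) ** 2

    @property
    def norm(self) -> np.ndarray:
        return self.populations.sum(axis=1)

    def at_frames(self) -> np.ndarray:
        """Amplitudes subsampled at the nuclear frame times."""
        return self.c[:: self.substeps]


def _expm2(m: np.ndarray) -> np.ndarray:
    """Closed-form exponential of one 2x2 complex matrix."""
    mu = 0.5 * (m[0, 0] + m[1, 1])
    b = m - mu * np.eye(2)
    lam2 = -(b[0, 0] * b[1, 1] - b[0, 1] * b[1, 0])  # -det(B); B^2 = lam2 * I
    lam = np.sqrt(lam2.astype(complex) if isinstance(lam2, np.ndarray) else complex(lam2))
    if abs(lam) < 1e-30:
        f0, f1 = 1.0, 1.0
    else:
        f0, f1 = np.cosh(lam), np.sinh(lam) / lam
    return np.exp(mu) * (f0 * np.eye(2) + f1 * b)


def _generator(w0, w1, sig):
    """dC/dt = M C for the two-state equation, M anti-Hermitian."""
    return np.array([[-1j * w0 / HBAR_EV_FS, -sig],
                     [sig, -1j * w1 / HBAR_EV_FS]], dtype=complex)


def propagate_amplitudes(traj: TrajectoryRecord, init: AmplitudeState | None = None,
                         substeps: int = 10) -> AmplitudeSeries:
    """Integrate the two-state amplitude equation along a trajectory.

    Frame energies and couplings are interpolated linearly within each
    nuclear step; each electronic substep applies a fourth-order Magnus
    propagator (two Gauss collocation points) in closed 2x2 form, which is
    exactly norm-preserving.

    Parameters
    ----------
    traj : TrajectoryRecord
        Must carry ``e_s0``, ``e_s1`` and ``sigma`` per frame.
    init : AmplitudeState, optional
        Normalized initial amplitudes; default is the vertically excited
        state (C_S1 = 1).
    substeps : int
        Electronic substeps per nuclear step; coupling spikes near small
        gaps need a few substeps even though the scheme is fourth order.
    """
    init = init or AmplitudeState()
    init.validate()
    n_frames = len(traj)
    if n_frames < 2:
        raise InputError("trajectory needs at least two frames")
    dt = traj.dt
    h = dt / substeps

    # fine grid and linear interpolation of the electronic data
    n_sub = (n_frames - 1) * substeps
    t_fine = traj.times[0] + np.arange(n_sub + 1) * h
    w0 = np.interp(t_fine, traj.times, traj.e_s0)
    w1 = np.interp(t_fine, traj.times, traj.e_s1)
    sg = np.interp(t_fine, traj.times, traj.sigma)

    # Gauss points of each substep for the 4th-order Magnus propagator
    gauss_off = 0.5 * np.array([1.0 - 1.0 / np.sqrt(3.0), 1.0 + 1.0 / np.sqrt(3.0)])
    t_starts = t_fine[:-1]
    tg1 = t_starts + gauss_off[0] * h
    tg2 = t_starts + gauss_off[1] * h

    def gen_batch(ts):
        a0 = np.interp(ts, traj.times, traj.e_s0) * (-1j / HBAR_EV_FS)
        a1 = np.interp(ts, traj.times, traj.e_s1) * (-1j / HBAR_EV_FS)
        s = np.interp(ts, traj.times, traj.sigma)
        m = np.zeros((ts.size, 2, 2), dtype=complex)
        m[:, 0, 0] = a0
        m[:, 1, 1] = a1
        m[:, 0, 1] = -s
        m[:, 1, 0] = s
        return m

    m1 = gen_batch(tg1)
    m2 = gen_batch(tg2)
    comm = m1 @ m2 - m2 @ m1
    omega = 0.5 * h * (m1 + m2) - (np.sqrt(3.0) / 12.0) * h * h * comm

    # batched closed-form 2x2 exponential of the traceless-split Magnus term
    mu = 0.5 * (omega[:, 0, 0] + omega[:, 1, 1])
    b = omega - mu[:, None, None] * np.eye(2)
    lam = np.sqrt((-(b[:, 0, 0] * b[:, 1, 1] - b[:, 0, 1] * b[:, 1, 0])).astype(complex))
    small = np.abs(lam) < 1e-30
    lam_safe = np.where(small, 1.0, lam)
    f0 = np.where(small, 1.0, np.cosh(lam_safe))
    f1 = np.where(small, 1.0, np.sinh(lam_safe) / lam_safe)
    props = np.exp(mu)[:, None, None] * (
        f0[:, None, None] * np.eye(2) + f1[:, None, None] * b)

    c = np.empty((n_sub + 1, 2), dtype=complex)
    c[0] = init.as_vector()
    vec = c[0]
    for k in range(n_sub):
        vec = props[k] @ vec
        c[k + 1] = vec

    norm = np.abs(c[:, 0]) ** 2 + np.abs(c[:, 1]) ** 2
    drift = float(np.max(np.abs(norm - 1.0)))
    if drift > 1e-6:
        raise PropagationError(f"amplitude norm drift {drift:.2e} exceeds 1e-6")
    return AmplitudeSeries(times=t_fine, c=c, sigma=sg, substeps=substeps)


def step_nrp(amplitudes: np.ndarray, sigma: np.ndarray, dt_sub: float, *,
             normalize_by: str = "s1", clamp: bool = True) -> float:
    """Fewest-switches hopping probability S1->S0 over one nuclear step.

    ``amplitudes`` (n, 2) and ``sigma`` (n,) sample the step interval
    [t, t+dt] at spacing ``dt_sub``; the flux integral is evaluated by the
    trapezoid rule and normalized by the occupied-state population at the
    start of the step.  The raw value is clamped to [0, 1]: a negative flux
    means population flowing back into S1 and yields no hop.

    ``normalize_by`` selects the population in the denominator: ``"s1"``
    (the occupied state, standard fewest-switches) or ``"s0"``.
    """
    amplitudes = np.asarray(amplitudes)
    sigma = np.asarray(sigma)
    # d|C_S1|^2/dt = +2 Re[C_S1* C_S0 sigma_01]; flux out of S1 is its negative
    integrand = -2.0 * np.real(amplitudes[:, 1] * np.conj(amplitudes[:, 0]) * sigma)
    flux = float(np.trapezoid(integrand, dx=dt_sub))
    col = 1 if normalize_by == "s1" else 0
    pop = float(np.abs(amplitudes[0, col]) ** 2)
    if pop < _POP_FLOOR:
        raise PropagationError(f"population of normalization state below {_POP_FLOOR}")
    raw = flux / pop
    if clamp:
        return min(max(raw, 0.0), 1.0)
    return raw


def nrp_series(series: AmplitudeSeries, *, normalize_by: str = "s1",
               clamp: bool = True) -> np.ndarray:
    """Per-nuclear-step NRP along a propagated amplitude series."""
    n = series.substeps
    n_steps = (len(series.times) - 1) // n
    dt_sub = series.times[1] - series.times[0]
    out = np.empty(n_steps)
    for k in range(n_steps):
        sl = slice(k * n, (k + 1) * n + 1)
        out[k] = step_nrp(series.c[sl], series.sigma[sl], dt_sub,
                          normalize_by=normalize_by, clamp=clamp)
    return out


@dataclass
class DecayProfile:
    """Per-step NRP, survival-weighted hazard and accumulated decay.

    ``times`` are the n+1 frame times; ``nrp`` and ``hazard`` have length n
    (one value per step); ``anrp`` has length n+1 with anrp[0] = 0, and
    hazard[k] = (1 - anrp[k]) * nrp[k].
    """

    times: np.ndarray
    nrp: np.ndarray
    hazard: np.ndarray
    anrp: np.ndarray
    replica_id: int | None = None

    @property
    def final_anrp(self) -> float:
        return float(self.anrp[-1])


def accumulate_decay(nrp, times=None, dt: float = 1.0,
                     replica_id: int | None = None) -> DecayProfile:
    """Accumulate per-step hopping probabilities into an ANRP profile.

    Applies the survival recursion ANRP_{n+1} = ANRP_n + (1-ANRP_n)*NRP_n,
    which equals the closed form 1 - prod_k (1-NRP_k).  The result is
    bounded in [0, 1] and non-decreasing by construction.
    """
    nrp = np.asarray(nrp, dtype=float)
    if nrp.ndim != 1 or nrp.size == 0:
        raise InputError("nrp must be a non-empty 1-D series")
    if np.any((nrp < 0.0) | (nrp > 1.0)):
        raise InputError("nrp values must lie in [0, 1]")
    n = nrp.size
    if times is None:
        times = np.arange(n + 1) * dt
    times = np.asarray(times, dtype=float)
    if times.size != n + 1:
        raise InputError("times must have len(nrp)+1 entries")
    survival = np.concatenate([[1.0], np.cumprod(1.0 - nrp)])
    anrp = 1.0 - survival
    hazard = survival[:-1] * nrp
    return DecayProfile(times=times, nrp=nrp, hazard=hazard, anrp=anrp,
                        replica_id=replica_id)


def decay_profile_for_trajectory(traj: TrajectoryRecord,
                                 init: AmplitudeState | None = None,
                                 substeps: int = 10, *,
                                 normalize_by: str = "s1", clamp: bool = True,
                                 replica_id: int | None = None) -> DecayProfile:
    """Propagate amplitudes along ``traj`` and accumulate the decay profile."""
    series = propagate_amplitudes(traj, init=init, substeps=substeps)
    nrp = nrp_series(series, normalize_by=normalize_by, clamp=clamp)
    return accumulate_decay(nrp, times=traj.times, replica_id=replica_id)


@dataclass
class EnsembleDecay:
    """Replica ensemble of decay profiles for one hydrogen-bond condition."""

    label: str
    hb_length: float
    profiles: list[DecayProfile] = field(default_factory=list)

    @property
    def times(self) -> np.ndarray:
        return self.profiles[0].times

    @property
    def anrp_matrix(self) -> np.ndarray:
        return np.stack([p.anrp for p in self.profiles])

    @property
    def mean_anrp(self) -> np.ndarray:
        """Pointwise mean of the replica ANRP curves."""
        return self.anrp_matrix.mean(axis=0)

    @property
    def anrp_spread(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.anrp_matrix
        return m.min(axis=0), m.max(axis=0)

    @property
    def final_mean_anrp(self) -> float:
        return float(self.mean_anrp[-1])


def run_condition(hb_length: float, n_replicas: int = 5, *,
                  ground_equilibration: float = 3000.0,
                  excited_duration: float = 1000.0, dt: float = 0.5,
                  temperature: float = 300.0, seed_base: int = 0,
                  params: SurfaceParams | None = None,
                  surface: ModelSurface | None = None,
                  substeps: int = 10, normalize_by: str = "s1",
                  label: str | None = None) -> EnsembleDecay:
    """Full replica protocol for one hydrogen-bond condition.

    For each replica r (seed ``seed_base + r``): thermostatted ground-state
    equilibration (default 3 ps at 300 K, 0.5 fs steps), vertical excitation
    of the final frame to S1 (amplitudes reset to C_S1 = 1), excited-state
    propagation (default 1 ps) with no surface switches, amplitude
    integration and ANRP accumulation.  Replica failures abort the run.
    """
    if n_replicas < 1:
        raise InputError("n_replicas must be >= 1")
    surf = surface or build_surface(hb_length, params)
    ens = EnsembleDecay(label=label or f"hb-{hb_length:g}A", hb_length=hb_length)
    n_equil = int(round(ground_equilibration / dt))
    for r in range(n_replicas):
        seed = seed_base + r
        ground = sample_ground_trajectory(surf, temperature, dt, n_equil, seed)
        excited = run_excited_trajectory(surf, ground.frame(-1), excited_duration,
                                         dt, seed=seed + 10_000,
                                         temperature=temperature)
        profile = decay_profile_for_trajectory(excited, substeps=substeps,
                                               normalize_by=normalize_by,
                                               replica_id=r)
        ens.profiles.append(profile)
    return ens


# ---------------------------------------------------------------------------
# Landau-Zener reference problem
# ---------------------------------------------------------------------------

def linear_sweep_trajectory(coupling: float, sweep_rate: float, dt: float,
                            span: float) -> TrajectoryRecord:
    """Single avoided crossing traversed at constant speed.

    The diabatic gap sweeps linearly, DV(t) = sweep_rate * t for
    t in [-span, span] (eV, fs), with constant coupling c.  Adiabatic
    energies are +/- sqrt(DV^2 + 4c^2)/2 and the analytic coupling is
    sigma = -c * sweep_rate / (DV^2 + 4c^2).  Used to check the amplitude
    dynamics against the Landau-Zener closed form.
    """
    times = np.arange(-span, span + 0.5 * dt, dt)
    dv = sweep_rate * times
    gap = np.sqrt(dv**2 + 4.0 * coupling**2)
    sigma = -coupling * sweep_rate / (dv**2 + 4.0 * coupling**2)
    zeros = np.zeros((times.size, 1))
    return TrajectoryRecord(dt=dt, times=times, coords=zeros, velocities=zeros,
                            e_s0=-0.5 * gap, e_s1=0.5 * gap, sigma=sigma,
                            osc_strength=np.zeros_like(times),
                            active_state="S1", labels=("sweep",))


def landau_zener_probability(coupling: float, sweep_rate: float) -> float:
    """Closed-form probability of a nonadiabatic (diabat-following)
    transition for a linear sweep: exp(-2 pi c^2 / (hbar * |dDV/dt|))."""
    return float(np.exp(-2.0 * np.pi * coupling**2 / (HBAR_EV_FS * abs(sweep_rate))))
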