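"""Cartesian embedding of model trajectories on a toy molecule.

The two model coordinates (proton-transfer delta, distortion q) are mapped
onto the 3-D geometry of a minimal analog of a cyclized-glutamine dimer
fragment: a five-membered ring (four carbons and one nitrogen) attached
through a carboxyl carbon to an O1-H...O2 hydrogen-bond bridge.

- delta places the shared proton on the O1-O2 axis so that
  d(O1,H) - d(O2,H) = delta exactly;
- q stretches the carboxyl C=O bond (r = r0 + co_per_q * q) and lifts one
  ring atom out of the ring plane (h = pucker_per_q * q), so excited-state
  distortion shows up as a red-shifted C=O histogram and a growing ring
  deplanarization -- the two descriptors tracked downstream.

The embedding gives geometric descriptors something real to chew on; it is
a visualization/bookkeeping layer, not extra dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import Geometry
from .errors import InputError
from .model_system import TrajectoryRecord

__all__ = ["ToyMoleculeParams", "ELEMENTS", "O2_INDEX", "H_INDEX", "O1_INDEX",
           "CARBOXYL_C_INDEX", "RING_ATOMS", "toy_geometry", "embed_trajectory"]

#: atom order of the toy molecule
ELEMENTS = ("O", "H", "O", "C", "C", "C", "C", "C", "N")
O2_INDEX, H_INDEX, O1_INDEX, CARBOXYL_C_INDEX = 0, 1, 2, 3
RING_ATOMS = (4, 5, 6, 7, 8)
#: (i, j) of the carboxyl C=O bond
CO_BOND = (CARBOXYL_C_INDEX, O1_INDEX)


@dataclass(frozen=True)
class ToyMoleculeParams:
    """Geometric constants of the embedding (lengths in A)."""

    co_rest_length: float = 1.23     # carboxyl C=O at q = 0
    co_per_q: float = 0.09           # C=O stretch per unit q
    pucker_per_q: float = 0.45       # out-of-plane ring lift per unit q
    ring_bond: float = 1.50          # ring edge length
    ring_link: float = 1.50          # carboxyl C -- ring bond
    pucker_atom: int = 6             # which atom of RING_ATOMS plane to lift


def _base_coords(hb_length: float, delta: float, q: float,
                 p: ToyMoleculeParams) -> np.ndarray:
    if not (abs(delta) < hb_length):
        raise InputError(f"|delta| = {abs(delta)} must be < hb_length {hb_length}")
    coords = np.zeros((len(ELEMENTS), 3))
    # O2 at origin, O1 on the +x axis at the donor-acceptor distance
    coords[O1_INDEX] = (hb_length, 0.0, 0.0)
    # proton on the axis with d(O1,H) - d(O2,H) = delta
    coords[H_INDEX] = (0.5 * (hb_length - delta), 0.0, 0.0)
    r_co = p.co_rest_length + p.co_per_q * q
    coords[CARBOXYL_C_INDEX] = (hb_length + r_co, 0.0, 0.0)
    # regular pentagon in the xy-plane, one vertex bonded to the carboxyl C
    circum = p.ring_bond / (2.0 * np.sin(np.pi / 5.0))
    center_x = hb_length + r_co + p.ring_link + circum
    angles = np.pi + 2.0 * np.pi * np.arange(5) / 5.0
    for k, idx in enumerate(RING_ATOMS):
        coords[idx] = (center_x + circum * np.cos(angles[k]),
                       circum * np.sin(angles[k]), 0.0)
    coords[p.pucker_atom, 2] += p.pucker_per_q * q
    return coords


def toy_geometry(hb_length: float, delta: float = 0.0, q: float = 0.0,
                 params: ToyMoleculeParams | None = None) -> Geometry:
    """Static toy-molecule geometry for given model coordinates."""
    p = params or ToyMoleculeParams()
    return Geometry(elements=ELEMENTS, coords=_base_coords(hb_length, delta, q, p))


def embed_trajectory(traj: TrajectoryRecord, hb_length: float,
                     params: ToyMoleculeParams | None = None) -> TrajectoryRecord:
    """Map a (delta, q) model trajectory onto Cartesian toy-molecule frames.

    The returned record shares times and electronic data with the input but
    carries (n_frames, n_atoms, 3) coordinates and element labels; finite-
    difference Cartesian velocities are attached for completeness.
    """
    if traj.coords.ndim != 2 or traj.coords.shape[1] != 2:
        raise InputError("expected a 2-DOF model trajectory (delta, q)")
    p = params or ToyMoleculeParams()
    n = len(traj)
    coords = np.empty((n, len(ELEMENTS), 3))
    for k in range(n):
        coords[k] = _base_coords(hb_length, traj.coords[k, 0], traj.coords[k, 1], p)
    vel = np.gradient(coords, traj.dt, axis=0)
    return TrajectoryRecord(dt=traj.dt, times=traj.times.copy(), coords=coords,
                            velocities=vel, e_s0=traj.e_s0.copy(),
                            e_s1=traj.e_s1.copy(), sigma=traj.sigma.copy(),
                            osc_strength=traj.osc_strength.copy(),
                            active_state=traj.active_state, seed=traj.seed,
                            restraints=traj.restraints, labels=ELEMENTS)
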