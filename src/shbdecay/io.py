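"""File formats: extended XYZ trajectories, geometry files, CSV exports.

Extended XYZ: per frame an atom-count line, a comment line of ``key=value``
pairs carrying time and the electronic data (time, e_s0, e_s1, sigma, f),
then one ``element x y z`` line per atom.  Round trips preserve coordinates
to 1e-6 A and all metadata fields.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import Geometry
from .errors import InputError, ParseError
from .model_system import TrajectoryRecord

__all__ = ["write_xyz", "read_xyz", "read_geometry", "trajectory_to_csv",
           "decay_profile_to_csv", "spectrum_to_csv", "read_sticks_csv",
           "free_energy_profile_to_csv"]

_META_KEYS = ("time", "e_s0", "e_s1", "sigma", "f")


def write_xyz(traj: TrajectoryRecord, path) -> None:
    """Write a Cartesian trajectory as extended XYZ."""
    coords = traj.coords
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise InputError("write_xyz needs Cartesian coordinates (n_frames, n_atoms, 3)")
    elements = traj.labels
    lines = []
    for k in range(len(traj)):
        lines.append(str(coords.shape[1]))
        meta = (f"time={traj.times[k]:.6f} e_s0={traj.e_s0[k]:.8f} "
                f"e_s1={traj.e_s1[k]:.8f} sigma={traj.sigma[k]:.10e} "
                f"f={traj.osc_strength[k]:.8f} state={traj.active_state}")
        lines.append(meta)
        for el, xyz in zip(elements, coords[k]):
            lines.append(f"{el} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_comment(comment: str) -> dict:
    out = {}
    for tok in comment.split():
        if "=" in tok:
            k, v = tok.split("=", 1)
            out[k] = v
    return out


def read_xyz(path) -> TrajectoryRecord:
    """Read an extended-XYZ trajectory written by :func:`write_xyz`."""
    text = Path(path).read_text()
    raw = text.splitlines()
    if not any(line.strip() for line in raw):
        raise ParseError("empty trajectory file")
    frames, elements = [], None
    meta = {k: [] for k in _META_KEYS}
    state = "S0"
    i, lineno = 0, 0
    while i < len(raw):
        if not raw[i].strip():
            i += 1
            continue
        try:
            natoms = int(raw[i].strip())
        except ValueError:
            raise ParseError(f"expected atom count, got {raw[i]!r}", line=i + 1)
        if i + 1 >= len(raw):
            raise ParseError("missing comment line", line=i + 2)
        info = _parse_comment(raw[i + 1])
        frame_elements, coords = [], []
        for j in range(natoms):
            li = i + 2 + j
            if li >= len(raw) or not raw[li].strip():
                raise ParseError(f"frame {len(frames)} truncated: expected "
                                 f"{natoms} atoms", line=li + 1)
            parts = raw[li].split()
            if len(parts) < 4:
                raise ParseError(f"malformed atom line {raw[li]!r}", line=li + 1)
            frame_elements.append(parts[0])
            try:
                coords.append([float(x) for x in parts[1:4]])
            except ValueError:
                raise ParseError(f"non-numeric coordinate in {raw[li]!r}",
                                 line=li + 1)
        if elements is None:
            elements = tuple(frame_elements)
        elif tuple(frame_elements) != elements:
            raise ParseError(f"frame {len(frames)} atom list differs from frame 0",
                             line=i + 1)
        frames.append(coords)
        for key in _META_KEYS:
            meta[key].append(float(info.get(key, "nan")))
        state = info.get("state", state)
        i += 2 + natoms
    coords = np.asarray(frames)
    times = np.asarray(meta["time"])
    if np.all(np.isnan(times)):
        times = np.arange(len(frames), dtype=float)
    dt = float(times[1] - times[0]) if len(times) > 1 else 1.0
    zeros = np.zeros_like(coords)
    return TrajectoryRecord(dt=dt, times=times, coords=coords, velocities=zeros,
                            e_s0=np.asarray(meta["e_s0"]),
                            e_s1=np.asarray(meta["e_s1"]),
                            sigma=np.asarray(meta["sigma"]),
                            osc_strength=np.asarray(meta["f"]),
                            active_state=state, labels=elements)


def read_geometry(path) -> Geometry:
    """Read a single geometry from an XYZ or PDB file (Cartesian A)."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        import gemmi

        st = gemmi.read_structure(str(path))
        elements, coords = [], []
        for model in st:
            for chain in model:
                for res in chain:
                    for atom in res:
                        elements.append(atom.element.name)
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
            break
        if not elements:
            raise ParseError("no atoms in PDB file")
        return Geometry(elements=tuple(elements), coords=np.asarray(coords))
    traj = read_xyz(path)
    return Geometry(elements=traj.labels, coords=traj.coords[0])


def trajectory_to_csv(traj: TrajectoryRecord, path) -> None:
    """Columnar CSV of the electronic frames of a trajectory."""
    df = pd.DataFrame({
        "time_fs": traj.times, "e_s0_ev": traj.e_s0, "e_s1_ev": traj.e_s1,
        "gap_ev": traj.gap, "sigma_per_fs": traj.sigma,
        "osc_strength": traj.osc_strength,
    })
    if traj.coords.ndim == 2:
        for d, label in enumerate(traj.labels):
            df[label] = traj.coords[:, d]
    df.to_csv(path, index=False)


def decay_profile_to_csv(profile, path) -> None:
    """CSV of one decay profile: step-end time, nrp, hazard, anrp."""
    pd.DataFrame({
        "time_fs": profile.times[1:], "nrp": profile.nrp,
        "hazard": profile.hazard, "anrp": profile.anrp[1:],
    }).to_csv(path, index=False)


def spectrum_to_csv(spectrum, path) -> None:
    from .spectra import ev_to_nm

    pd.DataFrame({
        "energy_ev": spectrum.grid,
        "wavelength_nm": ev_to_nm(spectrum.grid),
        "intensity": spectrum.intensity,
    }).to_csv(path, index=False)


def free_energy_profile_to_csv(profile, path) -> None:
    pd.DataFrame({
        "coordinate_A": profile.bin_centers,
        "free_energy_ev": profile.free_energy,
        "n_samples": profile.n_samples,
    }).to_csv(path, index=False)


def read_sticks_csv(path) -> list[tuple[float, float]]:
    """Read excitation sticks from a CSV with columns energy_eV, osc_strength."""
    sticks = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key_e = next((k for k in row if k.lower().startswith("energy")), None)
            key_f = next((k for k in row if "osc" in k.lower()), None)
            if key_e is None or key_f is None:
                raise ParseError("sticks CSV needs energy_eV and osc_strength columns")
            sticks.append((float(row[key_e]), float(row[key_f])))
    return sticks
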