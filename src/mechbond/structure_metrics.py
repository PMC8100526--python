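"""Per-frame conformational metrics: superposed Cα-RMSD, Shrake–Rupley SASA
and buried interface area, inter-helix angle, and centroid/atom distances.

Conventions: coordinates Å, areas Å², angles degrees.  Buried interface SASA
is SASA(A) + SASA(B) − SASA(A∪B) and is *not* divided by two; the convention
is recorded in output metadata.  SASA uses the Shrake–Rupley algorithm with
Bondi element radii and a 1.4 Å probe (the water-probe convention).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .traj_io import AtomSelection, Frame, Trajectory

__all__ = [
    "SuperpositionResult",
    "SasaResult",
    "HelixAxis",
    "kabsch_superpose",
    "ca_rmsd_series",
    "shrake_rupley_sasa",
    "buried_sasa",
    "helix_axis",
    "interhelix_angle",
    "centroid_distance",
    "atom_pair_distance",
]

#: standard atomic masses (u) for centre-of-mass computations
ATOMIC_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "NA": 22.990, "CL": 35.45, "K": 39.098, "CA": 40.078,
}

#: Bondi van der Waals radii (Å) — consistent with the "Single" radius set
#: used by the SASA backend
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}


@dataclasses.dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # applied after rotation about the mobile centroid
    rmsd: float  # Å

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclasses.dataclass
class SasaResult:
    per_atom: np.ndarray  # Å² per selected atom
    total: float  # Å²
    probe_radius: float
    n_sphere_points: int


@dataclasses.dataclass
class HelixAxis:
    origin: np.ndarray  # centroid of the Cα coordinates
    direction: np.ndarray  # unit vector, oriented N→C


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> SuperpositionResult:
    """Optimal proper-rotation least-squares superposition (Kabsch).

    Returns the rotation/translation mapping ``mobile`` onto ``reference``
    and the post-superposition RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"point counts differ: {mobile.shape} vs {reference.shape}")
    if mobile.ndim != 2 or mobile.shape[1] != 3 or mobile.shape[0] < 3:
        raise ValueError("need >=3 three-dimensional points")
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    R = rot.as_matrix()
    translation = ref_c - R @ mob_c
    moved = mobile @ R.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return SuperpositionResult(R, translation, rmsd)


def ca_rmsd_series(
    traj: Trajectory,
    reference_frame: int = 0,
    selection: AtomSelection | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame Cα-RMSD against a reference frame.

    By default each frame is optimally superposed before the RMSD is taken,
    so the series measures conformational change with rigid drift removed
    (a pulled complex translates trivially).  ``superpose=False`` gives the
    raw coordinate RMSD.
    """
    if selection is None:
        selection = traj.select("name CA")
    idx = selection.indices
    if len(idx) == 0:
        raise ValueError("empty selection for RMSD series")
    ref = traj.coords[reference_frame][idx]
    out = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        mob = traj.coords[i][idx]
        if superpose:
            out[i] = kabsch_superpose(mob, ref).rmsd
        else:
            out[i] = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
    return out


def _frame_to_atom_array(frame: Frame, indices: np.ndarray):
    import biotite.structure as struc

    top = frame.topology
    n = len(indices)
    arr = struc.AtomArray(n)
    arr.coord = frame.coords[indices].astype(np.float32)
    arr.chain_id = np.asarray(top.chain_id[indices], dtype="U4")
    arr.res_id = np.asarray(top.residue_id[indices])
    arr.res_name = np.asarray(top.residue_name[indices], dtype="U5")
    arr.atom_name = np.asarray(top.name[indices], dtype="U6")
    arr.element = np.asarray(top.element[indices], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)
    return arr


def shrake_rupley_sasa(
    frame: Frame,
    selection: AtomSelection | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> SasaResult:
    """Solvent-accessible surface area by Shrake–Rupley sphere sampling.

    Per-atom areas for the selected atoms, Bondi element radii, probe radius
    in Å.  ``n_points`` is the precision/speed knob (points per sphere).
    """
    import biotite.structure as struc

    if selection is None:
        indices = np.arange(frame.n_atoms)
    else:
        indices = selection.indices
    if len(indices) == 0:
        raise ValueError("empty selection for SASA")
    top = frame.topology
    for i in indices:
        if str(top.element[i]).upper() not in BONDI_RADII:
            raise ValueError(
                f"no van der Waals radius for element {top.element[i]!r} "
                f"(atom {top.name[i]} {top.residue_name[i]}{top.residue_id[i]})"
            )
    arr = _frame_to_atom_array(frame, indices)
    per_atom = struc.sasa(
        arr, probe_radius=probe, point_number=n_points, vdw_radii="Single",
        ignore_ions=False,
    )
    per_atom = np.nan_to_num(np.asarray(per_atom, dtype=float))
    return SasaResult(per_atom, float(per_atom.sum()), probe, n_points)


def buried_sasa(
    frame: Frame,
    chain_a: AtomSelection,
    chain_b: AtomSelection,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Interface area buried on complexation:
    SASA(A alone) + SASA(B alone) − SASA(A∪B).  Not halved."""
    if np.intersect1d(chain_a.indices, chain_b.indices).size:
        raise ValueError("chain selections overlap")
    a = shrake_rupley_sasa(frame, chain_a, probe, n_points).total
    b = shrake_rupley_sasa(frame, chain_b, probe, n_points).total
    ab = shrake_rupley_sasa(frame, chain_a.union(chain_b), probe, n_points).total
    return a + b - ab


def helix_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Principal axis of an ordered (N→C) run of Cα coordinates.

    The direction is the leading right singular vector of the centred
    coordinates, sign-fixed to have positive projection on (last − first).
    """
    ca = np.asarray(ca_coords, dtype=float)
    if ca.ndim != 2 or ca.shape[1] != 3 or ca.shape[0] < 4:
        raise ValueError("helix axis needs >=4 ordered Calpha positions")
    origin = ca.mean(axis=0)
    _, _, vt = np.linalg.svd(ca - origin)
    direction = vt[0]
    span = ca[-1] - ca[0]
    if np.dot(direction, span) < 0:
        direction = -direction
    return HelixAxis(origin, direction / np.linalg.norm(direction))


def interhelix_angle(a: HelixAxis, b: HelixAxis) -> float:
    """Angle between two oriented helix axes, degrees in [0, 180]."""
    c = float(np.dot(a.direction, b.direction))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _masses(frame: Frame, indices: np.ndarray) -> np.ndarray:
    top = frame.topology
    out = np.empty(len(indices))
    for k, i in enumerate(indices):
        out[k] = ATOMIC_MASS.get(str(top.element[i]).upper(), 12.011)
    return out


def centroid_distance(
    frame: Frame, body: AtomSelection, point_atom: tuple[str, int, str]
) -> float:
    """Distance (Å) from the mass-weighted centroid of ``body`` to one atom.

    ``point_atom`` is (chain_id, residue_id, atom_name) — e.g. the Cα of a
    loop residue tracked against the molecular body.
    """
    if len(body) == 0:
        raise ValueError("empty body selection")
    idx = _find_atom(frame, point_atom)
    m = _masses(frame, body.indices)
    com = (frame.coords[body.indices] * m[:, None]).sum(axis=0) / m.sum()
    return float(np.linalg.norm(frame.coords[idx] - com))


def atom_pair_distance(
    frame: Frame, a: tuple[str, int, str], b: tuple[str, int, str]
) -> float:
    """Euclidean distance (Å) between two atoms given as
    (chain_id, residue_id, atom_name)."""
    return float(
        np.linalg.norm(frame.coords[_find_atom(frame, a)] - frame.coords[_find_atom(frame, b)])
    )


def _find_atom(frame: Frame, ref: tuple[str, int, str]) -> int:
    chain, resid, name = ref
    top = frame.topology
    hits = np.flatnonzero(
        (top.chain_id == chain) & (top.residue_id == int(resid)) & (top.name == name)
    )
    if len(hits) == 0:
        raise KeyError(f"atom (chain={chain!r}, resid={resid}, name={name!r}) not found")
    return int(hits[0])
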