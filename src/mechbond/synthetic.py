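"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the *structure* of the real inputs — two-state bond
dynamics with a prescribed stationary occupancy, occupancy-vs-force response
laws, ramp-then-clamp pulling traces, exponential bond lifetimes under a
two-pathway off-rate, and ideal helices — without any physical force field:
geometry is kinematic puppetry sufficient to exercise the detectors.

All generators are bit-reproducible given (parameters, seed).

Bond dynamics are a two-state Markov chain, not i.i.d. coin flips, so that
occupancy estimators face realistic frame-to-frame autocorrelation.  With
switching rate ``s`` the chain's transition probabilities are
``p(off→on) = s·ω*`` and ``p(on→off) = s·(1−ω*)``; the stationary
probability is ω* and the effective number of independent frames out of n is
``n_eff = n·s/(2−s)``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .force_response import ForceTrace, LifetimeRecord, TwoPathwayParams, classify_response
from .interactions import OccupancyTable
from .traj_io import Topology, Trajectory

__all__ = [
    "BondSpec",
    "ResponseLawSpec",
    "DEFAULT_RESPONSE_LAWS",
    "gen_interface_trajectory",
    "gen_occupancy_table",
    "gen_ramp_clamp_trace",
    "gen_afm_lifetimes",
    "gen_helix",
    "markov_effective_samples",
    "write_trace_tsv",
]


@dataclasses.dataclass
class BondSpec:
    """One designed interface hydrogen bond.

    The bound geometry (donor–acceptor 2.9 Å, 10° D-H...A deviation)
    satisfies the default H-bond criteria; the unbound geometry (5.5 Å)
    violates the distance cutoff.
    """

    target_occupancy: float  # stationary ω* in [0, 1]
    switching_rate: float = 0.5  # per-frame chain mobility s in (0, 1]
    bound_distance: float = 2.9  # Å, donor–acceptor
    bound_deviation_deg: float = 10.0  # D-H...A deviation when bound
    unbound_distance: float = 5.5  # Å

    def __post_init__(self):
        if not 0.0 <= self.target_occupancy <= 1.0:
            raise ValueError("target occupancy must be in [0, 1]")
        if not 0.0 < self.switching_rate <= 1.0:
            raise ValueError("switching rate must be in (0, 1]")
        if self.bound_distance >= 3.5 or self.unbound_distance <= 3.5:
            raise ValueError(
                "bound geometry must satisfy and unbound geometry violate the "
                "3.5 Å distance criterion"
            )


def markov_effective_samples(n_frames: int, switching_rate: float) -> float:
    """Effective independent sample count of the two-state bond chain."""
    return n_frames * switching_rate / (2.0 - switching_rate)


_BOND_SPACING = 20.0  # Å between hosted bonds along x
_MIN_SPACING = 8.0


def gen_interface_trajectory(
    bonds: Sequence[BondSpec],
    n_frames: int,
    seed: int,
    frame_interval: float = 1.0,
    spacing: float = _BOND_SPACING,
) -> tuple[Trajectory, np.ndarray]:
    """Two-chain toy complex hosting one designed H-bond per BondSpec.

    Chain A carries glycine donors (N-H), chain B glycine acceptors
    (backbone O).  Per frame each bond is bound or unbound according to its
    own seeded two-state Markov chain; unbound acceptors are displaced along
    the donor–acceptor axis past the distance cutoff.  All other atoms are
    rigid across frames.

    Returns the trajectory and the ground-truth presence matrix of shape
    (n_frames, n_bonds).
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if not bonds:
        raise ValueError("need at least one bond spec")
    if spacing < _MIN_SPACING:
        raise ValueError(
            f"bond spacing {spacing} Å < {_MIN_SPACING} Å would let designed "
            "bonds overlap across sites"
        )
    rng = np.random.default_rng(seed)
    n_bonds = len(bonds)

    # --- topology: per bond, ligand GLY (N,H,CA,C,O) + receptor GLY (N,H,CA,C,O)
    names, elements, resnames, resids, chains = [], [], [], [], []
    base = np.zeros((n_bonds * 10, 3))
    acceptor_rows = []
    for k, spec in enumerate(bonds):
        x = k * spacing
        # ligand residue (donor side), chain A
        lig = {
            "N": (x, 0.0, 0.0),
            "H": _h_position(spec.bound_deviation_deg),
            "CA": (x, -1.5, 0.0),
            "C": (x, -2.6, 0.8),
            "O": (x, -2.7, 2.0),
        }
        lig["H"] = (x + lig["H"][0], lig["H"][1], lig["H"][2])
        # receptor residue (acceptor side), chain B; O is the acceptor
        d = spec.bound_distance
        rec = {
            "O": (x, d, 0.0),
            "C": (x, d + 1.2, 0.0),
            "CA": (x, d + 2.4, 0.5),
            "N": (x, d + 3.6, 0.0),
            "H": (x, d + 4.3, 0.0),
        }
        for chain, resd in (("A", lig), ("B", rec)):
            for nm, pos in resd.items():
                names.append(nm)
                elements.append(nm[0])
                resnames.append("GLY")
                resids.append(k + 1)
                chains.append(chain)
                if chain == "B" and nm == "O":
                    acceptor_rows.append(len(names) - 1)
                base[len(names) - 1] = pos
    top = Topology(names, elements, resnames, resids, chains)

    # --- per-bond Markov state sequences
    presence = np.zeros((n_frames, n_bonds), dtype=bool)
    for k, spec in enumerate(bonds):
        w, s = spec.target_occupancy, spec.switching_rate
        state = rng.random() < w
        for t in range(n_frames):
            presence[t, k] = state
            flip = s * w if not state else s * (1.0 - w)
            if rng.random() < flip:
                state = not state

    # --- coordinates: displace the acceptor O (and its residue) when unbound
    coords = np.broadcast_to(base, (n_frames,) + base.shape).copy()
    for k, spec in enumerate(bonds):
        shift = spec.unbound_distance - spec.bound_distance
        row0 = k * 10 + 5  # first receptor atom of this bond
        unbound = ~presence[:, k]
        coords[unbound, row0:row0 + 5, 1] += shift
    return Trajectory(top, coords, frame_interval=frame_interval), presence


def _h_position(deviation_deg: float) -> tuple[float, float, float]:
    """Hydrogen 1.0 Å from the donor, tilted off the donor→acceptor (+y)
    axis by the requested deviation-producing angle."""
    th = np.radians(deviation_deg)
    return (float(np.sin(th)), float(np.cos(th)), 0.0)


# ---------------------------------------------------------------------------
# occupancy-vs-force response laws
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ResponseLawSpec:
    """A named occupancy-vs-force pattern with anchor occupancies."""

    pattern: str
    anchors: tuple[float, ...]
    noise_sd: float = 0.0

    def __post_init__(self):
        if any(not 0.0 <= a <= 1.0 for a in self.anchors):
            raise ValueError("anchor occupancies must lie in [0, 1]")
        got = classify_response(self.anchors, epsilon=0.0).pattern
        if got != self.pattern:
            raise ValueError(
                f"anchors {self.anchors} classify as {got!r}, not declared "
                f"{self.pattern!r}, at epsilon=0"
            )


#: one law per named bond type; anchor steps are large (>=0.15) relative to
#: the default classification tolerance
DEFAULT_RESPONSE_LAWS = (
    ResponseLawSpec("slip", (0.85, 0.65, 0.45, 0.25)),
    ResponseLawSpec("catch-slip", (0.30, 0.70, 0.85, 0.40)),
    ResponseLawSpec("slip-catch-slip", (0.80, 0.55, 0.72, 0.45)),
    ResponseLawSpec("catch-slip-catch", (0.25, 0.60, 0.30, 0.55)),
)


def gen_occupancy_table(
    laws: Sequence[ResponseLawSpec] = DEFAULT_RESPONSE_LAWS,
    forces: Sequence[float] = (0, 25, 50, 75),
    replicates: int = 1,
    seed: int = 0,
) -> OccupancyTable:
    """Occupancy table realising each response law at each force level.

    Each law becomes one bond of its own residue pair; the occupancy at a
    force is the mean over ``replicates`` noisy draws (Gaussian with the
    law's ``noise_sd``, clipped to [0, 1]).  Forces must be strictly
    increasing.
    """
    forces = [float(f) for f in forces]
    if not all(b > a for a, b in zip(forces, forces[1:])):
        raise ValueError("forces must be strictly increasing")
    if any(len(l.anchors) != len(forces) for l in laws):
        raise ValueError("each law needs one anchor per force level")
    rng = np.random.default_rng(seed)
    rows = []
    for i, law in enumerate(laws):
        for f, anchor in zip(forces, law.anchors):
            draws = np.clip(
                anchor + rng.normal(0.0, law.noise_sd, size=replicates), 0.0, 1.0
            )
            rows.append(
                {
                    "condition": _condition_label(f),
                    "ligand_chain": "L",
                    "ligand_resid": i + 1,
                    "ligand_resname": "GLY",
                    "receptor_chain": "R",
                    "receptor_resid": i + 1,
                    "receptor_resname": "GLY",
                    "donor_atom": "N",
                    "acceptor_atom": "O",
                    "kind": "hbond",
                    "occupancy": float(draws.mean()),
                }
            )
    return OccupancyTable(pd.DataFrame(rows, columns=OccupancyTable.COLUMNS))


def _condition_label(f: float) -> str:
    return str(int(f)) if float(f).is_integer() else str(f)


# ---------------------------------------------------------------------------
# pulling traces and AFM lifetimes
# ---------------------------------------------------------------------------


def gen_ramp_clamp_trace(
    velocity: float,
    duration: float,
    dt: float = 0.01,
    spring_constant: float = 13.89,
    rupture_time: float | None = None,
    clamp_force: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ForceTrace:
    """Ramp-then-clamp pulling force trace.

    Force rises at ``spring_constant × velocity`` (pN/ns) until either the
    clamp force is reached (then held constant, phase "clamp") or the bond
    ruptures at ``rupture_time`` (force drops to zero).  Units: velocity
    Å/ns, spring constant pN/Å, time ns, force pN.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, dt) + dt
    slope = spring_constant * velocity  # pN/ns
    force = slope * t
    phase = np.array(["ramp"] * len(t), dtype=object)
    if clamp_force is not None:
        clamped = force >= clamp_force
        force[clamped] = clamp_force
        phase[clamped] = "clamp"
    if rupture_time is not None:
        ruptured = t > rupture_time
        force[ruptured] = 0.0
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=len(t))
    return ForceTrace(t, force, phase)


def gen_afm_lifetimes(
    params: TwoPathwayParams,
    forces: Sequence[float],
    n_per_force: int,
    seed: int = 0,
) -> list[LifetimeRecord]:
    """Exponential single-bond lifetimes at each clamp force, with the mean
    1/k(f) set by the two-pathway off-rate."""
    rng = np.random.default_rng(seed)
    records: list[LifetimeRecord] = []
    for f in forces:
        mean = 1.0 / float(params.off_rate(f))
        for lt in rng.exponential(mean, size=n_per_force):
            records.append(LifetimeRecord(float(f), float(lt)))
    return records


# ---------------------------------------------------------------------------
# helices
# ---------------------------------------------------------------------------


def gen_helix(
    n_res: int,
    rise: float = 1.5,
    twist_deg: float = 100.0,
    radius: float = 2.3,
    direction: Sequence[float] = (0.0, 0.0, 1.0),
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Cα coordinates of an ideal α-helix along ``direction`` (N→C).

    Defaults are the canonical α-helix: 1.5 Å rise and 100° twist per
    residue at 2.3 Å radius.
    """
    if n_res < 4:
        raise ValueError("a helix needs >=4 residues")
    i = np.arange(n_res)
    ang = np.radians(twist_deg) * i
    coords = np.column_stack([radius * np.cos(ang), radius * np.sin(ang), rise * i])
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    if np.allclose(d, z):
        R = np.eye(3)
    elif np.allclose(d, -z):
        R = Rotation.from_rotvec(np.pi * np.array([1.0, 0.0, 0.0])).as_matrix()
    else:
        axis = np.cross(z, d)
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(axis * np.arccos(np.clip(np.dot(z, d), -1, 1))).as_matrix()
    return coords @ R.T + np.asarray(origin, dtype=float)


def write_trace_tsv(trace: ForceTrace, path) -> None:
    """Write a force trace as TSV (time_ns, force_pN[, phase])."""
    df = pd.DataFrame({"time_ns": trace.time, "force_pN": trace.force})
    if trace.phase is not None:
        df["phase"] = trace.phase
    df.to_csv(path, sep="\t", index=False)
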