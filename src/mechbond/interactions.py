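"""Interface hydrogen-bond and salt-bridge detection, and bond occupancies.

A hydrogen bond is counted when the donor–acceptor heavy-atom distance is
strictly below 3.5 Å AND the angle between the donor→hydrogen direction and
the hydrogen→acceptor direction (the deviation from linearity of D-H...A) is
strictly below 30°.  A salt bridge is counted when any side-chain oxygen of
an acidic residue (Asp OD1/OD2, Glu OE1/OE2) lies within 4.0 Å (inclusive)
of a side-chain nitrogen of a basic residue (Lys NZ, Arg NE/NH1/NH2).

The occupancy (survival ratio) ω of a bond is the fraction of trajectory
frames in which its geometric criterion holds; frames are weighted equally.
Occupancy is kept per individual H-bond (atom-level key); aggregation of the
M_ij bonds of one residue pair into a pair binding probability happens in
:mod:`mechbond.dissociation`.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .traj_io import AtomSelection, Frame, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "HBondCriteria",
    "SaltBridgeCriteria",
    "ResidueRef",
    "BondKey",
    "BondPresenceSeries",
    "OccupancyRecord",
    "OccupancyTable",
    "detect_hbonds_frame",
    "detect_salt_bridges_frame",
    "bond_presence",
    "occupancy",
    "hbond_count_series",
]

#: maximum covalent X–H distance used to pair hydrogens with their donor (Å)
_DH_COVALENT_CUTOFF = 1.25

_ACIDIC_O = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_BASIC_N = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}


@dataclasses.dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond criteria; both cutoffs are strict upper bounds."""

    max_da_distance: float = 3.5  # Å
    max_dha_angle: float = 30.0  # degrees, deviation of H→A from D→H
    #: accept donors without explicit hydrogens using the heavy-atom
    #: fallback: D–A distance plus acceptor–donor–antecedent angle > 90°
    allow_missing_hydrogens: bool = False

    def __post_init__(self):
        if self.max_da_distance <= 0 or self.max_dha_angle <= 0:
            raise ValueError("H-bond cutoffs must be strictly positive")


@dataclasses.dataclass(frozen=True)
class SaltBridgeCriteria:
    """Salt-bridge O–N distance cutoff (inclusive: 'within')."""

    max_on_distance: float = 4.0  # Å

    def __post_init__(self):
        if self.max_on_distance <= 0:
            raise ValueError("salt-bridge cutoff must be strictly positive")


@dataclasses.dataclass(frozen=True, order=True)
class ResidueRef:
    chain: str
    residue_id: int
    residue_name: str

    def label(self) -> str:
        """One-letter-code label in the field's shorthand, e.g. ``K244``."""
        one = _THREE_TO_ONE.get(self.residue_name.upper(), "X")
        return f"{one}{self.residue_id}"


_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "HSD": "H",
    "HSE": "H", "HSP": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T",
    "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclasses.dataclass(frozen=True, order=True)
class BondKey:
    """Canonical identifier of one interface bond, ligand residue first."""

    ligand_residue: ResidueRef
    receptor_residue: ResidueRef
    donor_atom: str
    acceptor_atom: str
    kind: str = "hbond"  # or "saltbridge"

    def __post_init__(self):
        if self.ligand_residue.chain == self.receptor_residue.chain:
            raise ValueError("ligand and receptor residues must be on different chains")

    @property
    def pair(self) -> tuple[ResidueRef, ResidueRef]:
        return (self.ligand_residue, self.receptor_residue)


@dataclasses.dataclass
class BondPresenceSeries:
    key: BondKey
    present: np.ndarray  # boolean per frame

    def __post_init__(self):
        self.present = np.asarray(self.present, dtype=bool)

    @property
    def n_frames(self) -> int:
        return len(self.present)


@dataclasses.dataclass
class OccupancyRecord:
    key: BondKey
    occupancy: float

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


class OccupancyTable:
    """Bond occupancies keyed by (BondKey, condition).

    Backed by a long-form DataFrame with one row per bond per condition.
    Conditions are labels: force levels in pN (numeric strings) or model
    ids.  Missing (bond, condition) combinations are treated as ω = 0 when a
    dense per-condition view is requested.
    """

    COLUMNS = [
        "condition", "ligand_chain", "ligand_resid", "ligand_resname",
        "receptor_chain", "receptor_resid", "receptor_resname",
        "donor_atom", "acceptor_atom", "kind", "occupancy",
    ]

    def __init__(self, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"occupancy table missing columns: {sorted(missing)}")
        frame = frame[self.COLUMNS].copy()
        frame["occupancy"] = frame["occupancy"].astype(float)
        bad = frame[(frame.occupancy < 0) | (frame.occupancy > 1)]
        if len(bad):
            raise ValueError("occupancies outside [0, 1] in table")
        if len(frame) == 0:
            raise ValueError("occupancy table has no conditions")
        dup = frame.duplicated(
            subset=[c for c in self.COLUMNS if c != "occupancy"]
        )
        if dup.any():
            raise ValueError("duplicate (bond, condition) rows in occupancy table")
        self.data = frame.reset_index(drop=True)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[OccupancyRecord], condition: str | float
    ) -> "OccupancyTable":
        rows = [
            {
                "condition": str(condition),
                "ligand_chain": r.key.ligand_residue.chain,
                "ligand_resid": r.key.ligand_residue.residue_id,
                "ligand_resname": r.key.ligand_residue.residue_name,
                "receptor_chain": r.key.receptor_residue.chain,
                "receptor_resid": r.key.receptor_residue.residue_id,
                "receptor_resname": r.key.receptor_residue.residue_name,
                "donor_atom": r.key.donor_atom,
                "acceptor_atom": r.key.acceptor_atom,
                "kind": r.key.kind,
                "occupancy": r.occupancy,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))

    @classmethod
    def concat(cls, tables: Sequence["OccupancyTable"]) -> "OccupancyTable":
        return cls(pd.concat([t.data for t in tables], ignore_index=True))

    # -- views -------------------------------------------------------------

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data["condition"]))

    def occupancies(self, condition: str | float) -> np.ndarray:
        sub = self.data[self.data.condition == str(condition)]
        if len(sub) == 0:
            raise KeyError(
                f"condition {condition!r} not in table (have {self.conditions})"
            )
        return sub.occupancy.to_numpy()

    def bonds(self, condition: str | float) -> pd.DataFrame:
        sub = self.data[self.data.condition == str(condition)]
        if len(sub) == 0:
            raise KeyError(
                f"condition {condition!r} not in table (have {self.conditions})"
            )
        return sub.reset_index(drop=True)

    def n_pairs(self, condition: str | float, nonzero: bool = True) -> int:
        """Number of distinct residue pairs for a condition."""
        sub = self.bonds(condition)
        if nonzero:
            sub = sub[sub.occupancy > 0]
        return len(
            sub.drop_duplicates(
                subset=["ligand_chain", "ligand_resid", "receptor_chain", "receptor_resid"]
            )
        )

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OccupancyTable":
        """Read the full table dialect written by :meth:`to_tsv`."""
        return cls(pd.read_csv(path, sep="\t", dtype={"condition": str}))

    @classmethod
    def read_reduced(cls, path: str | Path, sep: str = "\t") -> "OccupancyTable":
        """Read the reduced dialect mirroring printed occupancy tables.

        Expected header: ``ligand`` and ``receptor`` residue-label columns
        (e.g. ``K244``, ``D18``) followed by one occupancy column per
        condition.  Ligand residues are placed on chain 'L', receptor
        residues on chain 'R'; each row is treated as a single bond of its
        residue pair (the printed tables do not resolve atom names), with a
        row counter disambiguating repeated pairs.
        """
        raw = pd.read_csv(path, sep=sep, comment="#")
        if raw.shape[1] < 3:
            raise ValueError("reduced table needs ligand, receptor and >=1 condition column")
        lig_col, rec_col = raw.columns[:2]
        rows = []
        pair_seen: dict[tuple[str, str], int] = {}
        for _, row in raw.iterrows():
            lig, rec = str(row[lig_col]), str(row[rec_col])
            idx = pair_seen.get((lig, rec), 0)
            pair_seen[(lig, rec)] = idx + 1
            for cond in raw.columns[2:]:
                val = row[cond]
                if pd.isna(val):
                    continue
                rows.append(
                    {
                        "condition": str(cond),
                        "ligand_chain": "L",
                        "ligand_resid": _label_resid(lig),
                        "ligand_resname": lig,
                        "receptor_chain": "R",
                        "receptor_resid": _label_resid(rec),
                        "receptor_resname": rec,
                        "donor_atom": f"X{idx}",
                        "acceptor_atom": "X",
                        "kind": "hbond",
                        "occupancy": float(val),
                    }
                )
        return cls(pd.DataFrame(rows, columns=cls.COLUMNS))


def _label_resid(label: str) -> int:
    m = "".join(ch for ch in label if ch.isdigit())
    return int(m) if m else 0


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _chain_roles(frame: Frame, ligand: AtomSelection, receptor: AtomSelection):
    top = frame.topology
    lig_chain = set(top.chain_id[ligand.indices])
    rec_chain = set(top.chain_id[receptor.indices])
    if lig_chain & rec_chain:
        raise ValueError("ligand and receptor selections share a chain")
    return lig_chain, rec_chain


def _residue_ref(top, i: int) -> ResidueRef:
    return ResidueRef(str(top.chain_id[i]), int(top.residue_id[i]), str(top.residue_name[i]))


def _donors_and_hydrogens(frame: Frame, indices: np.ndarray):
    """Map donor heavy atoms (N/O with covalently attached H) to H indices.

    Pairing is geometric (H within 1.25 Å of an N/O of the same residue),
    so it works for any protonation state without a bond topology.
    """
    top = frame.topology
    coords = frame.coords
    heavy = [i for i in indices if top.element[i] in ("N", "O")]
    hydro = [i for i in indices if top.element[i] == "H"]
    donors: dict[int, list[int]] = {}
    if heavy and hydro:
        tree = cKDTree(coords[hydro])
        for i in heavy:
            for jh in tree.query_ball_point(coords[i], _DH_COVALENT_CUTOFF):
                h = hydro[jh]
                if (top.chain_id[h], top.residue_id[h]) == (top.chain_id[i], top.residue_id[i]):
                    donors.setdefault(i, []).append(h)
    return donors, heavy


def _antecedent(frame: Frame, donor: int, indices: np.ndarray) -> int | None:
    """Nearest heavy atom of the same residue — proxy for the donor's bonded
    antecedent, used only by the hydrogen-free fallback criterion."""
    top = frame.topology
    same = [
        i for i in indices
        if i != donor
        and top.element[i] != "H"
        and top.chain_id[i] == top.chain_id[donor]
        and top.residue_id[i] == top.residue_id[donor]
    ]
    if not same:
        return None
    d = np.linalg.norm(frame.coords[same] - frame.coords[donor], axis=1)
    return same[int(np.argmin(d))]


def detect_hbonds_frame(
    frame: Frame,
    ligand: AtomSelection,
    receptor: AtomSelection,
    criteria: HBondCriteria = HBondCriteria(),
) -> set[BondKey]:
    """Detect inter-chain hydrogen bonds in one frame.

    Both directions are scanned (ligand donor → receptor acceptor and vice
    versa).  Keys are canonical with the ligand residue first regardless of
    donor direction.
    """
    if len(ligand) == 0 or len(receptor) == 0:
        logger.warning("empty ligand or receptor selection: no H-bonds detected")
        return set()
    _chain_roles(frame, ligand, receptor)
    top = frame.topology
    coords = frame.coords
    found: set[BondKey] = set()
    for donor_sel, acc_sel, lig_is_donor in (
        (ligand, receptor, True),
        (receptor, ligand, False),
    ):
        donors, heavies = _donors_and_hydrogens(frame, donor_sel.indices)
        acceptors = [i for i in acc_sel.indices if top.element[i] in ("N", "O")]
        if not acceptors:
            continue
        acc_tree = cKDTree(coords[acceptors])
        donor_pool = donors.keys() if not criteria.allow_missing_hydrogens else heavies
        for d in donor_pool:
            for ja in acc_tree.query_ball_point(coords[d], criteria.max_da_distance):
                a = acceptors[ja]
                dist = np.linalg.norm(coords[a] - coords[d])
                if not dist < criteria.max_da_distance:  # strict
                    continue
                if d in donors:
                    ok = any(
                        _dha_deviation(coords[d], coords[h], coords[a]) < criteria.max_dha_angle
                        for h in donors[d]
                    )
                else:  # heavy-atom fallback (explicitly enabled)
                    ante = _antecedent(frame, d, donor_sel.indices)
                    if ante is None:
                        ok = True
                    else:
                        ok = _angle(coords[a], coords[d], coords[ante]) > 90.0
                if not ok:
                    continue
                if lig_is_donor:
                    key = BondKey(
                        _residue_ref(top, d), _residue_ref(top, a),
                        str(top.name[d]), str(top.name[a]), "hbond",
                    )
                else:
                    key = BondKey(
                        _residue_ref(top, a), _residue_ref(top, d),
                        str(top.name[d]), str(top.name[a]), "hbond",
                    )
                found.add(key)
    return found


def _dha_deviation(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """Angle (deg) between the D→H and H→A directions: 0 for a linear bond."""
    v1 = h - d
    v2 = a - h
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def _angle(p1: np.ndarray, vertex: np.ndarray, p2: np.ndarray) -> float:
    v1 = p1 - vertex
    v2 = p2 - vertex
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def detect_salt_bridges_frame(
    frame: Frame,
    ligand: AtomSelection,
    receptor: AtomSelection,
    criteria: SaltBridgeCriteria = SaltBridgeCriteria(),
) -> set[BondKey]:
    """Detect inter-chain salt bridges (side-chain O of Asp/Glu within the
    cutoff of side-chain N of Lys/Arg; inclusive comparison)."""
    if len(ligand) == 0 or len(receptor) == 0:
        logger.warning("empty ligand or receptor selection: no salt bridges detected")
        return set()
    _chain_roles(frame, ligand, receptor)
    top = frame.topology
    coords = frame.coords

    def classify(indices):
        oxy, nit = [], []
        for i in indices:
            key = (str(top.residue_name[i]).upper(), str(top.name[i]).upper())
            if key in _ACIDIC_O:
                oxy.append(i)
            elif key in _BASIC_N:
                nit.append(i)
        return oxy, nit

    lig_o, lig_n = classify(ligand.indices)
    rec_o, rec_n = classify(receptor.indices)
    found: set[BondKey] = set()
    for o_pool, n_pool, lig_has_o in ((lig_o, rec_n, True), (rec_o, lig_n, False)):
        for o in o_pool:
            for n in n_pool:
                if np.linalg.norm(coords[o] - coords[n]) <= criteria.max_on_distance:
                    if lig_has_o:
                        key = BondKey(
                            _residue_ref(top, o), _residue_ref(top, n),
                            str(top.name[n]), str(top.name[o]), "saltbridge",
                        )
                    else:
                        key = BondKey(
                            _residue_ref(top, n), _residue_ref(top, o),
                            str(top.name[n]), str(top.name[o]), "saltbridge",
                        )
                    found.add(key)
    return found


def bond_presence(
    traj: Trajectory,
    ligand: AtomSelection,
    receptor: AtomSelection,
    criteria: HBondCriteria | SaltBridgeCriteria = HBondCriteria(),
) -> list[BondPresenceSeries]:
    """Per-frame presence for the union of all bonds ever observed.

    Presence is evaluated independently per frame; the result covers every
    key observed in at least one frame (never silently truncated).
    """
    detect = (
        detect_salt_bridges_frame
        if isinstance(criteria, SaltBridgeCriteria)
        else detect_hbonds_frame
    )
    per_frame = [detect(f, ligand, receptor, criteria) for f in traj]
    keys = sorted(set().union(*per_frame)) if per_frame else []
    return [
        BondPresenceSeries(k, np.array([k in fr for fr in per_frame]))
        for k in keys
    ]


def occupancy(series: BondPresenceSeries) -> OccupancyRecord:
    """ω = (frames present) / (total frames)."""
    if series.n_frames == 0:
        raise ValueError("cannot compute occupancy over zero frames")
    return OccupancyRecord(series.key, float(series.present.mean()))


def hbond_count_series(
    traj: Trajectory,
    ligand: AtomSelection,
    receptor: AtomSelection,
    criteria: HBondCriteria = HBondCriteria(),
) -> np.ndarray:
    """N_HB per frame: the number of distinct inter-chain H-bond keys.

    The mean of this series equals the sum of per-bond occupancies over the
    same key set (an exact linearity identity).
    """
    return np.array(
        [len(detect_hbonds_frame(f, ligand, receptor, criteria)) for f in traj],
        dtype=int,
    )
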