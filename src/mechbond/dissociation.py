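"""Independence-based receptor–ligand dissociation probability model.

Every interface bond is treated as an independent two-state unit whose
survival probability over the observation window is its occupancy ω.  From a
table of occupancies the model derives, per condition:

* ``p_ij = 1 − Π_l (1 − ω_ij,l)`` — the probability that residue pair
  (i, j) is bonded through at least one of its M_ij bonds;
* ``P_j,L = 1 − Π_i (1 − p_ji)`` and ``P_j,R`` — per-residue binding
  probabilities on the ligand and receptor side;
* ``P_D = Π_bonds (1 − ω) = Π_j (1 − P_j,L) = Π_j (1 − P_j,R)`` — the
  probability that *no* interface bond survives, i.e. complex dissociation;
* ``f_D = P_D(f) / P_D(0)`` — the normalized (mechano-regulation) ratio
  against a zero-force reference condition.

Note on the complement form ``1 − Π_j (1 − P_j,L)``: that expression is the
probability that *some* residue still binds and is therefore an association,
not a dissociation, probability.  It is available through
``as_printed=True`` for comparison, but the product form above is the one
whose values are meaningful (and it is an algebraic identity across the
per-bond, per-pair and per-residue factorizations, which the implementation
checks to 1e-12).

Products are computed as exponentiated sums of log1p(−ω) with ω = 1
short-circuited to a hard zero, so P_D ≪ 1 does not underflow for large
tables.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .interactions import OccupancyTable

__all__ = [
    "PairProbability",
    "ResidueBindingProbability",
    "DissociationResult",
    "DissociationModel",
    "DissociationResults",
    "pair_probability",
    "residue_probability",
    "complex_dissociation",
    "normalized_dissociation",
    "expected_bond_count",
]

_SIDE_TOL = 1e-12


def _log_survival(omegas: np.ndarray) -> float:
    """log Π (1 − ω); −inf when any ω == 1."""
    omegas = np.asarray(omegas, dtype=float)
    if np.any((omegas < 0) | (omegas > 1)):
        raise ValueError("occupancies must lie in [0, 1]")
    if np.any(omegas == 1.0):
        return float("-inf")
    return float(np.sum(np.log1p(-omegas)))


def _survival_product(omegas: np.ndarray) -> float:
    """Π (1 − ω) via logs, exact 0 when any ω == 1."""
    return float(np.exp(_log_survival(omegas)))


@dataclasses.dataclass
class PairProbability:
    ligand_residue: str
    receptor_residue: str
    p: float
    n_bonds: int  # M_ij


@dataclasses.dataclass
class ResidueBindingProbability:
    residue: str
    side: str  # "ligand" | "receptor"
    P: float
    n_partners: int


@dataclasses.dataclass
class DissociationResult:
    """Per-condition dissociation summary."""

    condition: str
    P_D: float
    f_D: float | None  # only when a reference condition exists
    log_P_D: float  # exact even when P_D underflows to 0
    n_bonds: int
    expected_bond_count: float  # Σω
    pair_probabilities: list[PairProbability]
    ligand_residues: list[ResidueBindingProbability]
    receptor_residues: list[ResidueBindingProbability]


def pair_probability(bond_occupancies: Sequence[float]) -> float:
    """p = 1 − Π_l (1 − ω_l) over the bonds of one residue pair."""
    omegas = np.asarray(bond_occupancies, dtype=float)
    if omegas.size == 0:
        raise ValueError("a residue pair needs at least one bond occupancy")
    return 1.0 - _survival_product(omegas)


def _pair_frame(bonds: pd.DataFrame) -> pd.DataFrame:
    g = bonds.groupby(
        ["ligand_chain", "ligand_resid", "ligand_resname",
         "receptor_chain", "receptor_resid", "receptor_resname"],
        sort=True,
    )["occupancy"]
    rows = []
    for key, om in g:
        rows.append(
            {
                "ligand": f"{key[2]}:{key[1]}",
                "receptor": f"{key[5]}:{key[4]}",
                "p": pair_probability(om.to_numpy()),
                "n_bonds": len(om),
            }
        )
    return pd.DataFrame(rows)


def residue_probability(
    table: OccupancyTable, residue: str, side: str, condition: str | float
) -> ResidueBindingProbability:
    """P = 1 − Π over partner residues (1 − p_partner) for one residue.

    ``residue`` is a ``RESNAME:resid`` label (e.g. ``"LYS:278"``) or a bare
    printed label matching the table's resname field (reduced dialect).
    """
    if side not in ("ligand", "receptor"):
        raise ValueError("side must be 'ligand' or 'receptor'")
    pairs = _pair_frame(table.bonds(condition))
    own, other = ("ligand", "receptor") if side == "ligand" else ("receptor", "ligand")
    sub = pairs[(pairs[own] == residue) | (pairs[own].str.split(":").str[0] == residue)]
    if len(sub) == 0:
        known = sorted(pairs[own].unique())
        raise KeyError(f"residue {residue!r} not on {side} side; known: {known}")
    P = 1.0 - _survival_product(sub.p.to_numpy())
    return ResidueBindingProbability(residue, side, P, len(sub))


def _condition_result(
    table: OccupancyTable, condition: str | float, as_printed: bool = False
) -> DissociationResult:
    try:
        bonds = table.bonds(condition)
    except KeyError:
        raise
    omegas = bonds.occupancy.to_numpy()
    pairs = _pair_frame(bonds)

    def side_probs(side: str) -> list[ResidueBindingProbability]:
        out = []
        for res, grp in pairs.groupby(side, sort=True):
            out.append(
                ResidueBindingProbability(
                    res, side, 1.0 - _survival_product(grp.p.to_numpy()), len(grp)
                )
            )
        return out

    lig = side_probs("ligand")
    rec = side_probs("receptor")
    log_pd = _log_survival(omegas)
    pd_bonds = float(np.exp(log_pd))
    pd_lig = _survival_product(np.array([r.P for r in lig])) if lig else 1.0
    pd_rec = _survival_product(np.array([r.P for r in rec])) if rec else 1.0
    # the three factorizations are one algebraic identity; enforce it
    if abs(pd_lig - pd_rec) > _SIDE_TOL or abs(pd_lig - pd_bonds) > _SIDE_TOL:
        raise AssertionError(
            f"side factorizations disagree: bonds={pd_bonds}, L={pd_lig}, R={pd_rec}"
        )
    P_D = (1.0 - pd_bonds) if as_printed else pd_bonds
    return DissociationResult(
        condition=str(condition),
        P_D=P_D,
        f_D=None,
        log_P_D=log_pd,
        n_bonds=len(bonds),
        expected_bond_count=float(omegas.sum()),
        pair_probabilities=[
            PairProbability(r.ligand, r.receptor, r.p, r.n_bonds)
            for r in pairs.itertuples()
        ],
        ligand_residues=lig,
        receptor_residues=rec,
    )


def complex_dissociation(
    table: OccupancyTable, condition: str | float, as_printed: bool = False
) -> DissociationResult:
    """P_D for one condition; ``as_printed=True`` returns the complement
    (association) form ``1 − Π`` for comparison purposes only."""
    return _condition_result(table, condition, as_printed=as_printed)


def normalized_dissociation(
    table: OccupancyTable,
    force: str | float,
    reference_force: str | float = 0,
) -> DissociationResult:
    """f_D = P_D(force) / P_D(reference_force); f_D(reference) ≡ 1."""
    res = _condition_result(table, force)
    ref = _condition_result(table, reference_force)
    if ref.P_D == 0.0:
        raise ZeroDivisionError(
            f"P_D at reference condition {reference_force!r} is 0; f_D undefined"
        )
    res.f_D = res.P_D / ref.P_D
    return res


def expected_bond_count(table: OccupancyTable, condition: str | float) -> float:
    """Σω over all bonds of a condition — the expected interface bond number
    (equals the trajectory mean of the per-frame bond count)."""
    return float(table.occupancies(condition).sum())


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class DissociationModel:
    """Dissociation-probability model over an occupancy table.

    Parameters
    ----------
    table : OccupancyTable
        Bond occupancies per condition (force level in pN or model label).
    reference : str or float, optional
        Condition used as the zero-force reference for f_D.  When omitted,
        the condition labelled ``"0"`` is used if present; otherwise f_D is
        not computed and P_D values are reported raw.
    as_printed : bool
        Compatibility flag selecting the complement (association) form.

    Examples
    --------
    >>> from mechbond.datasets import load_force_panel
    >>> res = DissociationModel(load_force_panel()).fit()
    >>> round(res.f_D["25"], 3)
    0.059
    """

    def __init__(
        self,
        table: OccupancyTable,
        reference: str | float | None = None,
        as_printed: bool = False,
    ):
        self.table = table
        if reference is None and "0" in table.conditions:
            reference = "0"
        self.reference = None if reference is None else str(reference)
        if self.reference is not None and self.reference not in table.conditions:
            raise KeyError(f"reference condition {self.reference!r} not in table")
        self.as_printed = as_printed

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "DissociationModel":
        return cls(OccupancyTable(frame), **kwargs)

    def fit(self) -> "DissociationResults":
        per_condition = {
            c: _condition_result(self.table, c, as_printed=self.as_printed)
            for c in self.table.conditions
        }
        if self.reference is not None and not self.as_printed:
            ref_pd = per_condition[self.reference].P_D
            if ref_pd > 0:
                for r in per_condition.values():
                    r.f_D = r.P_D / ref_pd
        return DissociationResults(self, per_condition)


class DissociationResults:
    """Fitted per-condition dissociation probabilities and breakdowns."""

    def __init__(self, model: DissociationModel, per_condition: dict[str, DissociationResult]):
        self.model = model
        self.results = per_condition

    @property
    def conditions(self) -> list[str]:
        return list(self.results)

    @property
    def P_D(self) -> dict[str, float]:
        return {c: r.P_D for c, r in self.results.items()}

    @property
    def f_D(self) -> dict[str, float]:
        return {c: r.f_D for c, r in self.results.items() if r.f_D is not None}

    @property
    def expected_bond_counts(self) -> dict[str, float]:
        return {c: r.expected_bond_count for c, r in self.results.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "condition": c,
                "n_bonds": r.n_bonds,
                "sum_occupancy": r.expected_bond_count,
                "P_D": r.P_D,
                "f_D": r.f_D if r.f_D is not None else np.nan,
            }
            for c, r in self.results.items()
        ]
        return pd.DataFrame(rows)

    def residue_frame(self) -> pd.DataFrame:
        rows = []
        for c, r in self.results.items():
            for rb in r.ligand_residues + r.receptor_residues:
                rows.append(
                    {"condition": c, "residue": rb.residue, "side": rb.side,
                     "P": rb.P, "n_partners": rb.n_partners}
                )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        lines = ["Dissociation probability model (independent-bond product form)"]
        if self.model.as_printed:
            lines[0] += " [printed complement form]"
        if self.model.reference is not None:
            lines.append(f"reference condition: {self.model.reference}")
        lines.append("")
        lines.append(f"{'condition':>12} {'n_bonds':>8} {'sum(w)':>8} {'P_D':>12} {'f_D':>10}")
        for c, r in self.results.items():
            fd = f"{r.f_D:10.4g}" if r.f_D is not None else " " * 10
            lines.append(
                f"{c:>12} {r.n_bonds:>8d} {r.expected_bond_count:8.3f} {r.P_D:12.4g} {fd}"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return f"<DissociationResults: {len(self.results)} conditions>"
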