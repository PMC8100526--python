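"""Force-response analysis: per-bond occupancy-vs-force pattern
classification, transition forces, segmented correlations, bond-number
histogram fits, rupture forces from pulling traces, and AFM bond-lifetime
binning with a two-pathway (catch–slip) off-rate fit.

Pattern classification works on the qualitative trend of a value (occupancy
or lifetime) across increasing force levels: consecutive changes within a
tolerance ``epsilon`` are flat and dropped, adjacent equal signs are merged,
and the residual sign sequence is mapped onto the named bond types —
(−) slip, (+,−) catch-slip, (−,+,−) slip-catch-slip, (+,−,+)
catch-slip-catch, empty = insensitive; any other sequence is "other".
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ResponsePattern",
    "ForceTrace",
    "LifetimeRecord",
    "TwoPathwayParams",
    "GaussianFit",
    "SegmentCorrelation",
    "RuptureResult",
    "classify_response",
    "transition_force",
    "segmented_pearson",
    "fit_gaussian_hist",
    "rupture_force",
    "read_force_trace",
    "bin_lifetimes",
    "two_pathway_lifetime",
    "TwoPathwayModel",
    "TwoPathwayResults",
    "fit_two_pathway",
]

#: thermal energy at 310 K in pN·nm
KBT_310K = 4.28

_SIGNATURE_MAP = {
    (): "insensitive",
    (-1,): "slip",
    (1, -1): "catch-slip",
    (-1, 1, -1): "slip-catch-slip",
    (1, -1, 1): "catch-slip-catch",
}


@dataclasses.dataclass
class ResponsePattern:
    key: object  # BondKey or a metric label
    pattern: str
    signature: tuple[int, ...]  # significant change signs, merged
    epsilon: float


def classify_response(
    values: Sequence[float],
    forces: Sequence[float] | None = None,
    epsilon: float = 0.025,
    key: object = None,
) -> ResponsePattern:
    """Classify an occupancy (or lifetime) trend over increasing forces.

    ``forces`` defaults to the value order; when given it must be strictly
    increasing.  At least three force levels are required.
    """
    vals = np.asarray(values, dtype=float)
    if len(vals) < 3:
        raise ValueError("classification needs >=3 force levels")
    if forces is not None:
        f = np.asarray(forces, dtype=float)
        if len(f) != len(vals):
            raise ValueError("forces and values lengths differ")
        if not np.all(np.diff(f) > 0):
            raise ValueError("forces must be strictly increasing")
    diffs = np.diff(vals)
    signs = [int(np.sign(d)) for d in diffs if abs(d) > epsilon]
    merged: list[int] = []
    for s in signs:
        if not merged or merged[-1] != s:
            merged.append(s)
    signature = tuple(merged)
    pattern = _SIGNATURE_MAP.get(signature, "other")
    return ResponsePattern(key=key, pattern=pattern, signature=signature, epsilon=epsilon)


def classify_table(table, epsilon: float = 0.025) -> pd.DataFrame:
    """Classify every bond of an OccupancyTable across its (numeric,
    increasing) force conditions; returns one row per bond with per-force
    occupancies, the signature, and the pattern label."""
    conditions = sorted(table.conditions, key=float)
    forces = [float(c) for c in conditions]
    wide = table.data.pivot_table(
        index=[c for c in table.COLUMNS if c not in ("condition", "occupancy")],
        columns="condition",
        values="occupancy",
        fill_value=0.0,
    )[conditions]
    rows = []
    for idx, occ in wide.iterrows():
        rp = classify_response(occ.to_numpy(), forces, epsilon=epsilon)
        rec = dict(zip(wide.index.names, idx))
        rec.update({f"occ_{c}": v for c, v in zip(conditions, occ)})
        rec["signature"] = "".join("+" if s > 0 else "-" for s in rp.signature)
        rec["pattern"] = rp.pattern
        rec["epsilon"] = epsilon
        rows.append(rec)
    return pd.DataFrame(rows)


@dataclasses.dataclass
class TransitionResult:
    force: float
    value: float
    tied_forces: tuple[float, ...]  # all forces attaining the extreme

    def __float__(self):
        return self.force


def transition_force(
    forces: Sequence[float], values: Sequence[float], mode: str = "min"
) -> TransitionResult:
    """Force at which the series attains its extreme value.

    Ties are broken toward the lowest force, and all tied forces are
    reported.  Invariant under monotone rescaling of the values.
    """
    f = np.asarray(forces, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(f) != len(v):
        raise ValueError("forces and values lengths differ")
    if len(f) < 3:
        raise ValueError("transition detection needs >=3 points")
    if len(np.unique(f)) != len(f):
        raise ValueError("forces must be distinct")
    order = np.argsort(f)
    f, v = f[order], v[order]
    extreme = v.min() if mode == "min" else v.max() if mode == "max" else None
    if extreme is None:
        raise ValueError("mode must be 'min' or 'max'")
    tied = f[v == extreme]
    return TransitionResult(float(tied[0]), float(extreme), tuple(float(x) for x in tied))


@dataclasses.dataclass
class SegmentCorrelation:
    segment: tuple[float, float]
    r: float | None  # None when undefined (constant input)
    n: int
    p_value: float | None
    degenerate: bool  # 2-point segment: r = ±1 by construction


def segmented_pearson(
    forces: Sequence[float], values: Sequence[float], split_force: float
) -> tuple[SegmentCorrelation, SegmentCorrelation]:
    """Pearson r on the segments [min, split] and (split, max].

    Two-point segments are flagged as degenerate (r is ±1 by construction);
    constant segments yield ``r=None`` instead of a NaN crash.
    """
    f = np.asarray(forces, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(f) != len(v):
        raise ValueError("forces and values lengths differ")
    lo = f <= split_force
    hi = f > split_force
    out = []
    for mask in (lo, hi):
        fs, vs = f[mask], v[mask]
        if len(fs) < 2:
            raise ValueError("each segment needs >=2 points")
        seg = (float(fs.min()), float(fs.max()))
        if np.ptp(fs) == 0 or np.ptp(vs) == 0:
            out.append(SegmentCorrelation(seg, None, len(fs), None, len(fs) == 2))
            continue
        r, p = stats.pearsonr(fs, vs)
        out.append(SegmentCorrelation(seg, float(r), len(fs), float(p), len(fs) == 2))
    return out[0], out[1]


@dataclasses.dataclass
class GaussianFit:
    mean: float
    sigma: float
    amplitude: float
    residual_norm: float


def fit_gaussian_hist(counts: Sequence[int]) -> GaussianFit:
    """Least-squares Gaussian on the relative-frequency histogram of an
    integer-valued series (e.g. per-frame interface bond numbers).

    A least-squares fit needs at least three distinct observed values (three
    free parameters); with exactly two distinct values the Gaussian is
    moment-matched instead, and a single value is an error.
    """
    c = np.asarray(counts)
    vals, freq = np.unique(c, return_counts=True)
    if len(vals) < 2:
        raise ValueError("Gaussian fit needs >=2 distinct observed values")
    rel = freq / freq.sum()
    mu0, sd0 = float(c.mean()), float(max(c.std(), 0.5))
    if len(vals) == 2:  # underdetermined for least squares: moment match
        return GaussianFit(mu0, sd0, float(rel.max()), 0.0)

    def gauss(x, amp, mu, sd):
        return amp * np.exp(-((x - mu) ** 2) / (2.0 * sd ** 2))

    popt, _ = optimize.curve_fit(
        gauss, vals.astype(float), rel, p0=[rel.max(), mu0, sd0], maxfev=10000
    )
    amp, mu, sd = popt
    resid = rel - gauss(vals.astype(float), *popt)
    return GaussianFit(float(mu), abs(float(sd)), float(amp), float(np.linalg.norm(resid)))


# ---------------------------------------------------------------------------
# pulling traces
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ForceTrace:
    """A pulling force–time series (time ns, force pN) with optional
    ramp/clamp phase labels."""

    time: np.ndarray
    force: np.ndarray
    phase: np.ndarray | None = None  # "ramp" / "clamp" per sample

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.shape != self.force.shape:
            raise ValueError("time and force lengths differ")
        if len(self.time) and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        if self.phase is not None:
            self.phase = np.asarray(self.phase, dtype=object)
            if self.phase.shape != self.time.shape:
                raise ValueError("phase labels length differs from samples")


@dataclasses.dataclass
class RuptureResult:
    force: float  # pN, peak of the (ramp-phase) force
    time: float  # ns, time of the peak

    def __float__(self):
        return self.force


def rupture_force(trace: ForceTrace) -> RuptureResult:
    """Peak force of the ramp phase (whole trace if phases are unlabeled) —
    the mechanical-strength readout of a constant-velocity pull."""
    if len(trace.time) < 2:
        raise ValueError("rupture detection needs >=2 samples")
    if trace.phase is not None and np.any(trace.phase == "ramp"):
        mask = trace.phase == "ramp"
    else:
        mask = np.ones(len(trace.time), dtype=bool)
    i = int(np.argmax(trace.force[mask]))
    t = trace.time[mask]
    f = trace.force[mask]
    return RuptureResult(float(f[i]), float(t[i]))


def read_force_trace(path: str | Path, sep: str = "\t") -> ForceTrace:
    """Read a two-column (time_ns, force_pN) delimiter-separated trace;
    comment lines starting with '#' are skipped.  A third ``phase`` column
    is honoured when present."""
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.shape[1] < 2:
        raise ValueError("force trace needs two columns: time_ns, force_pN")
    phase = df.iloc[:, 2].to_numpy() if df.shape[1] > 2 else None
    return ForceTrace(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), phase)


# ---------------------------------------------------------------------------
# AFM lifetimes and the two-pathway off-rate
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class LifetimeRecord:
    clamp_force: float  # pN
    lifetime: float  # s

    def __post_init__(self):
        if self.clamp_force < 0 or self.lifetime < 0:
            raise ValueError("force and lifetime must be non-negative")


def bin_lifetimes(
    records: Iterable[LifetimeRecord], bin_width: float = 7.5
) -> pd.DataFrame:
    """Bin single-bond lifetimes by clamp force.

    Bins are left-closed right-open, anchored at 0 pN; empty bins are
    omitted.  Returns columns force_mid, mean_lifetime, sem, n.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    recs = list(records)
    rows: dict[int, list[float]] = {}
    for r in recs:
        rows.setdefault(int(r.clamp_force // bin_width), []).append(r.lifetime)
    out = []
    for b in sorted(rows):
        lt = np.asarray(rows[b])
        sem = float(lt.std(ddof=1) / np.sqrt(len(lt))) if len(lt) > 1 else 0.0
        out.append(
            {
                "force_mid": (b + 0.5) * bin_width,
                "mean_lifetime": float(lt.mean()),
                "sem": sem,
                "n": len(lt),
            }
        )
    return pd.DataFrame(out, columns=["force_mid", "mean_lifetime", "sem", "n"])


@dataclasses.dataclass
class TwoPathwayParams:
    """Two-pathway (catch + slip) off-rate parameters.

    k(f) = k_c·exp(−x_c·f/kBT) + k_s·exp(x_s·f/kBT); lifetime = 1/k(f).
    Rates in 1/s, barrier distances in nm, kBT in pN·nm (default 310 K).
    """

    k_c: float
    x_c: float
    k_s: float
    x_s: float
    kBT: float = KBT_310K

    def __post_init__(self):
        if min(self.k_c, self.x_c, self.k_s, self.x_s, self.kBT) < 0:
            raise ValueError("two-pathway parameters must be non-negative")

    def off_rate(self, force):
        f = np.asarray(force, dtype=float)
        return self.k_c * np.exp(-self.x_c * f / self.kBT) + self.k_s * np.exp(
            self.x_s * f / self.kBT
        )

    def optimum_force(self) -> float:
        """Closed-form argmax of the lifetime curve; 0 for pure slip."""
        if self.k_c == 0 or self.x_c == 0:
            return 0.0
        if self.k_s == 0 or self.x_s == 0:
            return float("inf")
        f = self.kBT / (self.x_c + self.x_s) * np.log(
            (self.k_c * self.x_c) / (self.k_s * self.x_s)
        )
        return float(max(f, 0.0))


def two_pathway_lifetime(force, params: TwoPathwayParams):
    """Mean bond lifetime 1/k(f) under the two-pathway off-rate (s)."""
    return 1.0 / params.off_rate(force)


class TwoPathwayModel:
    """Two-pathway off-rate model for binned force–lifetime data.

    Parameters
    ----------
    binned : DataFrame with force_mid and mean_lifetime columns
        Typically the output of :func:`bin_lifetimes` (>=4 bins).
    kBT : float, pN·nm

    The fit is nonlinear least squares on log-lifetime, which equalises the
    relative weight of the long-lifetime (catch) and short-lifetime (slip)
    regimes.
    """

    def __init__(self, binned: pd.DataFrame, kBT: float = KBT_310K):
        if len(binned) < 4:
            raise ValueError("two-pathway fit needs >=4 force bins")
        self.forces = np.asarray(binned["force_mid"], dtype=float)
        self.lifetimes = np.asarray(binned["mean_lifetime"], dtype=float)
        if np.any(self.lifetimes <= 0):
            raise ValueError("lifetimes must be positive")
        self.kBT = kBT

    @classmethod
    def from_records(
        cls, records: Iterable[LifetimeRecord], bin_width: float = 7.5, kBT: float = KBT_310K
    ) -> "TwoPathwayModel":
        return cls(bin_lifetimes(records, bin_width), kBT=kBT)

    def _log_lifetime(self, f, log_kc, x_c, log_ks, x_s):
        k = np.exp(log_kc) * np.exp(-x_c * f / self.kBT) + np.exp(log_ks) * np.exp(
            x_s * f / self.kBT
        )
        return -np.log(k)

    def fit(self, p0: TwoPathwayParams | None = None) -> "TwoPathwayResults":
        y = np.log(self.lifetimes)
        if p0 is None:
            k0 = 1.0 / self.lifetimes[0]
            k1 = 1.0 / self.lifetimes[-1]
            p0_vec = [np.log(max(k0, 1e-6)), 0.3, np.log(max(k1 / 10, 1e-6)), 0.3]
        else:
            p0_vec = [np.log(max(p0.k_c, 1e-12)), p0.x_c, np.log(max(p0.k_s, 1e-12)), p0.x_s]
        converged = True
        pcov = None
        try:
            popt, pcov = optimize.curve_fit(
                self._log_lifetime,
                self.forces,
                y,
                p0=p0_vec,
                bounds=([-30, 0, -30, 0], [30, 10, 30, 10]),
                maxfev=20000,
            )
        except (RuntimeError, optimize.OptimizeWarning):
            converged = False
            popt = np.asarray(p0_vec, dtype=float)
        params = TwoPathwayParams(
            k_c=float(np.exp(popt[0])), x_c=float(popt[1]),
            k_s=float(np.exp(popt[2])), x_s=float(popt[3]), kBT=self.kBT,
        )
        resid = y - self._log_lifetime(self.forces, *popt)
        return TwoPathwayResults(self, params, resid, converged, pcov)


class TwoPathwayResults:
    """Fitted two-pathway parameters, residuals and the optimum force."""

    def __init__(self, model, params, residuals, converged, pcov):
        self.model = model
        self.params = params
        self.residuals = np.asarray(residuals)
        self.converged = converged
        self.pcov = pcov

    @property
    def optimum_force(self) -> float:
        return self.params.optimum_force()

    @property
    def catch_pathway_negligible(self) -> bool:
        """Flag: the fitted catch term contributes <1% of the zero-force
        off-rate (monotone slip-bond data)."""
        p = self.params
        total0 = p.k_c + p.k_s
        return total0 == 0 or p.k_c / total0 < 0.01

    def predicted_lifetime(self, force):
        return two_pathway_lifetime(force, self.params)

    def bse(self) -> np.ndarray | None:
        """Approximate standard errors of (log k_c, x_c, log k_s, x_s)."""
        if self.pcov is None:
            return None
        return np.sqrt(np.clip(np.diag(self.pcov), 0, None))

    def summary(self) -> str:
        p = self.params
        lines = [
            "Two-pathway catch-slip lifetime fit",
            f"  converged: {self.converged}",
            f"  k_c = {p.k_c:.4g} 1/s   x_c = {p.x_c:.4g} nm",
            f"  k_s = {p.k_s:.4g} 1/s   x_s = {p.x_s:.4g} nm   (kBT = {p.kBT} pN nm)",
            f"  optimum force (lifetime max): {self.optimum_force:.3g} pN",
            f"  residual norm (log-lifetime): {np.linalg.norm(self.residuals):.3g}",
        ]
        if self.catch_pathway_negligible:
            lines.append("  note: catch pathway negligible (pure slip behaviour)")
        return "\n".join(lines)


def fit_two_pathway(binned: pd.DataFrame, kBT: float = KBT_310K) -> TwoPathwayResults:
    """Functional wrapper over :class:`TwoPathwayModel`."""
    return TwoPathwayModel(binned, kBT=kBT).fit()
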