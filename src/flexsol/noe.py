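"""NOE build-up analysis: from NOESY peak intensities to distance restraints.

A NOESY cross peak between proton groups *a* and *b* grows with mixing time
τ; within the initial-rate approximation the normalized intensity is linear,
``I(τ) = σ_ab · τ``, and the build-up rate σ_ab scales with the interproton
distance as r⁻⁶.  Intensities are normalized symmetrically,

    I = sqrt((c_ab · c_ba) / (d_a · d_b)),

with c the cross peaks on either side of the diagonal and d the diagonal
peaks.  The distance follows from a reference proton pair of known
separation (geminal methylene protons, 1.78 Å):

    r_ab = r_ref · (σ_ref / σ_ab)^(1/6).

A restraint is accepted for ensemble deconvolution only if its build-up fit
used at least ``min_points`` mixing times (default 3) with R² at least
``r2_threshold`` (default 0.91).

Optional ³J(HH) scalar couplings are inverted through a user-supplied
Karplus curve ``³J(θ) = A·cos²θ + B·cosθ + C`` into the set of admissible
dihedral angles; no coefficient set is privileged, the triple is a required
input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PeakSeries",
    "BuildupFit",
    "DistanceRestraint",
    "DihedralRestraint",
    "BuildupError",
    "NoSolutionError",
    "R2_THRESHOLD",
    "MIN_MIXING_TIMES",
    "R_REF",
    "normalize_noe",
    "fit_buildup",
    "distance_from_buildup",
    "dihedrals_from_coupling",
    "read_peak_table",
    "restraints_from_peak_table",
    "write_restraint_table",
    "read_restraint_table",
]

# acceptance thresholds for build-up fits
R2_THRESHOLD = 0.91
MIN_MIXING_TIMES = 3
R_REF = 1.78  # Å, geminal methylene reference distance


class BuildupError(ValueError):
    """Raised for degenerate build-up data (no signal, bad diagonals)."""


class NoSolutionError(ValueError):
    """Raised when a coupling constant is outside the Karplus curve's range."""


@dataclass
class PeakSeries:
    """Cross/diagonal NOESY intensities for one proton-group pair across
    mixing times (seconds).  Groups are 0-based atom-index tuples of size
    1 (CH), 2 (CH2) or 3 (CH3)."""

    group_a: tuple[int, ...]
    group_b: tuple[int, ...]
    mixing_times: np.ndarray
    cross_ab: np.ndarray
    cross_ba: np.ndarray
    diag_a: np.ndarray
    diag_b: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("mixing_times", "cross_ab", "cross_ba", "diag_a", "diag_b"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1 or len(arr) < 1 or not np.all(np.isfinite(arr)):
                raise BuildupError(f"{name} must be a finite 1-D series")
            arrays[name] = arr
            setattr(self, name, arr)
        n = len(arrays["mixing_times"])
        if any(len(a) != n for a in arrays.values()):
            raise BuildupError("all intensity series must align with mixing times")


@dataclass(frozen=True)
class BuildupFit:
    """Origin-constrained linear fit of a build-up curve."""

    slope: float  # 1/s
    r_squared: float
    n_points: int


@dataclass
class DistanceRestraint:
    """An experimental interproton distance with its build-up provenance."""

    group_a: tuple[int, ...]
    group_b: tuple[int, ...]
    distance: float  # Å
    source_fit: BuildupFit | None = None
    accepted: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        if self.accepted and not (self.distance > 0):
            raise ValueError("accepted restraint must have positive distance")


@dataclass
class DihedralRestraint:
    """A ³J(HH) coupling and the dihedral angles compatible with it."""

    atom_indices: tuple[int, int, int, int]
    coupling: float  # Hz
    admissible_angles: list[float] = field(default_factory=list)  # degrees


# ---------------------------------------------------------------------------
# Normalization and fitting
# ---------------------------------------------------------------------------


def normalize_noe(p: PeakSeries, single_sided: bool = False) -> pd.DataFrame:
    """Normalize cross-peak intensities against the diagonal peaks.

    Returns a frame with ``mixing_time`` (s) and ``intensity`` columns,
    intensity = sqrt((c_ab·c_ba)/(d_a·d_b)) with the sign of c_ab·c_ba
    preserved.  With ``single_sided`` the square of the ab cross peak is
    used, for peaks observable on one side of the diagonal only.
    """
    if np.any(p.diag_a <= 0) or np.any(p.diag_b <= 0):
        raise BuildupError("diagonal intensities must be positive")
    num = p.cross_ab * p.cross_ab if single_sided else p.cross_ab * p.cross_ba
    intensity = np.sign(num) * np.sqrt(np.abs(num) / (p.diag_a * p.diag_b))
    return pd.DataFrame({"mixing_time": p.mixing_times, "intensity": intensity})


def fit_buildup(points: pd.DataFrame, centered_r2: bool = True) -> BuildupFit:
    """Least-squares line through the origin, ``I = σ·τ``, over the build-up
    points; R² is reported against that origin-constrained model.

    With ``centered_r2`` (default) the total sum of squares is taken about
    the mean intensity; the uncentered alternative uses raw intensities.
    """
    tau = np.asarray(points["mixing_time"], dtype=float)
    inten = np.asarray(points["intensity"], dtype=float)
    if len(tau) < 2 or len(np.unique(tau)) < 2:
        raise BuildupError("need at least 2 distinct mixing times")
    if np.allclose(inten, 0.0):
        raise BuildupError("no build-up: all intensities are zero")
    slope = float(np.dot(tau, inten) / np.dot(tau, tau))
    resid = inten - slope * tau
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.dot(inten - inten.mean(), inten - inten.mean())) if centered_r2 else float(
        np.dot(inten, inten)
    )
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return BuildupFit(slope=slope, r_squared=min(max(r2, 0.0), 1.0), n_points=len(tau))


def distance_from_buildup(
    fit: BuildupFit,
    ref: BuildupFit,
    group_a: tuple[int, ...] = (),
    group_b: tuple[int, ...] = (),
    r_ref: float = R_REF,
    r2_threshold: float = R2_THRESHOLD,
    min_points: int = MIN_MIXING_TIMES,
) -> DistanceRestraint:
    """Convert a build-up rate into a distance via the reference pair.

    A non-positive cross-peak slope (anti-phase artifact) cannot yield a
    distance and produces a rejected restraint carrying the reason.  The
    acceptance flag enforces the minimum number of mixing times and the R²
    threshold on both the pair and the reference fit.
    """
    if ref.slope <= 0:
        raise BuildupError("reference build-up slope must be positive")
    if fit.slope <= 0:
        return DistanceRestraint(
            group_a, group_b, distance=math.nan, source_fit=fit,
            accepted=False, reason="non-positive build-up slope",
        )
    distance = r_ref * (ref.slope / fit.slope) ** (1.0 / 6.0)
    ok = (
        fit.n_points >= min_points
        and ref.n_points >= min_points
        and fit.r_squared >= r2_threshold
        and ref.r_squared >= r2_threshold
    )
    reason = "" if ok else (
        f"requires >= {min_points} mixing times with R^2 >= {r2_threshold}"
    )
    return DistanceRestraint(group_a, group_b, distance, fit, accepted=ok, reason=reason)


# ---------------------------------------------------------------------------
# Karplus inversion
# ---------------------------------------------------------------------------


def dihedrals_from_coupling(
    j: float,
    karplus: tuple[float, float, float],
    tolerance_hz: float = 0.1,
    dedup_deg: float = 1.0,
) -> list[float]:
    """All dihedral angles θ ∈ (−180°, 180°] with ³J(θ) within
    ``tolerance_hz`` of ``j`` under ³J(θ) = A·cos²θ + B·cosθ + C.

    Solved in closed form as a quadratic in cosθ; solutions are deduplicated
    at ``dedup_deg`` resolution.  A coupling outside the curve's attainable
    range raises :class:`NoSolutionError` naming that range.
    """
    a, b, c = karplus
    # attainable range over x = cosθ ∈ [-1, 1]
    candidates = [-1.0, 1.0]
    if abs(a) > 1e-12:
        x_star = -b / (2.0 * a)
        if -1.0 <= x_star <= 1.0:
            candidates.append(x_star)
    values = [a * x * x + b * x + c for x in candidates]
    j_min, j_max = min(values), max(values)
    if not (j_min - tolerance_hz <= j <= j_max + tolerance_hz):
        raise NoSolutionError(
            f"coupling {j:.2f} Hz outside attainable range "
            f"[{j_min:.2f}, {j_max:.2f}] Hz"
        )

    roots: list[float] = []
    if abs(a) < 1e-12:
        if abs(b) > 1e-12:
            roots.append((j - c) / b)
    else:
        disc = b * b - 4.0 * a * (c - j)
        if disc >= 0:
            sq = math.sqrt(disc)
            roots.extend([(-b + sq) / (2 * a), (-b - sq) / (2 * a)])
    angles: list[float] = []
    for x in roots:
        x = min(1.0, max(-1.0, x))
        th = math.degrees(math.acos(x))
        for cand in (th, -th):
            if cand == -180.0:
                cand = 180.0
            if abs(a * x * x + b * x + c - j) <= tolerance_hz and all(
                abs(cand - prev) >= dedup_deg for prev in angles
            ):
                angles.append(cand)
    return sorted(angles)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def _parse_group(text: str) -> tuple[int, ...]:
    """Proton groups in tables are 1-based indices joined by '+': "17+18"."""
    try:
        idx = tuple(int(tok) - 1 for tok in str(text).split("+"))
    except ValueError as exc:
        raise ValueError(f"bad proton group {text!r}") from exc
    if not 1 <= len(idx) <= 3 or any(i < 0 for i in idx):
        raise ValueError(f"bad proton group {text!r}")
    return idx


def _format_group(group: tuple[int, ...]) -> str:
    return "+".join(str(i + 1) for i in group)


def read_peak_table(path: str | Path) -> list[PeakSeries]:
    """Read a delimited peak table with columns group_a, group_b, tau_mix_ms,
    cross_ab, cross_ba, diag_a, diag_b (one row per pair per mixing time)."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"group_a", "group_b", "tau_mix_ms", "cross_ab", "cross_ba", "diag_a", "diag_b"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    out = []
    for (ga, gb), sub in df.groupby(["group_a", "group_b"], sort=False):
        sub = sub.sort_values("tau_mix_ms")
        out.append(
            PeakSeries(
                group_a=_parse_group(ga),
                group_b=_parse_group(gb),
                mixing_times=sub["tau_mix_ms"].to_numpy(dtype=float) / 1000.0,
                cross_ab=sub["cross_ab"].to_numpy(dtype=float),
                cross_ba=sub["cross_ba"].to_numpy(dtype=float),
                diag_a=sub["diag_a"].to_numpy(dtype=float),
                diag_b=sub["diag_b"].to_numpy(dtype=float),
            )
        )
    return out


def restraints_from_peak_table(
    series: list[PeakSeries],
    reference_pair: tuple[tuple[int, ...], tuple[int, ...]],
    r_ref: float = R_REF,
    r2_threshold: float = R2_THRESHOLD,
    min_points: int = MIN_MIXING_TIMES,
    single_sided: bool = False,
) -> list[DistanceRestraint]:
    """Full build-up pipeline over a peak table: normalize every series, fit
    the reference pair, then convert every other pair into a distance
    restraint with acceptance flags."""
    ref_fit = None
    fits: list[tuple[PeakSeries, BuildupFit]] = []
    for p in series:
        fit = fit_buildup(normalize_noe(p, single_sided=single_sided))
        key = (p.group_a, p.group_b)
        if key == reference_pair or key == reference_pair[::-1]:
            ref_fit = fit
        else:
            fits.append((p, fit))
    if ref_fit is None:
        raise ValueError("reference pair not present in peak table")
    return [
        distance_from_buildup(
            fit, ref_fit, p.group_a, p.group_b,
            r_ref=r_ref, r2_threshold=r2_threshold, min_points=min_points,
        )
        for p, fit in fits
    ]


def write_restraint_table(restraints: list[DistanceRestraint], path: str | Path) -> None:
    rows = []
    for r in restraints:
        fit = r.source_fit
        rows.append(
            {
                "group_a": _format_group(r.group_a),
                "group_b": _format_group(r.group_b),
                "distance_A": r.distance,
                "slope_per_s": fit.slope if fit else np.nan,
                "r_squared": fit.r_squared if fit else np.nan,
                "n_points": fit.n_points if fit else 0,
                "accepted": r.accepted,
                "reason": r.reason,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_restraint_table(path: str | Path) -> list[DistanceRestraint]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        fit = BuildupFit(
            slope=float(row["slope_per_s"]),
            r_squared=float(row["r_squared"]),
            n_points=int(row["n_points"]),
        )
        out.append(
            DistanceRestraint(
                group_a=_parse_group(row["group_a"]),
                group_b=_parse_group(row["group_b"]),
                distance=float(row["distance_A"]),
                source_fit=fit,
                accepted=bool(row["accepted"]),
                reason="" if pd.isna(row.get("reason")) else str(row.get("reason", "")),
            )
        )
    return out
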