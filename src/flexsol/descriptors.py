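"""Conformation-level 3D descriptors: radius of gyration, solvent-accessible
surface area, and solvent-accessible 3D polar surface area (SA 3D PSA).

Chameleonic molecules hide polarity by folding: their compact conformations
bury N/O/polar-H surface that extended conformations expose.  Per-conformer
size is measured by the mass-weighted radius of gyration and polarity by the
SA 3D PSA — the solvent-accessible area summed over all polar atoms (O, N,
and H bonded to either), computed with a 1.4 Å water probe.  Ensemble-level
values are population-weighted means over the conformer weights.

The SASA engine is a Shrake–Rupley implementation sampling each atomic
sphere (van der Waals radius + probe) with a deterministic golden-section
spiral, so areas are reproducible bit-for-bit at a fixed point count.
van der Waals radii default to the Bondi set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem import Conformation, FragmentMap

__all__ = [
    "BONDI_RADII",
    "SasaParams",
    "DescriptorRecord",
    "radius_of_gyration",
    "sphere_points",
    "shrake_rupley_sasa",
    "sa3d_psa",
    "weighted_ensemble_descriptors",
]

_PT = Chem.GetPeriodicTable()

# Bondi (1964) van der Waals radii, Å
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "P": 1.80, "S": 1.80, "Cl": 1.75, "Br": 1.85, "I": 1.98,
    "B": 1.92, "Si": 2.10, "Se": 1.90,
}


@dataclass
class SasaParams:
    probe_radius: float = 1.4  # Å, water probe
    n_sphere_points: int = 960
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(BONDI_RADII))

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe radius must be non-negative")
        if self.n_sphere_points < 24:
            raise ValueError("need at least 24 sphere points")


@dataclass
class DescriptorRecord:
    """Per-conformer descriptor row; interaction counts are filled in by the
    interactions module."""

    conformer_id: str
    weight: float
    rgyr: float  # Å
    sasa_total: float  # Å^2
    sa3dpsa_total: float  # Å^2
    sa3dpsa_by_fragment: dict[str, float] = field(default_factory=dict)
    imhb_count: int = 0
    pipi_count: int = 0
    nhpi_count: int = 0


def radius_of_gyration(c: Conformation, mass_weighted: bool = True) -> float:
    """√(Σ m_i |r_i − r_cm|² / Σ m_i) with r_cm the (mass-weighted) centroid;
    unit masses when ``mass_weighted`` is false."""
    coords = c.coords
    if mass_weighted:
        masses = np.array([_PT.GetAtomicWeight(a.element) for a in c.atoms])
    else:
        masses = np.ones(len(coords))
    cm = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    sq = ((coords - cm) ** 2).sum(axis=1)
    return float(np.sqrt(np.dot(masses, sq) / masses.sum()))


def sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-section spiral of ``n`` points on the unit sphere."""
    k = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k  # golden angle increments
    z = 1.0 - 2.0 * (k + 0.5) / n
    rho = np.sqrt(np.maximum(1.0 - z * z, 0.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_sasa(c: Conformation, params: SasaParams | None = None) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²) by Shrake–Rupley point
    sampling on each expanded sphere of radius r_vdw + probe."""
    p = params or SasaParams()
    if not c.has_explicit_h():
        raise ValueError(
            "structure lacks explicit hydrogens; SASA on heavy atoms only "
            "would misstate polar surface — add explicit H to the input"
        )
    try:
        radii = np.array([p.vdw_radii[a.element] for a in c.atoms])
    except KeyError as exc:
        raise ValueError(f"no van der Waals radius for element {exc.args[0]!r}") from exc
    radii = radii + p.probe_radius
    coords = c.coords
    unit = sphere_points(p.n_sphere_points)
    n = len(coords)

    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=-1)
    areas = np.empty(n)
    for i in range(n):
        # neighbors whose expanded spheres can occlude atom i's surface
        cut = (radii[i] + radii) ** 2
        nbr = np.flatnonzero((d2[i] < cut) & (np.arange(n) != i))
        pts = coords[i] + radii[i] * unit
        if len(nbr):
            dist2 = ((pts[:, None, :] - coords[nbr][None, :, :]) ** 2).sum(axis=-1)
            buried = (dist2 < (radii[nbr] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = frac * 4.0 * np.pi * radii[i] ** 2
    return areas


def _polar_atom_indices(c: Conformation) -> list[int]:
    out = []
    for i, a in enumerate(c.atoms):
        if a.element in ("N", "O") or (a.element == "H" and c.is_polar_h(i)):
            out.append(i)
    return out


def sa3d_psa(
    c: Conformation,
    sasa: np.ndarray,
    fragments: FragmentMap | None = None,
) -> tuple[float, dict[str, float]]:
    """Solvent-accessible 3D polar surface area: the SASA summed over all
    polar atoms (O, N, and H attached to O/N).  With a fragment map, also
    returns per-fragment totals, which sum to the total."""
    sasa = np.asarray(sasa, dtype=float)
    if len(sasa) != c.n_atoms:
        raise ValueError("SASA vector misaligned with conformation")
    polar = _polar_atom_indices(c)
    total = float(sasa[polar].sum()) if polar else 0.0
    by_fragment: dict[str, float] = {}
    if fragments is not None:
        if len(fragments.labels) != c.n_atoms:
            raise ValueError("fragment map misaligned with conformation")
        for i in polar:
            lab = fragments.labels[i]
            by_fragment[lab] = by_fragment.get(lab, 0.0) + float(sasa[i])
    return total, by_fragment


def weighted_ensemble_descriptors(
    records: list[DescriptorRecord], weights: np.ndarray | None = None
) -> dict:
    """Population-weighted means of the numeric descriptors plus the
    per-conformer spread (min, max) of each."""
    if weights is None:
        weights = np.array([r.weight for r in records], dtype=float)
    else:
        weights = np.asarray(weights, dtype=float)
    if len(weights) != len(records):
        raise ValueError("weights misaligned with records")
    if abs(weights.sum() - 1.0) > 1e-6 or np.any(weights < -1e-12):
        raise ValueError("weights must lie on the probability simplex")

    out: dict = {}
    for name in ("rgyr", "sasa_total", "sa3dpsa_total", "imhb_count", "pipi_count", "nhpi_count"):
        vals = np.array([getattr(r, name) for r in records], dtype=float)
        out[name] = {
            "weighted_mean": float(np.dot(weights, vals)),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    labels = sorted({lab for r in records for lab in r.sa3dpsa_by_fragment})
    for lab in labels:
        vals = np.array([r.sa3dpsa_by_fragment.get(lab, 0.0) for r in records])
        out[f"sa3dpsa_{lab}"] = {
            "weighted_mean": float(np.dot(weights, vals)),
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return out
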