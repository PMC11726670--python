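"""Geometric detection of intramolecular interactions per conformation:
hydrogen bonds (IMHB), π–π stacking, and NH–π contacts.

All criteria are explicit, tunable thresholds (literature-typical defaults)
so that counts are reproducible; nothing is delegated to opaque defaults.
Aromatic rings are taken from file aromaticity flags when present (aromatic
bond orders), otherwise perceived as planar five- or six-membered cycles of
sp2-compatible atoms.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .chem import Conformation

__all__ = [
    "InteractionCriteria",
    "InteractionRecord",
    "AromaticRing",
    "find_rings",
    "detect_imhb",
    "detect_pipi",
    "detect_nhpi",
    "detect_all",
    "interaction_counts",
]


@dataclass
class InteractionCriteria:
    """Distance (Å) and angle (deg) thresholds for each interaction type."""

    hbond_h_acceptor_max: float = 2.5
    hbond_dha_min_angle: float = 120.0
    hbond_min_bond_separation: int = 3
    pipi_centroid_max: float = 5.5
    pipi_interplane_max_angle: float = 30.0  # face-to-face window [0, max]
    pipi_edge_window: tuple[float, float] = (60.0, 90.0)  # edge-to-face
    nhpi_h_centroid_max: float = 3.5
    nhpi_approach_min_angle: float = 120.0
    nhpi_lateral_max_factor: float = 1.5  # × ring circumradius, in-plane offset

    def __post_init__(self) -> None:
        for name in ("hbond_h_acceptor_max", "pipi_centroid_max", "nhpi_h_centroid_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("hbond_dha_min_angle", "pipi_interplane_max_angle", "nhpi_approach_min_angle"):
            if not 0.0 <= getattr(self, name) <= 180.0:
                raise ValueError(f"{name} must be within [0, 180] degrees")


@dataclass(frozen=True)
class AromaticRing:
    atoms: tuple[int, ...]
    centroid: tuple[float, float, float]
    normal: tuple[float, float, float]
    circumradius: float


@dataclass
class InteractionRecord:
    kind: str  # "imhb" | "pipi" | "nhpi"
    atoms: tuple[int, ...]  # participating atom ids (donor D,H,A or ring atoms)
    geometry: dict = field(default_factory=dict)


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    cosv = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(min(1.0, max(-1.0, cosv))))


# ---------------------------------------------------------------------------
# Ring perception
# ---------------------------------------------------------------------------

_RING_ELEMENTS = {"C", "N", "O", "S"}
_PLANARITY_RMS_MAX = 0.10  # Å, RMS out-of-plane deviation of ring atoms


def find_rings(c: Conformation) -> list[AromaticRing]:
    """Aromatic 5/6-membered rings with centroid and SVD plane-fit normal.

    A cycle counts as aromatic if all its bonds carry aromatic flags from
    the input file, or failing that, if every ring atom is sp2-compatible
    (C/N/O/S with at most 3 connections) and the ring is planar.
    """
    g = c.graph()
    order = {frozenset((i, j)): o for i, j, o in c.bonds}
    coords = c.coords
    rings: list[AromaticRing] = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        ring_bonds = [
            frozenset((cycle[k], cycle[(k + 1) % len(cycle)])) for k in range(len(cycle))
        ]
        if not all(b in order for b in ring_bonds):
            continue
        flagged_aromatic = all(order[b] == 1.5 for b in ring_bonds)
        if not flagged_aromatic:
            ok = all(
                c.atoms[i].element in _RING_ELEMENTS and len(c.neighbors(i)) <= 3
                for i in cycle
            )
            if not ok:
                continue
        pts = coords[cycle]
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        _, s, vt = np.linalg.svd(centered)
        normal = vt[2]
        rms_dev = float(np.sqrt(np.mean((centered @ normal) ** 2)))
        if not flagged_aromatic and rms_dev > _PLANARITY_RMS_MAX:
            continue
        rings.append(
            AromaticRing(
                atoms=tuple(sorted(cycle)),
                centroid=tuple(map(float, centroid)),
                normal=tuple(map(float, normal / np.linalg.norm(normal))),
                circumradius=float(np.linalg.norm(centered, axis=1).max()),
            )
        )
    return rings


# ---------------------------------------------------------------------------
# Donors / acceptors
# ---------------------------------------------------------------------------


def _nh_oh_donors(c: Conformation) -> list[tuple[int, int]]:
    """(donor heavy atom, hydrogen) pairs for N–H and O–H groups."""
    out = []
    for i, a in enumerate(c.atoms):
        if a.element in ("N", "O"):
            for j in c.neighbors(i):
                if c.atoms[j].element == "H":
                    out.append((i, j))
    return out


def detect_imhb(c: Conformation, criteria: InteractionCriteria | None = None) -> list[InteractionRecord]:
    """Intramolecular hydrogen bonds: N–H/O–H donors to N/O acceptors with
    H···A within the cutoff, D–H···A at least the minimum angle, and donor
    and acceptor at least 3 bonds apart (sulfur is not an acceptor)."""
    crit = criteria or InteractionCriteria()
    if not c.has_explicit_h():
        raise ValueError("IMHB detection requires explicit hydrogens")
    coords = c.coords
    g = c.graph()
    sep = dict(nx.all_pairs_shortest_path_length(g))
    acceptors = [i for i, a in enumerate(c.atoms) if a.element in ("N", "O")]
    out = []
    for d, h in _nh_oh_donors(c):
        for acc in acceptors:
            if acc == d or sep[d].get(acc, 10 ** 9) < crit.hbond_min_bond_separation:
                continue
            ha = float(np.linalg.norm(coords[acc] - coords[h]))
            if ha > crit.hbond_h_acceptor_max:
                continue
            # D-H...A angle measured at H; linear = 180
            ang = _angle_deg(coords[d] - coords[h], coords[acc] - coords[h])
            if ang < crit.hbond_dha_min_angle:
                continue
            out.append(
                InteractionRecord(
                    "imhb", (d, h, acc),
                    {"h_acceptor_distance": ha, "dha_angle": ang},
                )
            )
    return out


def detect_pipi(c: Conformation, criteria: InteractionCriteria | None = None) -> list[InteractionRecord]:
    """π–π contacts: aromatic ring pairs with centroid distance within the
    cutoff and interplane angle in the face-to-face window ([0, max]) or the
    edge-to-face window."""
    crit = criteria or InteractionCriteria()
    rings = find_rings(c)
    out = []
    for r1, r2 in itertools.combinations(rings, 2):
        if set(r1.atoms) & set(r2.atoms):
            continue
        dist = float(np.linalg.norm(np.array(r1.centroid) - np.array(r2.centroid)))
        if dist > crit.pipi_centroid_max:
            continue
        ang = _angle_deg(np.array(r1.normal), np.array(r2.normal))
        ang = min(ang, 180.0 - ang)  # plane angle, [0, 90]
        lo, hi = crit.pipi_edge_window
        face = ang <= crit.pipi_interplane_max_angle
        edge = lo <= ang <= hi
        if not (face or edge):
            continue
        out.append(
            InteractionRecord(
                "pipi", r1.atoms + r2.atoms,
                {
                    "centroid_distance": dist,
                    "interplane_angle": ang,
                    "geometry_class": "face_to_face" if face else "edge_to_face",
                },
            )
        )
    return out


def detect_nhpi(c: Conformation, criteria: InteractionCriteria | None = None) -> list[InteractionRecord]:
    """NH–π contacts: an N–H hydrogen within the cutoff of an aromatic ring
    centroid, approaching along the ring normal (N–H···centroid angle at H of
    at least the minimum) with its in-plane projection inside 1.5× the ring
    circumradius."""
    crit = criteria or InteractionCriteria()
    coords = c.coords
    rings = find_rings(c)
    out = []
    for d, h in _nh_oh_donors(c):
        if c.atoms[d].element != "N":
            continue
        for ring in rings:
            if d in ring.atoms or h in ring.atoms:
                continue
            centroid = np.array(ring.centroid)
            hc = float(np.linalg.norm(centroid - coords[h]))
            if hc > crit.nhpi_h_centroid_max:
                continue
            approach = _angle_deg(coords[d] - coords[h], centroid - coords[h])
            if approach < crit.nhpi_approach_min_angle:
                continue
            normal = np.array(ring.normal)
            offset = coords[h] - centroid
            lateral = float(np.linalg.norm(offset - np.dot(offset, normal) * normal))
            if lateral > crit.nhpi_lateral_max_factor * ring.circumradius:
                continue
            out.append(
                InteractionRecord(
                    "nhpi", (d, h) + ring.atoms,
                    {
                        "h_centroid_distance": hc,
                        "approach_angle": approach,
                        "lateral_offset": lateral,
                    },
                )
            )
    return out


def detect_all(c: Conformation, criteria: InteractionCriteria | None = None) -> list[InteractionRecord]:
    crit = criteria or InteractionCriteria()
    return detect_imhb(c, crit) + detect_pipi(c, crit) + detect_nhpi(c, crit)


def interaction_counts(records: list[InteractionRecord]) -> dict[str, int]:
    counts = {"imhb": 0, "pipi": 0, "nhpi": 0}
    for rec in records:
        counts[rec.kind] += 1
    return counts
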