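"""Molecular structure model: conformations, ensembles, file I/O, and
redundancy elimination.

A flexible molecule in solution is represented as a :class:`ConformerEnsemble`
— an ordered pool of rigid 3D geometries (:class:`Conformation`) sharing one
bond graph and atom ordering, optionally carrying population weights on the
probability simplex.  Pools typically come from an external conformational
search written as multi-record SDF, multi-MODEL PDB, or concatenated XYZ.

Redundant pool members are removed by greedy leader clustering on the
heavy-atom RMSD (Kabsch superposition by default), and the completeness of a
random conformational search is estimated from the standard coupon-collector
style bound ``1 - (1 - 1/N)**M``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Geometry import Point3D

__all__ = [
    "Atom",
    "Conformation",
    "ConformerEnsemble",
    "FragmentMap",
    "EnsembleFormatError",
    "PartitionError",
    "read_ensemble",
    "write_sdf",
    "heavy_atom_rmsd",
    "eliminate_redundant",
    "search_completeness",
    "assign_fragments",
]

_PT = Chem.GetPeriodicTable()

POI_LIGAND = "POI_ligand"
LINKER = "linker"
E3_LIGAND = "E3_ligand"
FRAGMENT_LABELS = (POI_LIGAND, LINKER, E3_LIGAND)


class EnsembleFormatError(ValueError):
    """Raised for unreadable or internally inconsistent structure files."""


class PartitionError(ValueError):
    """Raised when a linker designation does not split a molecule in two."""


@dataclass(frozen=True)
class Atom:
    """One atom: element symbol, Cartesian coordinates in Å, formal charge."""

    element: str
    coords: tuple[float, float, float]
    formal_charge: int = 0

    def __post_init__(self) -> None:
        try:
            ok = _PT.GetAtomicNumber(self.element) > 0
        except RuntimeError:
            ok = False
        if not ok:
            raise EnsembleFormatError(f"unknown element {self.element!r}")
        if not all(math.isfinite(x) for x in self.coords):
            raise EnsembleFormatError(f"non-finite coordinates for {self.element}")


@dataclass
class Conformation:
    """A single rigid 3D geometry of a molecule.

    ``bonds`` are ``(i, j, order)`` triples over 0-based atom indices with
    order 1, 2, 3 or 1.5 (aromatic).  All conformations of one ensemble share
    the same atoms and bonds in the same order.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, float]] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise EnsembleFormatError(
                    f"bond ({i}, {j}) out of range for {n} atoms"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.element != "H"], dtype=int
        )

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from((i, j) for i, j, _ in self.bonds)
        return g

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b, _ in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def is_polar_h(self, i: int) -> bool:
        """True for a hydrogen bonded to nitrogen or oxygen."""
        if self.atoms[i].element != "H":
            return False
        return any(self.atoms[j].element in ("N", "O") for j in self.neighbors(i))

    def has_explicit_h(self) -> bool:
        return any(a.element == "H" for a in self.atoms)

    def with_coords(self, coords: np.ndarray, conf_id: str | None = None) -> "Conformation":
        atoms = [
            Atom(a.element, tuple(map(float, xyz)), a.formal_charge)
            for a, xyz in zip(self.atoms, np.asarray(coords, dtype=float))
        ]
        return Conformation(atoms, list(self.bonds), conf_id if conf_id is not None else self.id)


@dataclass
class ConformerEnsemble:
    """Ordered conformer pool of one molecule, optionally population-weighted."""

    conformations: list[Conformation]
    weights: np.ndarray | None = None
    molecule_id: str = ""

    def __post_init__(self) -> None:
        if not self.conformations:
            raise EnsembleFormatError("ensemble must contain at least one conformer")
        ref = self.conformations[0].elements
        for k, c in enumerate(self.conformations[1:], start=2):
            if c.elements != ref:
                raise EnsembleFormatError(
                    f"record {k} has inconsistent atoms "
                    f"({c.n_atoms} vs {len(ref)} in record 1)"
                )
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != len(self.conformations):
                raise ValueError("weights length must match conformer count")
            if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("weights must be non-negative and sum to 1")
            self.weights = w

    def __len__(self) -> int:
        return len(self.conformations)

    def __iter__(self):
        return iter(self.conformations)

    def __getitem__(self, k: int) -> Conformation:
        return self.conformations[k]

    @property
    def n_atoms(self) -> int:
        return self.conformations[0].n_atoms

    def subset(self, indices: Sequence[int], weights: np.ndarray | None = None) -> "ConformerEnsemble":
        return ConformerEnsemble(
            [self.conformations[i] for i in indices], weights, self.molecule_id
        )


@dataclass
class FragmentMap:
    """Per-atom fragment labels partitioning a heterobifunctional molecule
    into POI ligand, linker and E3 ligand; hydrogens carry the label of the
    heavy atom they are bonded to."""

    labels: list[str]

    def __post_init__(self) -> None:
        bad = set(self.labels) - set(FRAGMENT_LABELS)
        if bad:
            raise ValueError(f"unknown fragment labels: {sorted(bad)}")

    def atoms_with_label(self, label: str) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab == label]


# ---------------------------------------------------------------------------
# RDKit bridge and file I/O
# ---------------------------------------------------------------------------

_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}
_ORDER_BOND = {v: k for k, v in _BOND_ORDER.items()}


def conformation_from_rdkit(mol: Chem.Mol, conf_id: int = -1, record_id: str = "") -> Conformation:
    conf = mol.GetConformer(conf_id)
    atoms = []
    for a in mol.GetAtoms():
        p = conf.GetAtomPosition(a.GetIdx())
        atoms.append(Atom(a.GetSymbol(), (p.x, p.y, p.z), a.GetFormalCharge()))
    bonds = [
        (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), _BOND_ORDER.get(b.GetBondType(), 1.0))
        for b in mol.GetBonds()
    ]
    return Conformation(atoms, bonds, record_id)


def rdkit_from_conformation(c: Conformation) -> Chem.Mol:
    em = Chem.RWMol()
    for a in c.atoms:
        at = Chem.Atom(a.element)
        at.SetFormalCharge(a.formal_charge)
        at.SetNoImplicit(True)
        em.AddAtom(at)
    for i, j, order in c.bonds:
        em.AddBond(i, j, _ORDER_BOND.get(order, Chem.BondType.SINGLE))
    mol = em.GetMol()
    conf = Chem.Conformer(c.n_atoms)
    for i, a in enumerate(c.atoms):
        conf.SetAtomPosition(i, Point3D(*a.coords))
    mol.AddConformer(conf, assignId=True)
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_FINDRADICALS)
    mol.UpdatePropertyCache(strict=False)
    return mol


def _read_sdf(path: Path) -> list[Conformation]:
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    out = []
    for k, mol in enumerate(supplier, start=1):
        if mol is None:
            raise EnsembleFormatError(f"{path}: unparseable SDF record {k}")
        mol.UpdatePropertyCache(strict=False)
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        out.append(conformation_from_rdkit(mol, record_id=name or f"conf_{k}"))
    return out


def _read_pdb(path: Path) -> list[Conformation]:
    mol = Chem.MolFromPDBFile(str(path), sanitize=False, removeHs=False)
    if mol is None or mol.GetNumConformers() == 0:
        raise EnsembleFormatError(f"{path}: unparseable PDB file")
    mol.UpdatePropertyCache(strict=False)
    return [
        conformation_from_rdkit(mol, conf_id=conf.GetId(), record_id=f"model_{k}")
        for k, conf in enumerate(mol.GetConformers(), start=1)
    ]


def _read_xyz(path: Path) -> list[Conformation]:
    # concatenated XYZ: each frame is "natoms\ncomment\n<atom lines>"
    lines = Path(path).read_text().splitlines()
    out: list[Conformation] = []
    pos, k = 0, 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        k += 1
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise EnsembleFormatError(f"{path}: bad XYZ frame header at line {pos + 1}") from exc
        block = lines[pos : pos + n + 2]
        if len(block) < n + 2:
            raise EnsembleFormatError(f"{path}: truncated XYZ record {k}")
        mol = Chem.MolFromXYZBlock("\n".join(block) + "\n")
        if mol is None:
            raise EnsembleFormatError(f"{path}: unparseable XYZ record {k}")
        out.append(conformation_from_rdkit(mol, record_id=f"frame_{k}"))
        pos += n + 2
    return out


def read_ensemble(path: str | Path, format: str | None = None) -> ConformerEnsemble:
    """Read a multi-conformer structure file (SDF, PDB or XYZ).

    All records must contain the same atoms in the same order; the first
    offending record is named otherwise.  Weights are never read from the
    file — a freshly read pool is unweighted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    readers = {"sdf": _read_sdf, "sd": _read_sdf, "pdb": _read_pdb, "xyz": _read_xyz}
    if fmt not in readers:
        raise EnsembleFormatError(f"unsupported format {fmt!r}")
    confs = readers[fmt](path)
    return ConformerEnsemble(confs, molecule_id=path.stem)


def write_sdf(ensemble: ConformerEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-record V2000 SDF; population weights, if
    present, are stored in a ``weight`` data field per record."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for k, c in enumerate(ensemble):
            mol = rdkit_from_conformation(c)
            mol.SetProp("_Name", c.id or f"conf_{k + 1}")
            if ensemble.weights is not None:
                mol.SetProp("weight", f"{ensemble.weights[k]:.6f}")
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# RMSD and redundancy elimination
# ---------------------------------------------------------------------------


def _kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    diff = pc @ rot.T - qc
    return float(np.sqrt((diff * diff).sum() / len(p)))


def heavy_atom_rmsd(a: Conformation, b: Conformation, superpose: bool = True) -> float:
    """Heavy-atom RMSD between two conformations of the same molecule, after
    optimal rigid-body (Kabsch) superposition when ``superpose`` is true."""
    if a.elements != b.elements:
        raise ValueError("conformations have different atoms/ordering")
    idx = a.heavy_indices
    p = a.coords[idx]
    q = b.coords[idx]
    if superpose:
        if len(idx) < 3:
            raise ValueError("superposition needs at least 3 heavy atoms")
        return _kabsch_rmsd(p, q)
    diff = p - q
    return float(np.sqrt((diff * diff).sum() / len(p)))


def eliminate_redundant(
    e: ConformerEnsemble, cutoff: float = 3.0, superpose: bool = True
) -> ConformerEnsemble:
    """Redundant conformational elimination: greedy leader clustering in input
    order.  Conformer *i* is kept iff its heavy-atom RMSD to every previously
    kept conformer is ≥ ``cutoff`` (Å).  Representatives therefore depend on
    input order; pools from energy-ranked searches keep lowest-energy leaders.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    kept: list[int] = []
    for i, c in enumerate(e):
        if all(
            heavy_atom_rmsd(c, e[j], superpose=superpose) >= cutoff for j in kept
        ):
            kept.append(i)
    return e.subset(kept)


def search_completeness(n_conformers: int, n_steps: int) -> float:
    """Probability that a random search of ``n_steps`` steps over a pool of
    ``n_conformers`` distinct minima has visited any given one:
    ``1 - (1 - 1/N)**M``."""
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    return 1.0 - (1.0 - 1.0 / n_conformers) ** n_steps


# ---------------------------------------------------------------------------
# Fragment partitioning
# ---------------------------------------------------------------------------


def assign_fragments(
    c: Conformation,
    linker_atom_ids: Iterable[int],
    poi_contains: int | None = None,
) -> FragmentMap:
    """Partition a heterobifunctional molecule into POI ligand / linker / E3
    ligand given the heavy-atom indices of the linker (0-based).

    Removing the linker atoms from the heavy-atom bond graph must leave
    exactly two connected components.  ``poi_contains`` names one atom of the
    POI-side component; by default the component holding the lowest atom
    index is labelled POI.  Hydrogens inherit the label of their heavy atom.
    """
    linker = set(int(i) for i in linker_atom_ids)
    heavy = set(int(i) for i in c.heavy_indices)
    if not linker or not linker.issubset(heavy):
        raise PartitionError("linker atom ids must be a non-empty set of heavy atoms")

    g = c.graph().subgraph(heavy).copy()
    if not nx.is_connected(g.subgraph(linker)):
        raise PartitionError("linker atoms do not form a connected subgraph")
    g.remove_nodes_from(linker)
    comps = [set(comp) for comp in nx.connected_components(g)]
    if len(comps) != 2:
        raise PartitionError(
            f"removing linker atoms leaves {len(comps)} components, expected 2"
        )
    comps.sort(key=min)
    if poi_contains is not None:
        if poi_contains in comps[1]:
            comps = [comps[1], comps[0]]
        elif poi_contains not in comps[0]:
            raise PartitionError(f"atom {poi_contains} is not in either ligand component")
    poi, e3 = comps

    labels = [""] * c.n_atoms
    for i in linker:
        labels[i] = LINKER
    for i in poi:
        labels[i] = POI_LIGAND
    for i in e3:
        labels[i] = E3_LIGAND
    for i, a in enumerate(c.atoms):
        if a.element == "H":
            nbrs = c.neighbors(i)
            if not nbrs:
                raise PartitionError(f"hydrogen {i} has no bonded heavy atom")
            labels[i] = labels[nbrs[0]]
    return FragmentMap(labels)
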