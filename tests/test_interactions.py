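"""Interaction detection: ring perception, constructed ideal geometries,
planted-contact recovery, and criterion-tightening monotonicity."""

import math

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from flexsol.chem import Atom, Conformation, conformation_from_rdkit
from flexsol.interactions import (
    InteractionCriteria,
    detect_all,
    detect_imhb,
    detect_nhpi,
    detect_pipi,
    find_rings,
)


def _benzene(center=(0.0, 0.0, 0.0), z=0.0, radius=1.39, with_h=True, start=0):
    atoms, bonds = [], []
    cx, cy, _ = center
    for k in range(6):
        ang = math.pi * k / 3
        atoms.append(Atom("C", (cx + radius * math.cos(ang), cy + radius * math.sin(ang), z)))
    for k in range(6):
        bonds.append((start + k, start + (k + 1) % 6, 1.5))
    if with_h:
        for k in range(6):
            ang = math.pi * k / 3
            atoms.append(
                Atom("H", (cx + (radius + 1.09) * math.cos(ang), cy + (radius + 1.09) * math.sin(ang), z))
            )
            bonds.append((start + k, start + 6 + k, 1.0))
    return atoms, bonds


def _embedded(smiles):
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = 7
    AllChem.EmbedMolecule(mol, params)
    return conformation_from_rdkit(mol)


class TestFindRings:
    def test_benzene_single_ring(self):
        atoms, bonds = _benzene()
        rings = find_rings(Conformation(atoms, bonds))
        assert len(rings) == 1
        assert np.allclose(rings[0].centroid, (0, 0, 0), atol=1e-9)
        assert np.linalg.norm(rings[0].normal) == pytest.approx(1.0)

    def test_cyclohexane_is_not_aromatic(self):
        rings = find_rings(_embedded("C1CCCCC1"))
        assert rings == []

    def test_methylthiazole_five_ring(self):
        rings = find_rings(_embedded("Cc1cscn1"))
        assert len(rings) == 1
        assert len(rings[0].atoms) == 5


def _imhb_scene(h_acc=1.9, angle_deg=165.0, spacer=True):
    """N-H donor and C=O acceptor joined by a dummy chain (>=3 bonds)."""
    rad = math.radians(180.0 - angle_deg)
    h = np.array([0.0, 0.0, 0.0])
    n = h + np.array([-1.01, 0.0, 0.0])
    acc = h + h_acc * np.array([math.cos(rad), math.sin(rad), 0.0])
    c_carbonyl = acc + np.array([1.23, 0.8, 0.0])
    atoms = [
        Atom("N", tuple(n)), Atom("H", tuple(h)), Atom("O", tuple(acc)),
        Atom("C", tuple(c_carbonyl)),
        Atom("C", tuple(n + np.array([0.0, 1.5, 0.0]))),
        Atom("C", tuple(n + np.array([1.0, 2.6, 0.0]))),
    ]
    bonds = [(0, 1, 1.0), (2, 3, 2.0), (0, 4, 1.0), (4, 5, 1.0)]
    if spacer:
        bonds.append((5, 3, 1.0))  # N...acceptor now 4 bonds apart
    else:
        bonds.append((0, 3, 1.0))  # direct N-C(=O): 2-bond separation
    return Conformation(atoms, bonds)


class TestDetectImhb:
    def test_ideal_geometry_detected(self):
        recs = detect_imhb(_imhb_scene())
        assert len(recs) == 1
        assert recs[0].geometry["h_acceptor_distance"] == pytest.approx(1.9, abs=1e-6)

    def test_covalent_neighbors_excluded(self):
        assert detect_imhb(_imhb_scene(spacer=False)) == []

    def test_long_distance_rejected(self):
        assert detect_imhb(_imhb_scene(h_acc=3.2)) == []

    def test_bent_angle_rejected(self):
        assert detect_imhb(_imhb_scene(angle_deg=90.0)) == []

    def test_planted_conformer_found_extended_clean(self, planted, pool):
        conf, manifest = planted
        expected = next(m for m in manifest if m["kind"] == "imhb")
        recs = detect_imhb(conf)
        assert any(set(expected["atoms"]) <= set(r.atoms) for r in recs)
        assert detect_imhb(pool[0]) == []


def _two_ring_scene(offset=(0.0, 0.0, 3.8), tilt_deg=0.0):
    atoms1, bonds1 = _benzene()
    atoms2, bonds2 = _benzene(start=len(atoms1))
    # tilt then translate the second ring
    rad = math.radians(tilt_deg)
    rot = np.array(
        [[1, 0, 0], [0, math.cos(rad), -math.sin(rad)], [0, math.sin(rad), math.cos(rad)]]
    )
    moved = []
    for a in atoms2:
        xyz = rot @ np.array(a.coords) + np.array(offset)
        moved.append(Atom(a.element, tuple(xyz)))
    return Conformation(atoms1 + moved, bonds1 + bonds2)


class TestDetectPipi:
    def test_parallel_stack_detected_face_to_face(self):
        recs = detect_pipi(_two_ring_scene())
        assert len(recs) == 1
        assert recs[0].geometry["geometry_class"] == "face_to_face"

    def test_distant_rings_rejected(self):
        assert detect_pipi(_two_ring_scene(offset=(10.0, 0.0, 0.0))) == []

    def test_t_shaped_edge_to_face(self):
        recs = detect_pipi(_two_ring_scene(offset=(0.0, 0.0, 5.0), tilt_deg=85.0))
        assert len(recs) == 1
        assert recs[0].geometry["geometry_class"] == "edge_to_face"
        assert recs[0].geometry["centroid_distance"] == pytest.approx(5.0, abs=1e-6)

    def test_intermediate_tilt_rejected(self):
        assert detect_pipi(_two_ring_scene(offset=(0.0, 0.0, 4.0), tilt_deg=45.0)) == []

    def test_planted_stack_found(self, planted, pool):
        conf, manifest = planted
        assert len(detect_pipi(conf)) >= 1
        assert detect_pipi(pool[0]) == []


def _nhpi_scene(height=2.8, in_plane=False):
    atoms, bonds = _benzene()
    n0 = len(atoms)
    if in_plane:
        h = np.array([2.8, 0.0, 0.0])
        n = h + np.array([1.01, 0.0, 0.0])
    else:
        h = np.array([0.0, 0.0, height])
        n = h + np.array([0.0, 0.0, 1.01])
    atoms += [Atom("N", tuple(n)), Atom("H", tuple(h)), Atom("C", tuple(n + np.array([1.4, 0.5, 0.3])))]
    bonds += [(n0, n0 + 1, 1.0), (n0, n0 + 2, 1.0)]
    return Conformation(atoms, bonds)


class TestDetectNhpi:
    def test_perpendicular_approach_detected(self):
        recs = detect_nhpi(_nhpi_scene())
        assert len(recs) == 1
        assert recs[0].geometry["h_centroid_distance"] == pytest.approx(2.8, abs=1e-6)

    def test_in_plane_approach_rejected(self):
        assert detect_nhpi(_nhpi_scene(in_plane=True)) == []

    def test_planted_contact_found(self, planted, pool):
        conf, manifest = planted
        expected = next(m for m in manifest if m["kind"] == "nhpi")
        recs = detect_nhpi(conf)
        assert any(set(expected["atoms"][:2]) <= set(r.atoms) for r in recs)
        assert detect_nhpi(pool[0]) == []


class TestProperties:
    def test_rigid_motion_invariance(self, planted):
        conf, _ = planted
        rng = np.random.default_rng(4)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
            ]
        )
        moved = conf.with_coords(conf.coords @ rot.T + np.array([5.0, -2.0, 1.0]))
        base = {r.kind for r in detect_all(conf)}, len(detect_all(conf))
        assert ({r.kind for r in detect_all(moved)}, len(detect_all(moved))) == base

    def test_tightening_cutoffs_never_increases_counts(self):
        rng = np.random.default_rng(12)
        loose = InteractionCriteria()
        tight = InteractionCriteria(
            hbond_h_acceptor_max=2.0, hbond_dha_min_angle=150.0,
            pipi_centroid_max=4.2, pipi_interplane_max_angle=15.0,
            nhpi_h_centroid_max=2.9, nhpi_approach_min_angle=150.0,
        )
        for _ in range(200):
            scene = _random_scene(rng)
            n_loose = len(detect_all(scene, loose))
            n_tight = len(detect_all(scene, tight))
            assert n_tight <= n_loose

    def test_records_satisfy_their_own_criteria(self, planted):
        conf, _ = planted
        crit = InteractionCriteria()
        for rec in detect_all(conf, crit):
            g = rec.geometry
            if rec.kind == "imhb":
                assert g["h_acceptor_distance"] <= crit.hbond_h_acceptor_max
                assert g["dha_angle"] >= crit.hbond_dha_min_angle
            elif rec.kind == "pipi":
                assert g["centroid_distance"] <= crit.pipi_centroid_max
            else:
                assert g["h_centroid_distance"] <= crit.nhpi_h_centroid_max
                assert g["approach_angle"] >= crit.nhpi_approach_min_angle


def _random_scene(rng):
    """Two benzene rings plus an amide-like N-H/C=O pair in random poses."""
    atoms1, bonds1 = _benzene()
    atoms2, bonds2 = _benzene(start=len(atoms1))
    shift = rng.uniform(-6, 6, size=3)
    ang = rng.uniform(0, math.pi)
    rot = np.array(
        [[1, 0, 0], [0, math.cos(ang), -math.sin(ang)], [0, math.sin(ang), math.cos(ang)]]
    )
    ring2 = [Atom(a.element, tuple(rot @ np.array(a.coords) + shift)) for a in atoms2]
    n0 = len(atoms1) + len(ring2)
    n_pos = rng.uniform(-5, 5, size=3)
    h_pos = n_pos + 1.01 * _unit(rng)
    o_pos = rng.uniform(-5, 5, size=3)
    c_pos = o_pos + 1.23 * _unit(rng)
    extra = [
        Atom("N", tuple(n_pos)), Atom("H", tuple(h_pos)),
        Atom("O", tuple(o_pos)), Atom("C", tuple(c_pos)),
        Atom("C", tuple(n_pos + np.array([1.4, 0, 0]))),
        Atom("C", tuple(n_pos + np.array([2.4, 1.0, 0]))),
    ]
    bonds = bonds1 + bonds2 + [
        (n0, n0 + 1, 1.0), (n0 + 2, n0 + 3, 2.0), (n0, n0 + 4, 1.0),
        (n0 + 4, n0 + 5, 1.0), (n0 + 5, n0 + 3, 1.0),
    ]
    return Conformation(atoms1 + ring2 + extra, bonds)


def _unit(rng):
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)
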