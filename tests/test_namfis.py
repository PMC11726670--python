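"""Population deconvolution: pseudo-atom averaging, r⁻⁶ ensemble averages,
weight fitting with ground-truth recovery, and stability validation."""

import itertools

import numpy as np
import pytest

from flexsol.chem import Atom, Conformation, ConformerEnsemble
from flexsol.namfis import (
    NamfisConfig,
    RestraintSet,
    backcalc_group_distance,
    ensemble_average,
    fit_populations,
    rmsd_fit_quality,
    validate_jackknife,
    validate_noise,
)
from flexsol.noe import DistanceRestraint


def _line_conformation(h_positions):
    atoms = [Atom("H", tuple(p)) for p in h_positions]
    return Conformation(atoms, [])


class TestBackcalcGroupDistance:
    def test_singleton_pair_is_plain_distance(self):
        c = _line_conformation([(0, 0, 0), (3.0, 0, 0)])
        assert backcalc_group_distance(c, (0,), (1,)) == pytest.approx(3.0)

    def test_equidistant_methylene_collapses(self):
        # both CH2 partners sit 2.5 Å from the singleton
        c = _line_conformation([(0, 0, 0), (2.5, 0, 0), (0, 2.5, 0)])
        assert backcalc_group_distance(c, (0,), (1, 2)) == pytest.approx(2.5)

    def test_unequal_methylene_matches_closed_form(self):
        c = _line_conformation([(0, 0, 0), (2.0, 0, 0), (0, 3.0, 0)])
        expected = ((2.0**-6 + 3.0**-6) / 2.0) ** (-1.0 / 6.0)
        got = backcalc_group_distance(c, (0,), (1, 2))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(2.2137, abs=1e-3)

    def test_matches_brute_force_over_all_pairs(self, pool):
        # independent oracle: explicit double loop over proton pairs
        c = pool[0]
        hs = [i for i, a in enumerate(c.atoms) if a.element == "H"]
        ga, gb = tuple(hs[:3]), tuple(hs[3:5])
        acc = []
        for i in ga:
            for j in gb:
                acc.append(np.linalg.norm(c.coords[i] - c.coords[j]) ** -6)
        expected = (sum(acc) / len(acc)) ** (-1 / 6)
        assert backcalc_group_distance(c, ga, gb) == pytest.approx(expected, abs=1e-12)

    def test_overlapping_groups_rejected(self):
        c = _line_conformation([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        with pytest.raises(ValueError):
            backcalc_group_distance(c, (0, 1), (1, 2))


class TestEnsembleAverage:
    def test_degenerate_inputs(self):
        assert ensemble_average([4.2], [1.0]) == pytest.approx(4.2)
        assert ensemble_average([2, 2, 2], [0.2, 0.5, 0.3]) == pytest.approx(2.0)

    def test_r6_average_closed_form(self):
        got = ensemble_average([2.0, 4.0], [0.5, 0.5])
        assert got == pytest.approx((0.5 * 2.0**-6 + 0.5 * 4.0**-6) ** (-1 / 6), abs=1e-12)
        assert got == pytest.approx(2.2393, abs=1e-3)

    def test_linear_mode(self):
        assert ensemble_average([2.0, 4.0], [0.25, 0.75], mode="linear") == pytest.approx(3.5)

    def test_bounded_by_extremes(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            r = rng.uniform(1.5, 6.0, size=5)
            w = rng.dirichlet(np.ones(5))
            avg = ensemble_average(r, w)
            assert r.min() - 1e-12 <= avg <= r.max() + 1e-12

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            ensemble_average([2.0, -1.0], [0.5, 0.5])


def _restraints_for(conf_or_pool, weights, pairs):
    """Noise-free restraints from ground truth (generator inverse)."""
    if isinstance(conf_or_pool, Conformation):
        pool = [conf_or_pool]
        weights = [1.0]
    else:
        pool = list(conf_or_pool)
    out = []
    for ga, gb in pairs:
        per = np.array([backcalc_group_distance(c, ga, gb) for c in pool])
        out.append(DistanceRestraint(ga, gb, ensemble_average(per, np.asarray(weights))))
    return out


class TestFitPopulations:
    def test_single_conformer_pool(self, pool, noisefree_restraints):
        e = ConformerEnsemble([pool[0]])
        sol = fit_populations(e, RestraintSet(noisefree_restraints))
        assert sol.weights == pytest.approx([1.0])

    def test_identical_conformers_flagged_non_identifiable(self, pool, noisefree_restraints):
        twin = ConformerEnsemble([pool[0], pool[0].with_coords(pool[0].coords, "copy")])
        single = ConformerEnsemble([pool[0]])
        rset = RestraintSet(noisefree_restraints)
        cfg = NamfisConfig(seed=1, n_starts=8)
        sol_twin = fit_populations(twin, rset, cfg)
        sol_one = fit_populations(single, rset, cfg)
        assert sol_twin.non_identifiable_groups == [(0, 1)]
        assert sol_twin.ssd == pytest.approx(sol_one.ssd, rel=1e-6, abs=1e-9)

    def test_ground_truth_recovery_noise_free(self, pool, true_weights, noisefree_restraints):
        sol = fit_populations(pool, RestraintSet(noisefree_restraints), NamfisConfig(seed=5))
        assert np.abs(sol.weights - true_weights).max() <= 0.02

    def test_permutation_equivariance(self, pool, true_weights, noisefree_restraints):
        cfg = NamfisConfig(seed=5)
        rset = RestraintSet(noisefree_restraints)
        sol = fit_populations(pool, rset, cfg)
        perm = np.array([3, 1, 4, 0, 2, 9, 5, 7, 8, 6])
        permuted = pool.subset(perm)
        sol_p = fit_populations(permuted, rset, cfg)
        assert np.abs(sol_p.weights - sol.weights[perm]).max() < 1e-4

    def test_pruning_never_worsens_objective(self, pool, true_weights, noisefree_restraints):
        cfg = NamfisConfig(seed=5, prune_threshold=0.05)
        sol = fit_populations(pool, RestraintSet(noisefree_restraints), cfg)
        # refit restricted to the support the prune step selected
        assert sol.ssd <= fit_populations(
            pool, RestraintSet(noisefree_restraints), NamfisConfig(seed=5, prune_threshold=0.0)
        ).ssd + 1e-9

    def test_reported_populations_are_whole_percent(self, pool, noisefree_restraints):
        sol = fit_populations(pool, RestraintSet(noisefree_restraints), NamfisConfig(seed=5))
        pops = sol.populations_percent
        assert pops.dtype.kind == "i" and pops.sum() in (99, 100, 101)


@pytest.fixture(scope="module")
def fitted(pool, noisefree_restraints):
    rset = RestraintSet(noisefree_restraints)
    cfg = NamfisConfig(seed=5)
    return fit_populations(pool, rset, cfg), rset, cfg


class TestValidation:
    def test_zero_noise_gives_zero_rmsd(self, pool, fitted):
        sol, rset, cfg = fitted
        rep = validate_noise(sol, pool, rset, noise_fraction=0.0, n_trials=2, seed=7, config=cfg)
        assert rep["weight_rmsd_per_trial"].max() < 1e-6

    def test_noise_report_deterministic_under_seed(self, pool, fitted):
        sol, rset, cfg = fitted
        r1 = validate_noise(sol, pool, rset, 0.05, n_trials=1, seed=7, config=cfg)
        r2 = validate_noise(sol, pool, rset, 0.05, n_trials=1, seed=7, config=cfg)
        assert np.array_equal(r1["weight_mean"], r2["weight_mean"])

    def test_jackknife_duplicate_restraint_is_uninfluential(self, pool, fitted):
        sol, rset, cfg = fitted
        doubled = RestraintSet(rset.distances + [rset.distances[0]])
        sol2 = fit_populations(pool, doubled, cfg)
        rep = validate_jackknife(sol2, pool, doubled, cfg)
        dup_indices = [0, len(doubled.distances) - 1]
        for k in dup_indices:
            assert rep["max_weight_change_per_restraint"][k] < 1e-3

    def test_jackknife_noise_free_system_has_no_influential_restraints(self, pool, fitted):
        sol, rset, cfg = fitted
        rep = validate_jackknife(sol, pool, rset, cfg)
        assert rep["influential_restraints"] == []
        assert len(rep["max_weight_change_per_restraint"]) == len(rset.distances)

    def test_jackknife_two_restraint_system_covers_both(self, pool, true_weights):
        # minimal 2-restraint system built directly from the pool
        c = pool[0]
        hs = [i for i, a in enumerate(c.atoms) if a.element == "H"]
        pairs = [((hs[0],), (hs[4],)), ((hs[1],), (hs[5],))]
        restr = _restraints_for(pool, true_weights, pairs)
        cfg = NamfisConfig(seed=2, n_starts=8)
        sol = fit_populations(pool, RestraintSet(restr), cfg)
        rep = validate_jackknife(sol, pool, RestraintSet(restr), cfg)
        assert len(rep["max_weight_change_per_restraint"]) == 2


class TestRmsdFitQuality:
    def _sol_with_residuals(self, res):
        from flexsol.namfis import NamfisSolution

        res = np.asarray(res, dtype=float)
        return NamfisSolution(
            weights=np.array([1.0]), ssd=0.0, d_calc=res, residuals=res,
            pruned_pool_ids=[], non_identifiable_groups=[], converged=True,
        )

    def test_zero_residuals(self):
        assert rmsd_fit_quality(self._sol_with_residuals([0.0, 0.0])) == 0.0

    def test_closed_form(self):
        assert rmsd_fit_quality(self._sol_with_residuals([0.3, -0.4])) == pytest.approx(
            0.354, abs=1e-3
        )

    def test_scales_linearly(self):
        r = [0.1, -0.25, 0.4]
        assert rmsd_fit_quality(self._sol_with_residuals([2 * x for x in r])) == pytest.approx(
            2 * rmsd_fit_quality(self._sol_with_residuals(r))
        )
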