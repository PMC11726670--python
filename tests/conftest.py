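"""Shared fixtures: one synthetic study (molecule, pool, hidden weights,
simulated NOE data) generated once per session."""

import numpy as np
import pytest

from flexsol.noe import read_peak_table, restraints_from_peak_table
from flexsol.synthetic import (
    SyntheticSpec,
    choose_proton_pairs,
    make_conformer_pool,
    make_molecule,
    plant_interactions,
    simulate_noe_table,
)


@pytest.fixture(scope="session")
def spec():
    return SyntheticSpec(seed=11)


@pytest.fixture(scope="session")
def molecule(spec):
    return make_molecule(spec)


@pytest.fixture(scope="session")
def pool(molecule, spec):
    return make_conformer_pool(molecule, spec.n_conformers, spec.seed)


@pytest.fixture(scope="session")
def true_weights(spec):
    return spec.padded_weights()


@pytest.fixture(scope="session")
def proton_pairs(pool, true_weights, spec):
    return choose_proton_pairs(pool, true_weights, spec.n_restraints, spec.seed)


@pytest.fixture(scope="session")
def noisefree_sim(pool, true_weights, proton_pairs, spec):
    return simulate_noe_table(pool, true_weights, proton_pairs, spec)


@pytest.fixture(scope="session")
def noisefree_restraints(noisefree_sim, tmp_path_factory):
    path = tmp_path_factory.mktemp("noe") / "peaks.tsv"
    noisefree_sim.table.to_csv(path, sep="\t", index=False)
    series = read_peak_table(path)
    return restraints_from_peak_table(series, noisefree_sim.reference_pair)


@pytest.fixture(scope="session")
def planted(molecule):
    return plant_interactions(molecule)
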