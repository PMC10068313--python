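"""Shared fixtures.

The expensive coarse-grained pulling ensemble and the flow-chamber
recovery dataset are session-scoped so that module tests and the
acceptance suite reuse a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from forcekin.arrest_survival import ligand_force_spectrum
from forcekin.bell_kinetics import BellBond
from forcekin.cg_pulling import (Deletion, PullingProtocol, force_spectrum,
                                 load_structure, native_contacts)
from forcekin.synthetic import LFCSimConfig, make_toy_complex, \
    simulate_arrest_table

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: frozen protocol of the toy pulling study (see docs/methods.md)
TOY_SPEEDS = (0.005, 0.015, 0.045)
TOY_CONSTRUCTS = {
    "full": [],
    "partial": [Deletion("B", "A", (8, 12))],
    "core": [Deletion("B", "A", (8, 15))],
}


@pytest.fixture(scope="session")
def toy_structure(tmp_path_factory):
    """Toy two-helix complex written to disk and loaded back."""
    toy = make_toy_complex(seed=0)
    path = tmp_path_factory.mktemp("toy") / "complex.pdb"
    toy.write(path)
    structure = load_structure(path)
    contacts = native_contacts(structure, criterion="cutoff",
                               cutoff=toy.contact_cutoff)
    return toy, structure, contacts


@pytest.fixture(scope="session")
def toy_spectrum(toy_structure):
    """Rupture-force spectrum of the toy complex over nested deletions.

    10 trajectories x 3 speeds x 3 constructs; the slow part of the
    suite (a few minutes), shared across all tests that inspect it.
    """
    _, structure, contacts = toy_structure
    return force_spectrum(structure, contacts, TOY_CONSTRUCTS,
                          speeds=TOY_SPEEDS, n=10,
                          protocol=PullingProtocol(dt=0.02), seed=42,
                          epsilon=1.0, epsilon_inter=3.0)


@pytest.fixture(scope="session")
def lfc_recovery():
    """Flow-chamber dataset with planted slip bond and its pipeline result.

    Planted k0_off = 0.29 1/s, x_beta = 0.3 nm; roughly 500 events in
    the slowest velocity bins.
    """
    cfg = LFCSimConfig(true_bond=BellBond(0.29, 0.3), n_beads=100)
    sim = simulate_arrest_table(cfg, seed=11)
    result = ligand_force_spectrum(sim.events, sim.controls,
                                   summaries=sim.summaries)
    return cfg, sim, result


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
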