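"""Shared fixtures: random DP instances and session-scoped simulations."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from localtag import (Candidate, CandidateFilterConfig, SimulationConfig,
                      simulate_diploid, write_simulation)
from localtag.haplotag_graph import HaplotagGraph, build_window_graph

#: fixed study conditions for the simulation-based checks: 50 kb diploid
#: genome, 1 het SNP per kb, 30x coverage, with and without 1% substitutions
CLEAN_SIM_CONFIG = SimulationConfig(seed=7, substitution_error_rate=0.0)
NOISY_SIM_CONFIG = SimulationConfig(seed=11, substitution_error_rate=0.01)


def random_graph_instance(seed: int) -> HaplotagGraph:
    """A small random allele graph: <=5 positions, <=3 vertices each,
    <=30 reads, built through the public graph constructor with permissive
    support thresholds so arbitrary topologies (orphan vertices, segment
    splits) occur."""
    rng = np.random.default_rng(seed)
    n_positions = int(rng.integers(1, 6))
    sizes = rng.integers(1, 4, size=n_positions)
    n_reads = int(rng.integers(1, 31))
    alleles = ["A", "C", "G"]

    support: list[dict[str, set[str]]] = [
        {a: set() for a in alleles[: sizes[n]]} for n in range(n_positions)]
    reads = []
    for r in range(n_reads):
        first = int(rng.integers(0, n_positions))
        last = int(rng.integers(first, n_positions))
        read_id = f"r{r}"
        reads.append(SimpleNamespace(read_id=read_id, start=first * 100))
        for n in range(first, last + 1):
            support[n][alleles[int(rng.integers(0, sizes[n]))]].add(read_id)

    candidates = []
    for n in range(n_positions):
        observed = {a: frozenset(s) for a, s in support[n].items() if s}
        if not observed:
            continue
        alts = tuple(a for a in observed if a != "A")
        if not alts:  # only the reference allele drew reads
            candidates.append(Candidate(n * 100, "A", ("C",),
                                        {"A": observed["A"], "C": frozenset()}))
        else:
            observed.setdefault("A", frozenset())
            candidates.append(Candidate(n * 100, "A", alts, observed))
    config = CandidateFilterConfig(min_ref_support=1, min_alt_support=1,
                                   min_alt_fraction=0.0)
    return build_window_graph(candidates, reads, config)


@pytest.fixture(scope="session")
def sim_clean():
    return simulate_diploid(CLEAN_SIM_CONFIG)


@pytest.fixture(scope="session")
def sim_noisy():
    return simulate_diploid(NOISY_SIM_CONFIG)


@pytest.fixture(scope="session")
def sim_clean_paths(sim_clean, tmp_path_factory):
    return write_simulation(sim_clean, tmp_path_factory.mktemp("sim_clean"))


@pytest.fixture(scope="session")
def sim_noisy_paths(sim_noisy, tmp_path_factory):
    return write_simulation(sim_noisy, tmp_path_factory.mktemp("sim_noisy"))
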