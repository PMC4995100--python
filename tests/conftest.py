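"""Shared fixtures: toy genomes/tracks and simulated reactions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from qznorm.genome_io import DyadAnnotation, FragmentSet, GenomeTable, IntervalSet, Track
from qznorm.profiles import midpoint_track
from qznorm.synthetic_data import SimulationConfig, make_genome, simulate_fractions
from qznorm.taz_norm import normalize_reaction


@pytest.fixture
def toy_genome() -> GenomeTable:
    return GenomeTable({"chrI": 2000, "chrII": 1500})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_fragments(rows: list[tuple[str, int, int]], counts=None) -> FragmentSet:
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    if counts is not None:
        df["count"] = counts
    return FragmentSet(df)


def random_fragments(genome: GenomeTable, n: int, rng: np.random.Generator) -> FragmentSet:
    chroms = rng.choice(genome.chroms, size=n)
    rows = []
    for c in chroms:
        length = int(rng.integers(50, 200))
        start = int(rng.integers(0, genome[c] - length))
        rows.append((c, start, start + length))
    return make_fragments(rows)


def random_track(genome: GenomeTable, rng: np.random.Generator) -> Track:
    return Track({c: rng.random(n) for c, n in genome.lengths.items()})


def make_dyads(rows: list[tuple[str, int, str, str]]) -> DyadAnnotation:
    return DyadAnnotation(pd.DataFrame(rows, columns=["chrom", "dyad", "strand", "role"]))


def make_intervals(rows: list[tuple[str, int, int]]) -> IntervalSet:
    return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated genome shared across tests (read-only)."""
    return make_genome(SimulationConfig(seed=7))


def normalized_reaction(sim, truth=None, seed=0):
    """Simulate one reaction and TAZ-normalize its midpoint tracks."""
    frags = simulate_fractions(sim, truth=truth, seed=seed)
    tracks = {tag: midpoint_track(fs, sim.genome) for tag, fs in frags.items()}
    return normalize_reaction(
        tracks["T"], tracks["A"], tracks["Z"], sim.nozzones, sim.plus_one
    )
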