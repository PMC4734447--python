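"""Shared fixtures: small simulated genome/proteome sets.

Everything is generated programmatically with fixed seeds; expensive
simulations are session-scoped so several test modules can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from gentaxo import seqio, simgen


def random_genome(rng: np.random.Generator, length: int, gc: float = 0.5,
                  genome_id: str = "g") -> seqio.GenomeRecord:
    """An i.i.d. random genome (no genes), for null controls."""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(np.random.default_rng(rng.integers(2**31)).choice(
        list("ACGT"), size=length, p=probs))
    return seqio.GenomeRecord(genome_id, [("chr", seq)])


@pytest.fixture(scope="session")
def pair_p05() -> simgen.SimResult:
    """A 60-kb genome pair at flat 5% nucleotide divergence, no indels."""
    cfg = simgen.SimConfig(seed=101, ancestor_length=60_000, n_genes=30,
                           divergence=0.05)
    return simgen.evolve(simgen.make_ancestor(cfg), cfg)


@pytest.fixture(scope="session")
def small_ancestor() -> simgen.Ancestor:
    """A 50-kb ancestor with 40 genes (proteome-level scenarios)."""
    cfg = simgen.SimConfig(seed=55, ancestor_length=50_000, n_genes=40,
                           gene_length_codons=(80, 120, 180))
    return simgen.make_ancestor(cfg)


@pytest.fixture(scope="session")
def marker_fixture() -> dict:
    """The marker_set scenario: 4 genomes with the 5 MLSA markers planted."""
    return simgen.fixture_suite("marker_set", seed=13)
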