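"""Shared fixtures: the default coupled simulation used across test modules.

Session-scoped so the expensive pieces (200k-fragment ATAC library and its
alignment to the assembly) are computed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from hmumap.align import MultimapAligner, truth_alignments
from hmumap.genome import (
    GenomeConfig,
    build_modification_map,
    build_occupancy_map,
    generate_genome,
)
from hmumap.simulate import (
    LibraryConfig,
    fragment_sequences,
    make_spike_genome,
    simulate_atac_fragments,
)

P_REPEAT = {
    "MaverickSim": 0.45,
    "CopiaSimLTR": 0.15,
    "SatSim": 0.10,
    "CollapsedSim": 0.10,
}


@pytest.fixture(scope="session")
def genome7():
    return generate_genome(GenomeConfig(seed=7))


@pytest.fixture(scope="session")
def mod7(genome7):
    return build_modification_map(genome7, p_repeat=P_REPEAT)


@pytest.fixture(scope="session")
def occ7(genome7, mod7):
    return build_occupancy_map(genome7, mod7, seed=7)


@pytest.fixture(scope="session")
def spike_genome():
    return make_spike_genome()


@pytest.fixture(scope="session")
def aligner7(genome7):
    return MultimapAligner(genome7.assembly_view)


@pytest.fixture(scope="session")
def atac200k(genome7, occ7):
    return simulate_atac_fragments(genome7, occ7, LibraryConfig(n_fragments=200_000, seed=21))


@pytest.fixture(scope="session")
def atac200k_truth(genome7, atac200k):
    return truth_alignments(atac200k, genome7)


@pytest.fixture(scope="session")
def atac200k_aligned(genome7, aligner7, atac200k):
    seqs = fragment_sequences(genome7, atac200k)
    return aligner7.align_fragments(seqs)


@pytest.fixture(scope="session")
def small_flat_genome():
    """One repeat-free 150-kbp contig; handy for conversion analyses."""
    cfg = GenomeConfig(
        n_contigs=1,
        contig_length=150_000,
        array_length_mean=15_000,
        repeat_families=(),
        collapsed_families={},
        seed=11,
    )
    return generate_genome(cfg)
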