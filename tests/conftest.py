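import numpy as np
import pytest

import mitopair as mp
from mitopair.genome import AnnotatedGenome, GeneFeature


@pytest.fixture
def toy_genome():
    # 30 bp circle: one forward PCG (ATG GCT TAA at 1..9), one tRNA at 13..24
    seq = "ATGGCTTAACCGGTTACGTACGTACGGATC"
    feats = [
        GeneFeature("pcgA", "PCG", 1, 9, "+", start_codon="ATG", stop_codon="TAA"),
        GeneFeature("trnX", "tRNA", 13, 24, "+", anticodon="CAT"),
    ]
    return AnnotatedGenome("toy", seq, feats)


@pytest.fixture(scope="session")
def sim_genome():
    genome, truth = mp.simulate_genome(mp.SimConfig(seed=1))
    return genome, truth


@pytest.fixture(scope="session")
def sim_pair(sim_genome):
    genome, _ = sim_genome
    return mp.evolve_pair(genome, mp.SimConfig(seed=1))


@pytest.fixture(scope="session")
def distance_table():
    return mp.load_distance_table()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_annotated_genome(rng, n_genes=4, length=600):
    """Small random circular genome with non-overlapping in-frame PCGs."""
    seq = "".join(rng.choice(list("ACGT"), size=length))
    starts = np.sort(rng.choice(np.arange(1, length - 60, 3), size=n_genes, replace=False))
    feats = []
    for i, s in enumerate(starts):
        span = 3 * int(rng.integers(4, 12))
        end = min(int(s) + span - 1, length)
        end -= (end - int(s) + 1) % 3
        strand = "+" if rng.random() < 0.5 else "-"
        feats.append(GeneFeature(f"g{i}", "PCG", int(s), end, strand))
    # keep non-overlapping
    pruned, last_end = [], 0
    for f in sorted(feats, key=lambda f: f.start):
        if f.start > last_end:
            pruned.append(f)
            last_end = f.end
    return AnnotatedGenome("rand", seq, pruned)
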