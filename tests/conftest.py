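import numpy as np
import pytest

from regulonscout import (AnnotatedGenome, CommunityConfig, Gene,
                          generate_community, motif_from_consensus)


@pytest.fixture(scope="session")
def verruco_motif():
    """Idealised 14 bp spaced-dyad motif with sharp arms and uniform spacer."""
    return motif_from_consensus("TGTTC-N4-GAACA", 1.8)


@pytest.fixture(scope="session")
def default_community():
    """One default synthetic community (3 species, planted regulon), seed 0."""
    return generate_community(CommunityConfig(seed=0))


@pytest.fixture()
def toy_genome():
    """Three genes on one 1 kb contig: distances 50 and 20, mean 35."""
    contig = "ACGT" * 250
    genes = [
        Gene("g1", "c1", 0, 100, "+", "M" * 10),
        Gene("g2", "c1", 150, 300, "+", "M" * 10),
        Gene("g3", "c1", 320, 500, "-", "M" * 10),
    ]
    return AnnotatedGenome("toy", [("c1", contig)], genes)


def random_toy_genome(rng: np.random.Generator, n_contigs=1, max_genes=8) -> AnnotatedGenome:
    """Small random annotated genome for brute-force comparisons."""
    contigs, genes = [], []
    for c in range(n_contigs):
        cid = f"c{c}"
        contigs.append((cid, "ACGT" * 300))
        pos = int(rng.integers(0, 30))
        for g in range(int(rng.integers(1, max_genes + 1))):
            length = int(rng.integers(30, 120))
            if pos + length > 1200:
                break
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(Gene(f"g{c}_{g}", cid, pos, pos + length, strand))
            pos += length + int(rng.integers(-20, 120))
            pos = max(pos, genes[-1].end - 20)
    return AnnotatedGenome("rand", contigs, genes)
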