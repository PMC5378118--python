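import numpy as np
import pytest

from intronsnp.gene_models import GeneModel, Intron
from intronsnp.synthetic_data import SimConfig, simulate_population


@pytest.fixture
def two_exon_model():
    return GeneModel(gene_id="g", exons=((0, 30), (80, 110)))


@pytest.fixture
def three_exon_model():
    exons = ((0, 40), (60, 90), (110, 150))
    introns = (
        Intron("g-i1", 40, 60, group="I", mobile=True,
               orf_content=frozenset({"endonuclease"})),
        Intron("g-i2", 90, 110, group="II", mobile=False),
    )
    return GeneModel(gene_id="g", exons=exons, introns=introns, code_table=3)


def random_gene_model(rng: np.random.Generator, gene_id="rg") -> GeneModel:
    """Random small gene: 2-6 exons (15-120 nt), introns 20-60 nt."""
    n_exons = int(rng.integers(2, 7))
    exon_lengths = rng.integers(15, 121, n_exons)
    # pad the last exon so the spliced length is a codon multiple
    exon_lengths[-1] += (-exon_lengths.sum()) % 3
    intron_lengths = rng.integers(20, 61, n_exons - 1)
    exons, introns, pos = [], [], 0
    groups = ["I", "II", "unknown"]
    for k, el in enumerate(exon_lengths):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if k < n_exons - 1:
            il = int(intron_lengths[k])
            introns.append(Intron(
                f"{gene_id}-i{k + 1}", pos, pos + il,
                group=groups[int(rng.integers(0, 3))],
                mobile=bool(rng.integers(0, 2)),
            ))
            pos += il
    return GeneModel(gene_id=gene_id, exons=tuple(exons),
                     introns=tuple(introns), code_table=3)


@pytest.fixture(scope="session")
def small_sim():
    """One moderate simulated population shared across tests."""
    cfg = SimConfig(n_strains=20, seed=11,
                    exon_lengths=(150, 120, 180), intron_lengths=(40, 40),
                    intron_attrs=(("I", True, ("endonuclease",)),
                                  ("II", False, ("none",))),
                    mu0=0.08, gradient_scope="mobile_only")
    return simulate_population(cfg)
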