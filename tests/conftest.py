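import numpy as np
import pandas as pd
import pytest

from circage.genome import GeneModel, GenomeBundle, Transcript
from circage.synthdata import SimulationConfig, simulate_study


def design_frame(truth):
    return pd.DataFrame(
        [dict(library=l, tissue=t, age=a, replicate=r)
         for l, t, a, r in truth.libraries])


@pytest.fixture(scope="session")
def tiny_config():
    """Small error-free two-group study with duplicates on."""
    return SimulationConfig(
        seed=5, n_chromosomes=1, chrom_length=400_000, n_genes=20,
        n_circ_genes=8, multi_circle_genes=2, n_fragments_per_library=2000,
        circ_fraction_of_reads=0.02, error_rate=0.0, duplicate_rate=0.05,
        groups=(("cortex", "young"), ("cortex", "old")), n_replicates=3)


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def toy_circle_genome():
    """Hand-built genome: one plus-strand gene with exons A=[200,300) and
    B=[400,500) joined by a circle B->A, splice signals planted so that
    genome[500:502]='GT' (donor after B) and genome[198:200]='AG'
    (acceptor before A), plus the linear intron signals."""
    rng = np.random.default_rng(123)
    seq = list(_random_seq(rng, 1000))
    seq[300:302] = "GT"   # linear intron donor after exon A
    seq[398:400] = "AG"   # linear intron acceptor before exon B
    seq[500:502] = "GT"   # donor signal after circle donor exon B
    seq[198:200] = "AG"   # acceptor signal before circle acceptor exon A
    genome = "".join(seq)
    gene = GeneModel("geneA", "chrT", "+",
                     [Transcript("geneA.t1", ((200, 300), (400, 500)), None)])
    return GenomeBundle({"chrT": genome}, [gene])
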