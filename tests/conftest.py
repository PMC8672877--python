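import numpy as np
import pytest

from gat import ripsim


@pytest.fixture(scope="session")
def sim_default():
    """One default-config simulation shared across tests (seed fixed)."""
    return ripsim.simulate_genome(ripsim.SimConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_genome_with_segments(
    rng, length, background_gc, planted, chrom_name="c1"
):
    """A single-chromosome sequence with planted low-GC segments.

    ``planted`` is a list of (start, seg_length, seg_gc).
    """
    from gat.ripsim import random_sequence
    from gat.genome_io import Chromosome, Genome

    seq = list(random_sequence(rng, length, background_gc))
    for start, seg_len, seg_gc in planted:
        seq[start : start + seg_len] = random_sequence(rng, seg_len, seg_gc)
    chrom = Chromosome(chrom_name, "".join(seq))
    return Genome([chrom], name="fixture"), chrom
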