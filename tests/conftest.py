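import io as _stdio

import pytest

from adnapipe.clipmerge import ClipMergeConfig
from adnapipe.io import write_fastq
from adnapipe.simulate import SimConfig, simulate_genome, simulate_reads


@pytest.fixture
def short_fragment_config():
    """Study conditions for merge round-trips: fragments shorter than the
    read length, so every pair overlaps; length filter at the smallest
    simulated fragment."""
    return ClipMergeConfig(min_read_length=20)


def make_simulated_pairs(seed=1, n=200, err=0.0, fmin=20, fmax=80,
                         read_length=100, genome_length=5000, **kw):
    cfg = SimConfig(seed=seed, n_fragments=n, fragment_dist="uniform",
                    fragment_min=fmin, fragment_max=fmax,
                    read_length=read_length, genome_length=genome_length,
                    substitution_error=err, **kw)
    name, genome, _ = simulate_genome(cfg)
    fwd, rev, truth = simulate_reads(genome, cfg)
    return genome, fwd, rev, truth


def fastq_handles(fwd, rev):
    b1, b2 = _stdio.StringIO(), _stdio.StringIO()
    write_fastq(b1, fwd)
    write_fastq(b2, rev)
    b1.seek(0)
    b2.seek(0)
    return b1, b2
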