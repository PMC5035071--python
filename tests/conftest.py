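import numpy as np
import pytest

from lmrsvm import evaluate, pipeline, synthetic
from lmrsvm.genome_io import Genome, GenomicInterval

SIM_SEED = 11


@pytest.fixture(scope="session")
def sim():
    """The default simulated study: toy genome plus all companion tracks."""
    return synthetic.simulate(synthetic.SimConfig(seed=SIM_SEED))


@pytest.fixture(scope="session")
def pipe(sim):
    """Full pipeline run (rank -> partition -> select -> scan -> merge)."""
    cfg = pipeline.RunConfig(seed=SIM_SEED)
    return pipeline.run_pipeline(sim.genome, sim.lmrs, sim.vista, sim.exons,
                                 cfg)


@pytest.fixture(scope="session")
def validation(sim, pipe):
    tracks = evaluate.MarkerTracks(dhs=sim.dhs, p300=sim.p300, tf=sim.tf,
                                   tss=sim.tss)
    tpm, _ = evaluate.build_tpm(tracks)
    return evaluate.categorize(pipe.representatives, tpm)


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(42)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 10_000)])
    return Genome({"chrT": seq})


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=100_000,
                     max_len=2_000):
    out = []
    for i in range(n):
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(str(rng.choice(chroms)), start,
                                   start + length, name=f"iv{i}"))
    return out
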