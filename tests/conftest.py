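import numpy as np
import pytest

from pirnet import pipeline, simulate


@pytest.fixture(scope="session")
def default_world():
    """The noiseless reference world (3 repeat families, 2 intrinsic
    ping-pong transcripts, 1 snetDNA network)."""
    return simulate.make_world(simulate.SimConfig(rng_seed=1))


@pytest.fixture(scope="session")
def default_run(default_world):
    w = default_world
    return pipeline.run_objects(
        w.reads, w.transcripts, w.genome, w.structural_refs, w.te_library
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240617)


def random_dna(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])
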