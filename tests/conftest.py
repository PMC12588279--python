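import numpy as np
import pytest

from finmix.haplotyping import MtcrSequence
from finmix.mixed_stock import BaselineMatrix, MixtureCounts
from finmix.synthetic_data import default_preset, gen_baseline, gen_mixture


@pytest.fixture(scope="session")
def preset_baseline():
    """9-source, 34-haplotype preset with its generating truth (seed 42)."""
    baseline, truth = gen_baseline(default_preset(), n_per_source=50, seed=42)
    return baseline, truth


@pytest.fixture(scope="session")
def preset_mixture(preset_baseline):
    _, truth = preset_baseline
    return gen_mixture(truth, n=150, seed=43)


@pytest.fixture
def diagnostic_baseline():
    """Two sources, each fixed for its own private haplotype."""
    return BaselineMatrix(
        sources=["A", "B"],
        haplotypes=["X", "Y"],
        counts=np.array([[50, 0], [0, 70]]),
    )


@pytest.fixture
def diagnostic_mixture():
    return MixtureCounts(haplotypes=["X", "Y"], counts=np.array([30, 70]))


def make_seqs(bases_list, prefix="s"):
    return [
        MtcrSequence(id=f"{prefix}{i}", bases=b) for i, b in enumerate(bases_list)
    ]


@pytest.fixture
def toy_seqs():
    return make_seqs
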