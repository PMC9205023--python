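import numpy as np
import pytest

from quartetconv.config import PipelineConfig
from quartetconv.quartets import quartet_from_sequences
from quartetconv.simulate import ConversionSpec, QuartetSimConfig, simulate_quartet


@pytest.fixture(scope="session")
def fast_config():
    """Pipeline configuration with a reduced bootstrap for unit tests."""
    return PipelineConfig(bootstrap_B=300)


@pytest.fixture(scope="session")
def null_quartet():
    """One conversion-free quartet at the default divergences."""
    seqs, truth = simulate_quartet(QuartetSimConfig(n_codons=400), seed=11)
    return quartet_from_sequences("null0", seqs), truth


@pytest.fixture(scope="session")
def tract_quartet():
    """One quartet with a 90-nt tract implanted at nt 301..390 of P2."""
    conv = ConversionSpec(kind="tract", acceptor="P2", donor="P1",
                          tract_start=301, tract_end=390, time_fraction=1.0)
    seqs, truth = simulate_quartet(
        QuartetSimConfig(n_codons=400, conversion=conv), seed=5
    )
    return quartet_from_sequences("tract0", seqs), truth


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random stop-free CDS."""
    from quartetconv.codontables import SENSE_CODONS, index_codon

    idx = rng.choice(SENSE_CODONS, size=n_codons)
    return "".join(index_codon(int(i)) for i in idx)
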