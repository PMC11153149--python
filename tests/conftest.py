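import pytest

from ragscan.synthetic import SimConfig, make_synthetic_locus


@pytest.fixture(scope="session")
def small_locus():
    """One 120-kb synthetic locus shared across tests (seeded, deterministic)."""
    cfg = SimConfig(locus_length=120_000, n_total_reads=50_000, cryptic_rate=0.2)
    return make_synthetic_locus(cfg, seed=1), cfg


@pytest.fixture(scope="session")
def feature_locus():
    """A locus with planted CBE / E2A / transcription features for annotation tests."""
    cfg = SimConfig(
        locus_length=100_000,
        cbe_positions=(20_000, 55_000),
        e2a_positions=(35_000,),
        transcription_positions=(70_000,),
    )
    return make_synthetic_locus(cfg, seed=7), cfg
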