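import numpy as np
import pytest

from oncopair.simulate import CNSegmentSpec, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """One patient, no planted effects, no noise beyond binomial sampling."""
    cfg = SimulationConfig(
        seed=11,
        n_patients=1,
        n_variant_sites=3_000,
        sequencing_error_rate=0.0,
        rt_artifact_rate=0.0,
        de_gene_fraction=0.0,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def ai_cohort():
    """One patient with a 10:1 allele-specific amplification and RT
    duplicate-start artifacts."""
    cfg = SimulationConfig(
        seed=5,
        n_patients=1,
        n_variant_sites=2_000,
        rt_artifact_rate=0.02,
        cn_segments=[CNSegmentSpec("chr1", 2_000_000, 3_000_000, 10.0, "A")],
    )
    return simulate_cohort(cfg)
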