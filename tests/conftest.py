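import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import arraycnv as ac

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def flat_probes() -> pd.DataFrame:
    """100 evenly spaced probes on one 120 kb chromosome (no jitter)."""
    layout = ac.GenomeLayout((("chr1", 120_000),), probe_spacing_bp=1200.0)
    return ac.simulate_probes(layout, seed=0, jitter_frac=0.0)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """47-sample noiseless cohort with planted loci on two chromosomes."""
    layout = ac.GenomeLayout(
        (("chr1", 600_000), ("chr2", 600_000)), probe_spacing_bp=1200.0
    )
    probes = ac.simulate_probes(layout, seed=11, jitter_frac=0.0)
    samples = [f"S{i + 1:02d}" for i in range(47)]
    cnvs = ac.plant_cohort_cnvs(
        probes, samples, seed=11, n_loci=8, probes_per_locus=(5, 30),
        carrier_freq=(0.2, 0.5), copy_states=(1, 3),
    )
    sm = ac.simulate_signal(probes, cnvs, ac.NoiseModel(0.0, 0.0), 11,
                            samples=samples)
    return probes, samples, cnvs, sm
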