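import numpy as np
import pandas as pd
import pytest

from gcquant import synthetic as syn


@pytest.fixture(scope="session")
def small_plates():
    """Noise-free 10-compound screen with two injected sensitizers."""
    cfg = syn.PlateSimConfig(
        n_compounds=10,
        concentrations=(5.0,),
        well_noise_sd=0.0,
        interaction_set={"cmpd_0001": -0.5, "cmpd_0003": -0.6},
        seed=11,
    )
    return syn.gen_plates(cfg)


@pytest.fixture(scope="session")
def cohort():
    cfg = syn.CohortSimConfig(seed=5)
    return syn.gen_cohort(cfg)


@pytest.fixture(scope="session")
def lfq_complete():
    cfg = syn.LFQSimConfig(n_proteins=300, missing_rate=0.0, seed=9)
    return syn.gen_lfq(cfg)
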