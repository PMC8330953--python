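import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pitfoam.amplicon_qc import OtuTable
from pitfoam.synthetic_cohort import CohortConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_config(**overrides) -> CohortConfig:
    """A desk-scale cohort that still exercises every pipeline stage."""
    defaults = dict(
        n_farms=8,
        n_months=8,
        n_bacterial_otus=120,
        n_methanogen_otus=40,
        n_tail_otus_16s=200,
        n_spurious_otus_16s=60,
        n_tail_otus_mcra=50,
        n_spurious_otus_mcra=15,
        mean_depth_16s=15_000,
        mean_depth_mcra=6_000,
        missingness_rate=0.0,
        seed=11,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture()
def toy_table() -> OtuTable:
    counts = pd.DataFrame(
        {
            "s1": [6, 1, 2, 0],
            "s2": [3, 2, 2, 0],
            "s3": [1, 1, 1, 0],
        },
        index=["otuA", "otuB", "otuC", "otuD"],
    )
    taxonomy = {
        "otuA": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Ruminococcaceae;g__Sporobacter;s__",
        "otuB": "k__Bacteria;p__Firmicutes;c__Clostridia;o__Clostridiales;f__Ruminococcaceae;g__Sporobacter;s__",
        "otuC": "k__Bacteria;p__Firmicutes;c__Clostridia;o__;f__;g__;s__",
        "otuD": "k__Bacteria;p__;c__;o__;f__;g__;s__",
    }
    return OtuTable(counts, taxonomy)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
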