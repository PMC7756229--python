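import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import convergescan as cs

settings.register_profile(
    "det",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_config():
    """Three small species with a shared core and a planted convergent signal."""
    return cs.SimConfig(
        species_ids=("A", "B", "C"),
        annotated_sizes=(120, 110, 100),
        shared_all=80,
        n_pops=6,
        factor_names=("F1", "F2"),
        snps_per_gene=3.0,
        n_planted_convergent=10,
        planted_factor="F1",
        effect_shift=6.0,
        null_outlier_rate=0.02,
        ns_fraction=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_universe(small_config):
    return cs.gen_ortholog_universe(small_config)


@pytest.fixture(scope="session")
def small_tables(small_universe, small_config):
    return cs.gen_scan_table(small_universe, small_config)
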