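import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from neumo.deconvolution import GuideMatrix
from neumo.simulate import simulate_paired_counts

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def two_state_guide() -> GuideMatrix:
    """A small Neu-like / DC-like guide: 6 + 8 one-state markers."""
    genes = [f"NEU{i}" for i in range(6)] + [f"DC{i}" for i in range(8)]
    values = pd.DataFrame(0, index=genes, columns=["Neu-like", "DC-like"])
    values.iloc[:6, 0] = 1
    values.iloc[6:, 1] = 1
    return GuideMatrix(values)


@pytest.fixture(scope="session")
def small_study():
    """A reusable simulated paired study with planted attenuated effects."""
    return simulate_paired_counts(
        n_genes=1000,
        n_pairs_yes=6,
        n_pairs_no=6,
        de_fraction=0.2,
        mean_abs_log2fc=2.0,
        attenuation_factor=0.5,
        dispersion=0.1,
        lib_size=500_000,
        seed=42,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
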