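import numpy as np
import pytest

from rfjem import synthetic as syn


@pytest.fixture(scope="session")
def tiny_jem():
    """Hand-built matrix: two exposed codes, one zero-prevalence, one absent."""
    from rfjem.jem import Jem, JemEntry

    entries = []
    for fk in ("E", "H"):
        entries += [
            JemEntry("1000", fk, intensity=2.0, prevalence=0.10, n_basis=5),
            JemEntry("2000", fk, intensity=0.5, prevalence=0.03, n_basis=3),
            JemEntry("3000", fk, intensity=9.9, prevalence=0.0, n_basis=1),
        ]
    return Jem(entries)


@pytest.fixture(scope="session")
def small_study():
    """One generated null study reused across read-only tests."""
    cfg = syn.SyntheticConfig(n_controls=900, n_glioma=400, n_meningioma=200)
    jem = syn.generate_jem(cfg, seed=12345)
    pdf, jdf, truth = syn.generate_cohort(cfg, jem, seed=54321)
    return cfg, jem, pdf, jdf, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
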