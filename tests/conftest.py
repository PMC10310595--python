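import numpy as np
import pytest

import soilrisk as sr

# Published mean concentrations (mg/kg) for the two e-waste source areas and
# the mean gastric-phase IVBA (%) per element, used as deterministic inputs.
BURNING_MEANS = {
    "Ag": 20.0, "As": 191.0, "Cd": 56.0, "Cr": 139.0, "Cu": 16700.0,
    "Mo": 18.0, "Ni": 138.0, "Pb": 6534.0, "Sb": 554.0, "Sn": 1005.0,
    "Zn": 15470.0,
}
DISMANTLING_MEANS = {
    "Ag": 38.0, "As": 19.0, "Cd": 38.0, "Cr": 337.0, "Cu": 3257.0,
    "Mo": 24.0, "Ni": 96.0, "Pb": 645.0, "Sb": 105.0, "Sn": 130.0,
    "Zn": 1530.0,
}
MEAN_IVBA = {
    "Ag": 65.8, "As": 23.3, "Cr": 8.8, "Cu": 58.9, "Ni": 38.3,
    "Pb": 67.5, "Zn": 58.4,
}


@pytest.fixture(scope="session")
def registry():
    return sr.builtin_registry()


@pytest.fixture(scope="session")
def mean_rba(registry):
    """RBA fractions resolved from the mean IVBA values."""
    elements = set(BURNING_MEANS)
    return {e: sr.resolve_rba(e, MEAN_IVBA.get(e), registry)[0] for e in elements}


def make_sample(concentrations, sample_id="S1", group=sr.SiteGroup.BURNING):
    return sr.SampleRecord(
        sample_id, group,
        measurements={e: sr.Measurement(v) for e, v in concentrations.items()})


@pytest.fixture
def burning_sample():
    return make_sample(BURNING_MEANS, "burn-mean", sr.SiteGroup.BURNING)


@pytest.fixture
def dismantling_sample():
    return make_sample(DISMANTLING_MEANS, "dism-mean", sr.SiteGroup.DISMANTLING)


@pytest.fixture(scope="session")
def small_dataset():
    """Small deterministic synthetic survey shared across tests."""
    cfg = sr.default_config(seed=0, n_per_group={
        "burning": 8, "dismantling": 6, "community": 16, "background": 6})
    return sr.generate(cfg)


def rng(seed=0):
    return np.random.default_rng(seed)
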