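import numpy as np
import pytest

from paleotroph import SpeciesSpec, SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_config(**overrides) -> SyntheticConfig:
    """A small two-epoch web: modern piscivore + fossil megatooth pair."""
    defaults = dict(
        species_list=[
            SpeciesSpec("Carcharias taurus", "Carcharias", "Modern", 4.4, True, 13),
            SpeciesSpec("Carcharias spp.", "Carcharias", "Miocene", 4.4, True, 12),
            SpeciesSpec("Otodus megalodon", "Otodus", "Miocene", 7.3, False, 12),
        ],
        seed=11,
    )
    defaults.update(overrides)
    cfg = SyntheticConfig(**defaults)
    cfg.validate()
    return cfg


@pytest.fixture
def small_config():
    return make_config()


def noise_free(**overrides) -> SyntheticConfig:
    """Config with every stochastic term switched off."""
    base = dict(
        biological_sd=0.0,
        meas_sd_eb=0.0,
        meas_sd_dentin=0.0,
        ref_meas_sd=0.0,
        blank_nmol_range=(0.0, 0.0),
        cal_slope=1.0,
        cal_intercept=0.0,
        standard_within_sd=0.0,
        standard_between_sd=0.0,
        standard_ncontent_within_sd=0.0,
        standard_ncontent_between_sd=0.0,
    )
    base.update(overrides)
    return make_config(**base)
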