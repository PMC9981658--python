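import dataclasses

import pytest

import cyclewell as cw


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (12 athletes, 150 days, seed 42)."""
    config = cw.SyntheticConfig(seed=42)
    profiles, records, samples = cw.generate_cohort(config)
    return config, profiles, records, samples


@pytest.fixture(scope="session")
def mc_only_config():
    """Natural-cycle athletes only: the enrichment simulation unit."""
    return cw.SyntheticConfig(n_mc_athletes=6, n_amenorrheic=0, n_hc_athletes=0)


@pytest.fixture()
def make_null_config(mc_only_config):
    from cyclewell.synthetic import null_cohort_config

    def _make(seed):
        return dataclasses.replace(null_cohort_config(mc_only_config), seed=seed)

    return _make
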