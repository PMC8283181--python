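import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table2_cohort():
    from faerspv.synth import build_table2_fixture

    return build_table2_fixture()


@pytest.fixture(scope="session")
def table2_spec():
    import json
    from importlib import resources

    return json.loads(
        resources.files("faerspv.data").joinpath("table2.json").read_text())


@pytest.fixture(scope="session")
def characteristics(table2_cohort):
    from faerspv.features import build_characteristics_table

    return build_characteristics_table(table2_cohort)


@pytest.fixture(scope="session")
def synthetic_quarter():
    """A small associated database: quarter, ledger and config."""
    from faerspv.synth import default_config, generate_database

    cfg = default_config(n_reports=6000, association={"nivolumab": 4.0})
    cfg.drugs[0].exposure_prob = 0.05
    cfg.pericardial_prob = 0.01
    quarter, ledger = generate_database(cfg, seed=11)
    return cfg, quarter, ledger


@pytest.fixture(scope="session")
def synthetic_reports(synthetic_quarter):
    from faerspv.cohort import deduplicate
    from faerspv.io import assemble_reports

    _cfg, quarter, _ledger = synthetic_quarter
    return deduplicate(assemble_reports(quarter))
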