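import pytest

from longmicro.simulate import CohortConfig, emit_fixture, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six subjects, one year of monthly samples, in memory."""
    cfg = CohortConfig(n_subjects=6, max_age_days=360, seed=0)
    records, tax, table, truth = generate_cohort(cfg)
    return cfg, records, tax, table, truth


@pytest.fixture(scope="session")
def tiny_fixture_dir(tmp_path_factory):
    """The tiny TSV fixture written to disk (exercises all writers)."""
    out = tmp_path_factory.mktemp("tiny") / "fx"
    emit_fixture("tiny", out, seed=0)
    return out


@pytest.fixture(scope="session")
def midsize_cohort():
    """A cohort big enough for window/pair statistics (two-year follow-up)."""
    cfg = CohortConfig(n_subjects=40, max_age_days=730, seed=3)
    records, tax, table, truth = generate_cohort(cfg)
    return cfg, records, tax, table, truth
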