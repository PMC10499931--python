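import pytest
from hypothesis import settings

from consevo import CohortConfig, RunConfig, generate_cohort, run_pipeline

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, generated once per session."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_dir(default_cohort, tmp_path_factory):
    path = tmp_path_factory.mktemp("cohort") / "cohort"
    default_cohort.write(path)
    return path


@pytest.fixture(scope="session")
def pipeline_run(cohort_dir, tmp_path_factory):
    """A full pipeline run over the default cohort."""
    outdir = tmp_path_factory.mktemp("run") / "out"
    cfg = RunConfig(cohort_dir=cohort_dir, outdir=outdir)
    manifest = run_pipeline(cfg)
    return cfg, manifest
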