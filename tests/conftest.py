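import pytest

from ligandatlas.config import PipelineConfig
from ligandatlas.synthetic_data import generate_cohort


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def cohort():
    """One shared default synthetic cohort (the study conditions)."""
    return generate_cohort(seed=7)


@pytest.fixture(scope="session")
def cohort_dir(cohort, tmp_path_factory):
    """The shared cohort written out as its text-file inputs."""
    outdir = tmp_path_factory.mktemp("cohort")
    paths = cohort.write(outdir)
    return paths
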