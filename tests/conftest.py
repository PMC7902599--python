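import pytest

from pollenx import pipeline
from pollenx.simulate import GroundTruth, SimConfig, simulate_run


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A small simulated cohort written to disk once per session."""
    outdir = tmp_path_factory.mktemp("cohort")
    simulate_run(SimConfig(seed=3, n_novel_loci=60), outdir=outdir)
    return outdir


@pytest.fixture(scope="session")
def cohort_truth(cohort_dir):
    return GroundTruth.from_json(cohort_dir / "ground_truth.json")


@pytest.fixture(scope="session")
def cohort_result(cohort_dir):
    return pipeline.run_pipeline(cohort_dir)
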