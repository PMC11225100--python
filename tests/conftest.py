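import numpy as np
import pytest

from precisim.config import load_study_config, paper_config_path
from precisim.performance import summarize_performance
from precisim.simstudy import run_study


@pytest.fixture(scope="session")
def paper_config():
    return load_study_config(paper_config_path())


@pytest.fixture(scope="session")
def paper_study(paper_config):
    """Full canonical study run (6 scenarios x 1000 reps), shared by tests."""
    results, provenance = run_study(paper_config)
    summary = summarize_performance(
        results,
        paper_config.true_values(),
        ref_method=paper_config.ref_method,
        alpha=paper_config.alpha,
    )
    return {"config": paper_config, "results": results, "summary": summary,
            "provenance": provenance}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
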