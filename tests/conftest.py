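"""Shared fixtures: all inputs are generated programmatically at test time."""
from __future__ import annotations

import pytest

from pgxtwist import (
    SimConfig,
    ryr3_hf_config,
    simulate_cohort,
    truth_analysis_table,
    write_study,
)


@pytest.fixture(scope="session")
def ryr3_small_truth():
    """rs877087/HF study conditions scaled to a tenth of the cohort."""
    cfg = ryr3_hf_config(n_treated=3_100, n_untreated=19_000, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def ryr3_small_table(ryr3_small_truth):
    return truth_analysis_table(ryr3_small_truth)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """A written study bundle plus its generating truth (3000 patients)."""
    cfg = SimConfig(n_patients=3_000, p_treated=0.3, rng_seed=7)
    truth = simulate_cohort(cfg)
    out = tmp_path_factory.mktemp("bundle")
    write_study(truth, out)
    return truth, out
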