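import numpy as np
import pandas as pd
import pytest

from oncotrace import scenario
from oncotrace.layout import GenomeLayout, TruthSet


@pytest.fixture(scope="session")
def small_layout() -> GenomeLayout:
    return GenomeLayout({"chr1": 1_000_000, "chr2": 500_000})


@pytest.fixture(scope="session")
def neutral_truth() -> TruthSet:
    return TruthSet()


@pytest.fixture(scope="session")
def scenario_run() -> scenario.ScenarioRun:
    """One full end-to-end two-timepoint run, shared across tests."""
    return scenario.run_two_timepoint_scenario(seed=11)


def uniform_track(chrom="chr1", length=1000, n_windows=100, reads_per_window=1):
    """Constant-density read-count track on one chromosome."""
    width = length // n_windows
    starts = np.arange(n_windows) * width
    return pd.DataFrame({
        "chrom": chrom, "start": starts, "end": starts + width,
        "count": reads_per_window,
    })
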