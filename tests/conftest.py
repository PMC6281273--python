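import pandas as pd
import pytest

from longmeth import binning, dmr
from longmeth import io as mio
from longmeth import simulate as sim


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale cohort: 1 chromosome, 4,000 CpGs, 4 planted hyper blocks."""
    return sim.SimulationConfig(
        seed=11, n_chroms=1, cpgs_per_chrom=4000, n_planted=4
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return sim.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    pooled = mio.pool_replicates(small_cohort["samples"])
    retained = mio.filter_min_coverage(pooled, min_cov=3)
    ws = binning.build_cpg_windows(retained)
    win = binning.window_methylation(ws, pooled)
    return ws, win


@pytest.fixture(scope="session")
def small_dmrs(small_windows):
    _, win = small_windows
    return dmr.call_dmrs(win, contrast=("control", "treated"))


def make_calls(rows):
    """rows: (chrom, pos, n_meth, n_unmeth) tuples -> calls DataFrame."""
    return pd.DataFrame(rows, columns=["chrom", "pos", "n_meth", "n_unmeth"])
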