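import numpy as np
import pytest

import mtbfocus as m


@pytest.fixture(scope="session")
def coarse_binning():
    """GRCh38 at 10 Mb bins (~320 bins): fast unit-test resolution."""
    return m.default_binning(10_000_000)


@pytest.fixture(scope="session")
def coarse_pon(coarse_binning):
    cfg = m.SimulationConfig(seed=11, total_reads=500_000, n_normals=8)
    normals = m.simulate_normal_profiles(coarse_binning, cfg)
    return m.build_panel_of_normals(normals)


@pytest.fixture()
def flat_ratio_profile():
    """All-zero ratio profile on a two-contig toy genome."""
    binning = m.toy_binning(n_contigs=2, contig_length=100_000, bin_width=1_000)
    n = binning.n_bins
    return m.RatioProfile(log2=np.zeros(n), valid=np.ones(n, dtype=bool),
                          binning=binning, sex="female")
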