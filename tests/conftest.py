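import matplotlib

matplotlib.use("Agg")

import pandas as pd
import pytest

from bafgrid.grid import CopyState, GridSolution
from bafgrid.simulate import Segment, SegmentProfile, SimTruth


def make_truth(
    states,
    n_loci=200,
    cellularity=0.68,
    single_copy_depth=15.0,
    seed=0,
    spacing=0,
    depth_noise="poisson",
    chrom="1",
):
    """A single-chromosome truth with one segment per state."""
    span = max(n_loci * max(spacing, 1) + 1, 10 * n_loci)
    segs = tuple(
        Segment(chrom, 1 + i * (span + 10), i * (span + 10) + span,
                CopyState(n1, n2), n_loci)
        for i, (n1, n2) in enumerate(states)
    )
    return SimTruth(
        SegmentProfile(segs),
        GridSolution(cellularity, single_copy_depth),
        seed=seed,
        depth_noise=depth_noise,
        spacing=spacing,
    )


@pytest.fixture(scope="session")
def tetraploid_smoothed():
    """Smoothed observations from the bundled tetraploid example truth."""
    from bafgrid.simulate import example_tetraploid_truth, simulate_observations
    from bafgrid.smooth import running_smooth

    truth = example_tetraploid_truth(300, seed=3)
    obs = simulate_observations(truth)
    return truth, obs, running_smooth(obs, 51)


@pytest.fixture()
def flat_observations():
    """A degenerate frame with every locus at the same point."""
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": range(1, 101),
            "depth": 40.0,
            "minor_fraction": 0.5,
        }
    )
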