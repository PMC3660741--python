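import warnings

import numpy as np
import pytest

from symanchor.core_structures import make_cn_group
from symanchor.symmetric_placement import place_ligand
from symanchor.synthetic_data import (ChannelSpec, ToxinSpec, gen_c4_channel,
                                      gen_placement_problem, gen_toxin)

NOISE_LEVELS = (0.0, 0.25, 0.5, 1.0, 2.0)
N_REPLICATES = 200


@pytest.fixture(scope="session")
def c4_group():
    return make_cn_group([0.0, 0.0, 0.0], [0.0, 0.0, 1.0], 4)


@pytest.fixture(scope="session")
def channel():
    return gen_c4_channel(ChannelSpec(), seed=0)


@pytest.fixture(scope="session")
def toxin():
    return gen_toxin(ToxinSpec(), seed=0)


@pytest.fixture(scope="session")
def placement_noise_stats():
    """Marker-RMSD and rotation-error statistics of exhaustive placement
    across noise levels, shared by the calibration and monotonicity tests.

    One disambiguated peak per marker (the calibrated configuration); the
    axis filter is off because no spurious peaks are generated and at large
    noise a genuine peak can wander near the axis.
    """
    stats = {}
    for sigma in NOISE_LEVELS:
        rmsds, rot_errs = [], []
        for i in range(N_REPLICATES):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                problem, truth = gen_placement_problem(
                    noise_sd=sigma, peaks_per_marker="single", seed=20000 + i)
                result = place_ligand(problem, filter_axis=False)
            rmsds.append(result.rmsd_markers)
            errs = []
            for pose in result.equivalent_poses:
                R = pose.rotation @ truth["pose"].rotation.T
                errs.append(np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1))))
            rot_errs.append(min(errs))
        stats[sigma] = {"median_rmsd": float(np.median(rmsds)),
                        "median_rot_err_deg": float(np.median(rot_errs))}
    return stats
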