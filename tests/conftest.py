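import numpy as np
import pandas as pd
import pytest

from vofdissect import PhantomConfig, SelectionCriteria, make_phantom
from vofdissect.tract_io import ParcellationVolume


@pytest.fixture(scope="session")
def small_phantom():
    """Well-separated left-hemisphere phantom with all four bundle kinds."""
    config = PhantomConfig(n_vof=400, n_ilf=60, n_af=60, n_clutter=40, seed=3)
    return make_phantom(config)


@pytest.fixture(scope="session")
def small_report(small_phantom):
    from vofdissect import run_selection

    criteria = SelectionCriteria(
        hemisphere="L",
        lateral_reference=small_phantom.bundle("ilf"),
        posterior_reference=small_phantom.bundle("af"),
    )
    return run_selection(small_phantom.tractogram, small_phantom.parcellation, criteria)


def tiny_parcellation(shape=(8, 8, 8), voxel=2.0, labels_spec=None):
    """Handmade parcellation on a small grid for brute-force oracle tests.

    ``labels_spec``: list of (label_id, voxel-index slices) painted in order.
    """
    grid = np.zeros(shape, dtype=np.int64)
    if labels_spec is None:
        labels_spec = [(1, (slice(0, 3), slice(0, 8), slice(5, 8))),
                       (2, (slice(5, 8), slice(0, 8), slice(0, 3)))]
    rows = []
    groups = ["dorsal", "ventral", "lateral_occipital", "other"]
    for k, (label, sl) in enumerate(labels_spec):
        grid[sl] = label
        rows.append({"label_id": label, "name": f"P{label}", "hemisphere": "L",
                     "group": groups[k % 3], "r": 10 * label, "g": 20, "b": 30})
    affine = np.diag([voxel, voxel, voxel, 1.0])
    return ParcellationVolume(labels=grid, affine=affine, table=pd.DataFrame(rows))


@pytest.fixture
def tiny_parc():
    return tiny_parcellation()
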