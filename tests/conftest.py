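import numpy as np
import pytest

from swathbench import IntensityTable


def make_table(values, groups=None, dataset_id="test"):
    """Small helper: build an IntensityTable from a 2-D array-like.

    ``groups`` maps sample index ranges implicitly: by default all samples
    share one group "G"; pass a list of group labels (one per column) to
    override.
    """
    values = np.asarray(values, dtype=float)
    p, s = values.shape
    protein_ids = [f"p{i + 1}" for i in range(p)]
    sample_ids = [f"s{j + 1}" for j in range(s)]
    if groups is None:
        group_map = {sid: "G" for sid in sample_ids}
    else:
        group_map = {sid: g for sid, g in zip(sample_ids, groups)}
    return IntensityTable(protein_ids, sample_ids, values, group_map,
                          dataset_id=dataset_id)


@pytest.fixture
def two_group_table():
    """Complete positive 30x6 table with two 3-replicate groups."""
    rng = np.random.default_rng(42)
    values = np.exp(rng.normal(14, 2, size=(30, 6)))
    return make_table(values, groups=["A", "A", "A", "B", "B", "B"])


@pytest.fixture
def missing_table():
    """200x8 two-group table with ~10% missing cells."""
    rng = np.random.default_rng(7)
    values = np.exp(rng.normal(14, 2, size=(200, 8)))
    holes = rng.random(values.shape) < 0.1
    values[holes] = np.nan
    return make_table(values, groups=["A"] * 4 + ["B"] * 4)
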