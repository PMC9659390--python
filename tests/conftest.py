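import numpy as np
import pytest

from nucleopart import (
    PhantomSpec,
    make_phantom_field,
    segment_micrograph,
)


@pytest.fixture(scope="session")
def clean_phantom():
    """One noise-free 9-cell phantom field with (1, 4, 8) reporter levels."""
    spec = PhantomSpec(
        n_cells=9,
        reporter_conc=(1.0, 4.0, 8.0),
        shot_noise=False,
        read_noise_sd=0.0,
        seed=100,
    )
    m, truth = make_phantom_field(spec)
    return spec, m, truth


@pytest.fixture(scope="session")
def segmented_phantom(clean_phantom):
    """The clean phantom run through the full segmentation chain."""
    spec, m, truth = clean_phantom
    return spec, m, truth, segment_micrograph(m)


def match_truth_cell(cell_mask, truth):
    """Ground-truth cell label whose region holds the mask centroid."""
    rr, cc = np.nonzero(cell_mask)
    return int(truth.cell_labels[int(rr.mean()), int(cc.mean())])
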