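import numpy as np
import pytest

from isckit.datamodel import BrainMask, SessionDataset, SubjectTimeSeriesVolume
from isckit.synthetic import SyntheticSpec, synth_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(data, tr=2.0, subject_id="sub-00"):
    return SubjectTimeSeriesVolume(
        data=np.asarray(data, dtype=float),
        affine=np.eye(4),
        tr_seconds=tr,
        subject_id=subject_id,
    )


def make_session(arrays, tr=2.0, mask=None, label="test"):
    """Session from a list of (X, Y, Z, T) arrays with a full mask by default."""
    vols = [make_volume(a, tr=tr, subject_id=f"sub-{k:02d}") for k, a in enumerate(arrays)]
    if mask is None:
        mask = BrainMask(mask=np.ones(vols[0].spatial_shape, dtype=bool))
    return SessionDataset(subjects=vols, mask=mask, condition_label=label)


@pytest.fixture
def tiny_session():
    """Small correlated session: N=4, 3x3x2 grid, T=60, true rho=0.4."""
    return synth_session(
        SyntheticSpec(n_subjects=4, T=60, rho=0.4, dims=(3, 3, 2), seed=7)
    )


@pytest.fixture
def null_session():
    """No shared signal: N=4, pink noise only."""
    return synth_session(
        SyntheticSpec(n_subjects=4, T=60, rho=0.0, dims=(3, 3, 2), seed=11)
    )
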