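import numpy as np
import pandas as pd
import pytest

from braincca import SyntheticSpec, generate_linked_blocks, standardize


@pytest.fixture(scope="session")
def single_mode_cohort():
    """Strong single-mode cohort, standardized blocks plus ground truth."""
    spec = SyntheticSpec(
        n_subjects=500,
        p_imaging=30,
        q_nonimaging=20,
        n_modes=1,
        support_x=(5,),
        support_y=(5,),
        target_r=(0.7,),
        noise_sd=1.0,
        seed=11,
    )
    data, truth = generate_linked_blocks(spec)
    return standardize(data.imaging), standardize(data.nonimaging), truth


@pytest.fixture(scope="session")
def null_cohort():
    """Independent blocks (no shared modes), standardized."""
    spec = SyntheticSpec(
        n_subjects=300,
        p_imaging=20,
        q_nonimaging=20,
        n_modes=0,
        support_x=(),
        support_y=(),
        target_r=(),
        noise_sd=1.0,
        seed=7,
    )
    data, _ = generate_linked_blocks(spec)
    return standardize(data.imaging), standardize(data.nonimaging)


def make_frame(arr, prefix="v"):
    arr = np.asarray(arr, dtype=float)
    ids = pd.Index([f"sub-{i:05d}" for i in range(arr.shape[0])], name="subject_id")
    return pd.DataFrame(arr, index=ids, columns=[f"{prefix}{j}" for j in range(arr.shape[1])])
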