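import numpy as np
import pytest
from hypothesis import settings

from fetclust.io import FrameSchedule
from fetclust.segmentation import (build_template, smooth_gaussian,
                                   static_from_dynamic)
from fetclust.synthetic import PhantomSpec, simulate_phantom, simulate_tacs
from fetclust.tac import TACMatrix, kmeans_dtw, label_centroids, znormalize

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def normal_template():
    """Template from 41 lesion-free phantom subjects (smoothed statics)."""
    statics = []
    for i in range(41):
        img, _ = simulate_phantom(PhantomSpec(seed=500 + i, lesions=[]))
        st = static_from_dynamic(img)
        st.voxels = smooth_gaussian(st.voxels, 8.0, img.voxel_size)
        statics.append(st)
    return build_template(statics)


@pytest.fixture(scope="session")
def labeled_centroids(schedule):
    """3-centroid model trained once on 300 archetype TACs (noise SD 0.2)."""
    X, _ = simulate_tacs(100, noise_sd=0.2, seed=7)
    mat = znormalize(TACMatrix(X, np.zeros((X.shape[0], 3), int)))
    cs, _, _ = kmeans_dtw(mat, 3, seed=7)
    return label_centroids(cs, schedule)
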