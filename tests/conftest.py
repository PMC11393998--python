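import numpy as np
import pytest

import bovimetry as bv


@pytest.fixture(scope="session")
def K():
    return bv.DEFAULT_INTRINSICS


@pytest.fixture(scope="session")
def pose():
    return bv.CameraPose()


@pytest.fixture(scope="session")
def default_model():
    return bv.build_cattle_model()


@pytest.fixture(scope="session")
def default_scene(default_model, pose, K):
    """Noiseless canonical scene: (model, depth image, keypoints)."""
    img = bv.render_depth(default_model, pose, K)
    kps = bv.ground_truth_keypoints(default_model, pose, K, img=img)
    return default_model, img, kps


@pytest.fixture(scope="session")
def cylinder_scene(pose, K):
    """Circular-cylinder torso (r = 350 mm), the girth oracle scene."""
    model = bv.build_cattle_model(torso_semi_depth=350.0, torso_semi_height=350.0)
    img = bv.render_depth(model, pose, K)
    kps = bv.ground_truth_keypoints(model, pose, K, img=img)
    return model, img, kps


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
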