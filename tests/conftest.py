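import numpy as np
import pytest

import shapesim as ss


@pytest.fixture(scope="session")
def shape_set():
    """Default 3x3 orthogonal (class x envelope) silhouette set."""
    return ss.generate_shape_set(ss.StimulusDesign(seed=7))


@pytest.fixture(scope="session")
def references(shape_set):
    """Physical (pixelwise) and perceived (class-block) reference RDMs."""
    pix = ss.stack_features(shape_set, ss.pixelwise_features, model_name="pixelwise")
    rdm_physical = ss.compute_rdm(pix, metric="correlation")
    labels = [s.class_labels["perceived"] for s in shape_set]
    rdm_perceived = ss.class_block_rdm(labels, pix.stimulus_ids)
    return pix, rdm_physical, rdm_perceived


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rdm(n, rng, strata=None, ids=None):
    """A random valid RDM on n stimuli."""
    tri = rng.uniform(0.1, 2.0, size=(n, n))
    vals = (tri + tri.T) / 2
    ids = ids or [f"s{i}" for i in range(n)]
    return ss.RDM(values=vals, stimulus_ids=ids, strata=strata)
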