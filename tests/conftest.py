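import numpy as np
import pytest

from muzzleid.annotations import crop_roi
from muzzleid.preprocess import preprocess
from muzzleid.synthetic import (
    CaptureParams,
    make_individual,
    render_base_pattern,
    render_capture,
    sample_population,
)


@pytest.fixture(scope="session")
def small_population(tmp_path_factory):
    """A 12-individual default-noise population written to disk."""
    out = tmp_path_factory.mktemp("pop12")
    manifest = sample_population(12, out, master_seed=7)
    return manifest


def canonical_capture(seed: int, params: CaptureParams, base=None, spec=None):
    """Render one capture and push it through crop + preprocessing."""
    spec = spec or make_individual(seed)
    record, ann = render_capture(spec, params, base=base)
    return preprocess(crop_roi(record.image, ann))


@pytest.fixture(scope="session")
def canonical_trio():
    """Two captures of one individual plus one of another, canonicalized."""
    s0, s1 = make_individual(3), make_individual(4)
    b0, b1 = render_base_pattern(s0), render_base_pattern(s1)
    mild = dict(blur_sigma=0.4, noise_sd=0.01)
    a1 = canonical_capture(3, CaptureParams(rotation_deg=1.0, translation=(3.0, -2.0),
                                            capture_seed=21, **mild), base=b0, spec=s0)
    a2 = canonical_capture(3, CaptureParams(rotation_deg=-1.5, translation=(-4.0, 5.0),
                                            capture_seed=22, **mild), base=b0, spec=s0)
    b = canonical_capture(4, CaptureParams(rotation_deg=0.5, translation=(1.0, 1.0),
                                           capture_seed=23, **mild), base=b1, spec=s1)
    return a1, a2, b


def textured_image(seed: int, shape=(96, 128), smooth=1.0):
    """Small seeded texture with structure at the matcher's cell scale."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.standard_normal(shape), smooth)
    return ((img - img.mean()) / img.std()).astype(np.float32)
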