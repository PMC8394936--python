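import numpy as np
import pytest
from scipy import ndimage

from ciliaquant import synth


def render_single_cilium(angle_deg, jitter_seed=0, subtype=None, size=220,
                         noise_sd=8.0, blur_sigma=1.5, noise_seed=0,
                         diameter=110):
    """One cilium centred in a small noisy image, rendered like a scene."""
    if subtype is None:
        spec = synth.CiliumSpec(center=(size / 2, size / 2),
                                angle_deg=angle_deg, jitter_seed=jitter_seed,
                                outer_diameter_px=diameter)
    else:
        spec = synth.CiliumSpec(
            center=(size / 2, size / 2),
            defect_class=synth.SUBTYPE_CLASS[subtype],
            defect_subtype=subtype, angle_deg=angle_deg,
            jitter_seed=jitter_seed, outer_diameter_px=diameter)
    canvas = np.full((size, size), synth.BACKGROUND, dtype=float)
    synth.render_cilium(spec, canvas)
    if blur_sigma:
        canvas = ndimage.gaussian_filter(canvas, blur_sigma)
    if noise_sd:
        rng = np.random.default_rng(noise_seed)
        canvas = canvas + rng.normal(0.0, noise_sd, canvas.shape)
    return np.clip(np.rint(canvas), 0, 255).astype(np.uint8), spec


@pytest.fixture(scope="session")
def template_scorer():
    from ciliaquant.detection import TemplateScorer
    return TemplateScorer()


@pytest.fixture(scope="session")
def small_scene():
    """A deterministic mixed scene small enough for fast tests."""
    return synth.render_scene(6, class_mix=(0.6, 0.2, 0.2),
                              image_size=(560, 560), seed=42,
                              image_id="small")
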