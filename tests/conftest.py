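"""Shared fixtures.

Heavy artifacts (phantoms, trained models) are session-scoped so the suite
generates them once.  All randomness is seeded; reruns are bit-identical.
"""

from __future__ import annotations

import pytest

from zernseg.models import ModelConfig, build_model
from zernseg.phantom import PhantomSpec, generate_phantom_full
from zernseg.trainer import ground_truth_from_labels, train

#: small, fast phantom for unit tests (still >= 32 in every dimension)
SMALL_SPEC = PhantomSpec(
    shape=(32, 64, 64),
    n_lacunae=4,
    lacuna_radii_vox=(2.5, 4.5),
    concavity_depth_vox=4.0,
    seed=3,
)

#: full-size phantom matching the reference acquisition cross-section scale
DEFAULT_SPEC = PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom_full(SMALL_SPEC)


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom_full(DEFAULT_SPEC)


@pytest.fixture(scope="session")
def trained_unet_small(small_phantom):
    """A U-Net trained briefly on the small phantom (for plumbing tests)."""
    vol, lab = small_phantom.gray, small_phantom.labels
    gt = ground_truth_from_labels(vol, lab, 8)
    model = build_model(
        ModelConfig(architecture="unet2d", patch_size_vox=32, base_channels=8, depth=2, seed=0)
    )
    run = train(model, gt, 32, seed=0, volume=vol, max_epochs=8, class_weights="balanced")
    return model, run

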