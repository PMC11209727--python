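import numpy as np
import pytest

from podkit.annotations import ImageAnnotation, PodAnnotation
from podkit.synthetic import SceneConfig, generate_scene


@pytest.fixture
def three_seed_pod() -> PodAnnotation:
    return PodAnnotation(pod_id=7, n_seeds=3, seeds=[(50.0, 80.0), (60.0, 70.0), (70.0, 60.0)])


@pytest.fixture
def simple_annotation(three_seed_pod) -> ImageAnnotation:
    return ImageAnnotation(
        image_id="img0",
        width=200,
        height=200,
        pods=[
            three_seed_pod,
            PodAnnotation(pod_id=8, n_seeds=1, seeds=[(120.0, 150.0)]),
            PodAnnotation(pod_id=9, n_seeds=2, seeds=[(30.0, 160.0), (40.0, 170.0)]),
        ],
    )


def toy_scene_config(seed: int, **overrides) -> SceneConfig:
    """Desk-scale scene geometry shared by detector round-trip tests."""
    kw = dict(
        width=256, height=256, pods_per_image=5, seed_spacing=12,
        spacing_jitter=2, seed_radius=4, curvature_jitter=1.5,
        overlap_fraction=0.1, rng_seed=seed,
    )
    kw.update(overrides)
    return SceneConfig(**kw)


@pytest.fixture
def toy_scene():
    return generate_scene(toy_scene_config(3))


def training_crop_config(seed: int) -> SceneConfig:
    """128 x 128 crops used by the toy-trainer smoke tests."""
    return SceneConfig(
        width=128, height=128, pods_per_image=(1, 3), seed_spacing=12,
        spacing_jitter=2, seed_radius=4, curvature_jitter=1.5,
        overlap_fraction=0.1, rng_seed=seed,
    )


def make_training_set(n: int, seed0: int):
    return [generate_scene(training_crop_config(seed0 + i)) for i in range(n)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
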