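import numpy as np
import pytest

from widif.image_io import TimeSeriesCurve, default_frame_schedule
from widif.phantom import (
    DynamicPhantomSpec,
    InputFunctionModel,
    StaticPhantomSpec,
    generate_dynamic_phantom,
    generate_static_tube_phantom,
    model_input_function,
)


@pytest.fixture(scope="session")
def schedule():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def input_model():
    return InputFunctionModel()


@pytest.fixture(scope="session")
def input_curve(schedule, input_model) -> TimeSeriesCurve:
    t = np.arange(0.0, schedule.span_s + 0.5, 0.5)
    return model_input_function(input_model, t)


@pytest.fixture(scope="session")
def static_phantom():
    """Default 6-mm tube phantom, 2.1 mm PSF, noise-free."""
    spec = StaticPhantomSpec()
    image, truth = generate_static_tube_phantom(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def small_dynamic_spec():
    """Cropped dynamic phantom for fast tests (same voxel size/schedule)."""
    return DynamicPhantomSpec(grid_shape=(64, 64, 36), seed=7)


@pytest.fixture(scope="session")
def small_dynamic_phantom(small_dynamic_spec):
    return generate_dynamic_phantom(small_dynamic_spec)


@pytest.fixture(scope="session")
def noise_free_dynamic_phantom():
    spec = DynamicPhantomSpec(grid_shape=(64, 64, 36), noise_scale=0.0, seed=1)
    return spec, generate_dynamic_phantom(spec)
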