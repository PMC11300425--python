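import numpy as np
import pytest

from uricads.annotations import CaseAnnotation, Lesion
from uricads.phantom import PhantomConfig, generate_phantom


@pytest.fixture
def simple_annotation() -> CaseAnnotation:
    """A hand-built pathological case on a 64x64 frame."""
    return CaseAnnotation(
        image_id="case_0",
        size=(64, 64),
        healthy=False,
        global_flags={"HC": False, "PCD": True},
        kidney_polygon=np.array([[10.0, 10.0], [54.0, 10.0],
                                 [54.0, 50.0], [10.0, 50.0]]),
        lesions=[Lesion(box=(20.0, 30.0, 22.0, 30.0), code="SCY")],
    )


@pytest.fixture
def healthy_annotation() -> CaseAnnotation:
    return CaseAnnotation(
        image_id="case_h",
        size=(64, 64),
        healthy=True,
        global_flags={"HC": False, "PCD": False},
        kidney_polygon=np.array([[8.0, 12.0], [56.0, 12.0],
                                 [56.0, 52.0], [8.0, 52.0]]),
        lesions=[],
    )


@pytest.fixture(scope="session")
def lesion_phantom():
    """One 96x96 phantom with a planted cyst and its exact annotation."""
    return generate_phantom(PhantomConfig(seed=3, lesions=(("C", 1),)))


@pytest.fixture(scope="session")
def tiny_model():
    """A reduced-width untrained network, shared across read-only tests."""
    from uricads.model import ModelConfig, SCDCNN

    return SCDCNN(ModelConfig.tiny(seed=7))
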