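import numpy as np
import pytest

from pectseg import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_trio():
    """One 128x128 phantom with annotations: (image, mask, annotations)."""
    return generate_phantom(PhantomSpec(image_size=(128, 128), n_annotations=4, seed=7))


def random_label_mask(rng: np.random.Generator, shape=(6, 6), n_classes=3) -> np.ndarray:
    return rng.integers(0, n_classes, size=shape).astype(np.uint8)
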