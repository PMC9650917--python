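import numpy as np
import pytest

from sonovid.encoder import Encoder, EncoderConfig
from sonovid.synthio import ClipParams, generate_clip


@pytest.fixture(scope="session")
def small_clips():
    """Eight in-memory 64x64 clips (4 benign / 4 malignant, T=8)."""
    return [
        generate_clip(ClipParams(T=8, H=64, W=64, class_label=label, seed=s))
        for label in ("benign", "malignant")
        for s in range(4)
    ]


@pytest.fixture(scope="session")
def tiny_encoder():
    """A shared tiny encoder (m=128); tests must not mutate its weights."""
    return Encoder(EncoderConfig.tiny(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
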