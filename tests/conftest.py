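import numpy as np
import pytest

from patdist.features import C1Stack, GaborBankConfig

# small-scale extractor settings used throughout the unit tests: 8 Gabor
# scales (largest filter 21 px) and small template extents, so modest
# synthetic frames host every size class
SMALL_EXTRACTOR = dict(n_scales=8, size_classes=(2, 4, 6, 8))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_c1_stack(rng, n_channels=2, n_orient=4, shapes=((8, 8), (6, 6)),
                    config=None) -> C1Stack:
    """A small random C1 stack for signature/oracle tests (values >= 0)."""
    bands = [rng.random((n_channels, n_orient, h, w)) for h, w in shapes]
    return C1Stack(
        bands=bands,
        channel_names=tuple(f"ch{i}" for i in range(n_channels)),
        config=config or GaborBankConfig().truncated(2 * len(shapes)),
    )
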