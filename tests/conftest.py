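import numpy as np
import pytest

from strobex import MinimizerOrder, StrobemerParams


def random_dna(rng, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_params():
    # n=3, l=7, v=16, w=11: span 49, min_cover 27
    return StrobemerParams(n=3, l=7, v=16, w=11)


@pytest.fixture(params=["hash", "lexicographic"])
def any_order(request):
    return MinimizerOrder(mode=request.param)


@pytest.fixture
def hash_order():
    return MinimizerOrder(mode="hash")
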