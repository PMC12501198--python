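from itertools import product as _iproduct

import numpy as np
import pytest

from phiid import (
    DiscreteDynSystem,
    build_product_lattice,
    make_copy_system,
    make_downward_xor,
    make_global_bit,
    make_ppr,
)


def three_channel_system(p0: float, q: float, s: float) -> DiscreteDynSystem:
    """A system with three independent binary channels so that duplication,
    storage and transfer strengths can be dialled separately.

    Part 1's past holds three bits (b0, b1, bs); part 2's past one bit.
    b0 passes through two independent flip-p0 channels into both futures
    (duplication, un1->red); b1 through a flip-q channel into part 1's future
    only (self-storage); bs is parity-encoded with X2_t and sent through a
    flip-s channel into part 2's future (synergistic transfer).  Under MMI:
    AIS(1) = f(p0) + f(q), TE(1->2) = f(p0) + f(s), and the un1->red atom is
    exactly f(p0), where f(p) = 1 - h2(p).
    """
    pmf = np.zeros((8, 2, 4, 4))
    for b0, b1, bs, x2, e0, e1, e0p, ep in _iproduct((0, 1), repeat=8):
        x1 = b0 * 4 + b1 * 2 + bs
        y1 = (b0 ^ e0) * 2 + (b1 ^ e1)
        y2 = (b0 ^ e0p) * 2 + ((bs ^ x2) ^ ep)
        w = (
            (1 / 16)
            * (p0 if e0 else 1 - p0)
            * (q if e1 else 1 - q)
            * (p0 if e0p else 1 - p0)
            * (s if ep else 1 - s)
        )
        pmf[x1, x2, y1, y2] += w
    return DiscreteDynSystem(pmf)


def duplication_gaussian_series(seed: int, n: int = 6000) -> np.ndarray:
    """Nine-column Gaussian series in three blocks: an AR(0.85) driver whose
    past is duplicated (with independent noise) into two follower columns."""
    rng = np.random.default_rng(seed)
    cols = []
    for b in (0.9, 0.65, 0.4):
        u = np.zeros(n + 1)
        eps = rng.standard_normal(n + 1)
        for t in range(1, n + 1):
            u[t] = 0.85 * u[t - 1] + eps[t]
        cols += [
            u[1:],
            b * u[:-1] + 0.6 * rng.standard_normal(n),
            b * u[:-1] + 0.6 * rng.standard_normal(n),
        ]
    return np.column_stack(cols)


@pytest.fixture(scope="session")
def lattice2():
    return build_product_lattice(2)


@pytest.fixture(scope="session")
def copy_system():
    return make_copy_system()


@pytest.fixture(scope="session")
def xor_system():
    return make_downward_xor()


@pytest.fixture(scope="session")
def ppr_system():
    return make_ppr()


@pytest.fixture(scope="session")
def global_bit_system():
    return make_global_bit()


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)
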