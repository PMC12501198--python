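"""Built-in example systems: logic gates, pure-atom constructions, AR process.

The three worked logic-gate systems (copy transfer, downward XOR,
parity-preserving random) all have whole-minus-sum integrated information of
exactly 1 bit, yet each concentrates its dynamics in a single, different
atom -- which is what makes them useful as oracles.

``make_pure_atom_system`` extends this idea to every one of the 16 atoms:
each label maps to a small binary construction whose MMI decomposition has
exactly one atom of ~1 bit, verified against the decomposition itself at
build time.
"""

from __future__ import annotations

from typing import Callable, Dict

import numpy as np

from .decompose import phiid_decompose
from .errors import InternalConsistencyError
from .systems import DiscreteDynSystem, GaussianDynSystem, stationary_lagged_cov

__all__ = [
    "make_copy_system",
    "make_downward_xor",
    "make_ppr",
    "make_global_bit",
    "make_duplication",
    "make_broadcast_xor",
    "make_pure_atom_system",
    "PURE_ATOM_LABELS",
    "make_ar_system",
    "sample_transition_pairs",
    "simulate_ar",
    "make_random_discrete",
    "make_random_gaussian",
]


def _pmf_from_rule(rule: Callable[[int, int, int, int], bool]) -> DiscreteDynSystem:
    """Uniform pmf over the binary states (x1, x2, y1, y2) satisfying ``rule``."""
    p = np.zeros((2, 2, 2, 2))
    for x1 in (0, 1):
        for x2 in (0, 1):
            for y1 in (0, 1):
                for y2 in (0, 1):
                    if rule(x1, x2, y1, y2):
                        p[x1, x2, y1, y2] = 1.0
    return DiscreteDynSystem(p / p.sum())


def make_copy_system() -> DiscreteDynSystem:
    """X1_t, X2_t, X1_{t+1} i.i.d. fair bits; X2_{t+1} = X1_t (pure transfer)."""
    return _pmf_from_rule(lambda x1, x2, y1, y2: y2 == x1)


def make_downward_xor() -> DiscreteDynSystem:
    """X1_{t+1} = X1_t XOR X2_t; X2_{t+1} a fresh fair bit (downward causation)."""
    return _pmf_from_rule(lambda x1, x2, y1, y2: y1 == x1 ^ x2)


def make_ppr() -> DiscreteDynSystem:
    """Parity-preserving random: X_{t+1} uniform over the two states with the
    same parity as X_t (persistent synergy)."""
    return _pmf_from_rule(lambda x1, x2, y1, y2: (x1 ^ x2) == (y1 ^ y2))


def make_global_bit() -> DiscreteDynSystem:
    """All four variables equal one shared fair bit (pure double-redundancy)."""
    return _pmf_from_rule(lambda x1, x2, y1, y2: x1 == x2 == y1 == y2)


def make_duplication() -> DiscreteDynSystem:
    """X1_{t+1} = X2_{t+1} = X1_t; X2_t an independent fair bit (information
    duplication: the atom shared by storage and transfer measures)."""
    return _pmf_from_rule(lambda x1, x2, y1, y2: y1 == x1 and y2 == x1)


def make_broadcast_xor() -> DiscreteDynSystem:
    """X1_{t+1} = X2_{t+1} = X1_t XOR X2_t (synergy broadcast redundantly)."""
    return _pmf_from_rule(lambda x1, x2, y1, y2: y1 == x1 ^ x2 and y2 == x1 ^ x2)


# Base constructions for pure-atom systems (part-1 variants; the part-2
# variants are obtained by swapping parts).
_PURE_ATOM_BASE: Dict[str, Callable[[], DiscreteDynSystem]] = {
    # shared bit everywhere
    "red->red": make_global_bit,
    # self-copy in part 1, independent noise in part 2
    "un1->un1": lambda: _pmf_from_rule(lambda x1, x2, y1, y2: y1 == x1),
    # cross copy
    "un1->un2": make_copy_system,
    # duplication of part 1's bit into both futures
    "un1->red": make_duplication,
    # shared past bit retained only by part 1
    "red->un1": lambda: _pmf_from_rule(lambda x1, x2, y1, y2: x1 == x2 and y1 == x1),
    # XOR broadcast to both futures
    "syn->red": make_broadcast_xor,
    # downward XOR
    "syn->un1": make_downward_xor,
    # parity-preserving random
    "syn->syn": make_ppr,
    # shared past bit, parity-encoded future
    "red->syn": lambda: _pmf_from_rule(
        lambda x1, x2, y1, y2: x1 == x2 and (y1 ^ y2) == x1
    ),
    # part-1 bit parity-encoded into the joint future
    "un1->syn": lambda: _pmf_from_rule(lambda x1, x2, y1, y2: (y1 ^ y2) == x1),
}

_MIRROR_TOKEN = {"red": "red", "syn": "syn", "un1": "un2", "un2": "un1"}


def _mirror_label(label: str) -> str:
    parts = label.split("->")
    if len(parts) != 2 or any(tok not in _MIRROR_TOKEN for tok in parts):
        raise ValueError(f"unsupported pure-atom label {label!r}")
    p, f = parts
    return f"{_MIRROR_TOKEN[p]}->{_MIRROR_TOKEN[f]}"


#: labels with a validated binary construction (all 16: the ten base
#: constructions plus their part-swapped mirrors)
PURE_ATOM_LABELS = tuple(
    sorted(set(_PURE_ATOM_BASE) | {_mirror_label(lab) for lab in _PURE_ATOM_BASE})
)


def make_pure_atom_system(atom_label: str) -> DiscreteDynSystem:
    """A binary system whose MMI decomposition has ``atom_label`` ~ 1 bit and
    every other atom below 1e-10, checked against the decomposition oracle."""
    label = atom_label.strip().lower().replace(" ", "")
    if label not in PURE_ATOM_LABELS:
        raise ValueError(
            f"unsupported pure-atom label {atom_label!r}; "
            f"supported: {', '.join(PURE_ATOM_LABELS)}"
        )
    if label in _PURE_ATOM_BASE:
        system = _PURE_ATOM_BASE[label]()
    else:
        system = _PURE_ATOM_BASE[_mirror_label(label)]().swap_parts()
    atoms = phiid_decompose(system, "mmi")
    nonzero = atoms.nonzero()
    if nonzero != [label] or abs(atoms[label] - 1.0) > 1e-9:
        raise InternalConsistencyError(
            f"construction for {label} failed its oracle check: "
            f"nonzero atoms {nonzero}"
        )
    return system


def make_ar_system(a: float, c: float) -> GaussianDynSystem:
    """Stationary two-node AR(1) system with all couplings ``a`` and unit-
    variance innovations with correlation ``c``.

    Stationarity of the all-``a`` coupling matrix requires |2a| < 1.
    """
    if abs(2 * a) >= 1:
        raise ValueError(f"|2a| must be < 1 for stationarity, got a={a}")
    if abs(c) >= 1:
        raise ValueError(f"noise correlation must satisfy |c| < 1, got {c}")
    A = np.full((2, 2), float(a))
    sigma = np.array([[1.0, float(c)], [float(c), 1.0]])
    return stationary_lagged_cov(A, sigma)


def sample_transition_pairs(
    system: DiscreteDynSystem, n: int, seed=None
) -> np.ndarray:
    """n i.i.d. draws from the joint (past, future) pmf, emitted as
    consecutive row pairs: a (2n) x 2 integer array where rows (2k, 2k+1)
    hold (x1_t, x2_t) and (x1_{t+1}, x2_{t+1}) of draw k.

    Draws are i.i.d. pairs, not a chain rollout: systems such as the
    parity-preserving random gate conserve a quantity along trajectories, so
    a single rollout would condition on one conserved class and no longer
    sample the stated one-step joint distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    flat = system.pmf.ravel()
    draws = rng.choice(flat.size, size=n, p=flat)
    states = np.column_stack(np.unravel_index(draws, system.pmf.shape))
    out = np.empty((2 * n, 2), dtype=np.int64)
    out[0::2] = states[:, :2]
    out[1::2] = states[:, 2:]
    return out


def simulate_ar(
    coupling: np.ndarray, noise_cov: np.ndarray, n_steps: int, seed=None
) -> np.ndarray:
    """Rollout of x_{t+1} = A x_t + eps, eps ~ N(0, noise_cov), started from
    the stationary distribution; returns an (n_steps) x 2 array."""
    joint = stationary_lagged_cov(coupling, noise_cov)  # validates inputs
    A = np.asarray(coupling, dtype=float)
    rng = np.random.default_rng(seed)
    chol_noise = np.linalg.cholesky(np.asarray(noise_cov, dtype=float))
    chol_stat = np.linalg.cholesky(joint.cov[:2, :2])
    x = chol_stat @ rng.standard_normal(2)
    eps = rng.standard_normal((n_steps, 2)) @ chol_noise.T
    out = np.empty((n_steps, 2))
    for t in range(n_steps):
        out[t] = x
        x = A @ x + eps[t]
    return out


def make_random_discrete(rng: np.random.Generator, sizes=(2, 2, 2, 2)) -> DiscreteDynSystem:
    """A random joint pmf (Dirichlet-uniform over the simplex); handy for
    property tests over ensembles of systems."""
    p = rng.dirichlet(np.ones(int(np.prod(sizes)))).reshape(sizes)
    return DiscreteDynSystem(p)


def make_random_gaussian(rng: np.random.Generator) -> GaussianDynSystem:
    """A random stationary Gaussian system: random stable coupling, random
    SPD innovations, joint covariance from the Lyapunov solution."""
    A = rng.uniform(-1, 1, size=(2, 2))
    A *= 0.95 / max(1.0, float(np.max(np.abs(np.linalg.eigvals(A)))))
    M = rng.standard_normal((2, 2))
    sigma = M @ M.T + 0.2 * np.eye(2)
    return stationary_lagged_cov(A, sigma)
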