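"""Two-part dynamical systems and their information-theoretic primitives.

A system is the joint distribution of the stacked vector
``(X1_t, X2_t, X1_{t+1}, X2_{t+1})`` -- either a finite joint pmf
(:class:`DiscreteDynSystem`) or the covariance of a stationary Gaussian
process (:class:`GaussianDynSystem`).  Variables are addressed by *slot*:

====  ==================
slot  variable
====  ==================
0     part 1, time t
1     part 2, time t
2     part 1, time t+1
3     part 2, time t+1
====  ==================

All information quantities are in bits (log base 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple, Union

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .errors import NonstationarySystemError, NumericalDegeneracyError

__all__ = [
    "DiscreteDynSystem",
    "GaussianDynSystem",
    "PART1_PAST",
    "PART2_PAST",
    "PART1_FUTURE",
    "PART2_FUTURE",
    "PAST",
    "FUTURE",
    "slots_for",
    "mutual_information",
    "conditional_mutual_information",
    "stationary_lagged_cov",
    "estimate_gaussian",
    "estimate_discrete",
]

# variable-group selectors (tuples of slot indices)
PART1_PAST: Tuple[int, ...] = (0,)
PART2_PAST: Tuple[int, ...] = (1,)
PART1_FUTURE: Tuple[int, ...] = (2,)
PART2_FUTURE: Tuple[int, ...] = (3,)
PAST: Tuple[int, ...] = (0, 1)
FUTURE: Tuple[int, ...] = (2, 3)

_GAUSS_JITTER = 1e-10


def slots_for(parts: Sequence[int], time: str) -> Tuple[int, ...]:
    """Slots of the given parts (1-based) at ``time`` 'past' or 'future'."""
    offset = {"past": -1, "future": 1}[time]
    return tuple(sorted(p - 1 + (2 if offset == 1 else 0) for p in parts))


@dataclass(frozen=True)
class DiscreteDynSystem:
    """Joint pmf over (X1_t, X2_t, X1_{t+1}, X2_{t+1}) on finite alphabets.

    ``pmf`` is a 4-d array indexed by slot; nonnegative and normalized.
    """

    pmf: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pmf, dtype=float)
        if p.ndim != 4:
            raise ValueError("pmf must be a 4-dimensional table (one axis per slot)")
        if np.any(p < -1e-15):
            raise ValueError("pmf entries must be nonnegative")
        total = p.sum()
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"pmf must sum to 1 (got {total})")
        object.__setattr__(self, "pmf", np.clip(p, 0.0, None))

    @property
    def alphabet_sizes(self) -> Tuple[int, ...]:
        return self.pmf.shape

    def marginal(self, slots: Sequence[int]) -> np.ndarray:
        """Marginal pmf over ``slots`` (axes kept in slot order)."""
        slots = tuple(sorted(set(slots)))
        drop = tuple(ax for ax in range(4) if ax not in slots)
        return self.pmf.sum(axis=drop) if drop else self.pmf

    def entropy(self, slots: Sequence[int]) -> float:
        m = self.marginal(slots).ravel()
        m = m[m > 0]
        return float(-(m * np.log2(m)).sum())

    def swap_parts(self) -> "DiscreteDynSystem":
        """The system with part labels 1 and 2 exchanged."""
        return DiscreteDynSystem(np.transpose(self.pmf, (1, 0, 3, 2)))


@dataclass(frozen=True)
class GaussianDynSystem:
    """Covariance of the stacked vector (X1_t, X2_t, X1_{t+1}, X2_{t+1})
    of a zero-mean stationary Gaussian process."""

    cov: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (4, 4):
            raise ValueError("cov must be a 4x4 matrix")
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("cov must be symmetric")
        if np.any(np.diag(c) <= 0):
            raise ValueError("cov must have strictly positive diagonal")
        eig_min = float(np.linalg.eigvalsh((c + c.T) / 2).min())
        if eig_min < -1e-8:
            raise ValueError(f"cov must be positive semidefinite (min eig {eig_min})")
        object.__setattr__(self, "cov", (c + c.T) / 2)

    def submatrix(self, slots: Sequence[int]) -> np.ndarray:
        idx = np.asarray(sorted(set(slots)))
        return self.cov[np.ix_(idx, idx)]

    def entropy(self, slots: Sequence[int]) -> float:
        """Differential entropy in bits, up to the additive Gaussian constant
        (constants cancel in every MI computed here)."""
        return 0.5 * _logdet2(self.submatrix(slots))

    def swap_parts(self) -> "GaussianDynSystem":
        perm = [1, 0, 3, 2]
        return GaussianDynSystem(self.cov[np.ix_(perm, perm)])


DynSystem = Union[DiscreteDynSystem, GaussianDynSystem]


def _logdet2(m: np.ndarray) -> float:
    """log2-determinant; near-singular matrices get a small diagonal jitter
    before failing hard."""
    m = np.atleast_2d(np.asarray(m, dtype=float))
    sign, logdet = np.linalg.slogdet(m)
    if sign <= 0:
        sign, logdet = np.linalg.slogdet(m + _GAUSS_JITTER * np.eye(m.shape[0]))
        if sign <= 0:
            raise NumericalDegeneracyError(
                "covariance submatrix is singular (after jitter)"
            )
    return float(logdet / np.log(2.0))


def _check_disjoint(*groups: Sequence[int]) -> None:
    flat = [s for g in groups for s in g]
    if len(flat) != len(set(flat)):
        raise ValueError("variable groups must be pairwise disjoint")
    if not all(0 <= s <= 3 for s in flat):
        raise ValueError("slot indices must be in 0..3")
    if any(len(g) == 0 for g in groups):
        raise ValueError("variable groups must be nonempty")


def mutual_information(
    system: DynSystem, a: Sequence[int], b: Sequence[int]
) -> float:
    """I(X_a ; X_b) in bits between two disjoint groups of slots.

    Discrete systems use the plug-in Shannon formula on marginal tables;
    Gaussian systems use 1/2 * log2(det S_a det S_b / det S_ab).  Tiny
    negative round-off is clipped to zero.
    """
    _check_disjoint(a, b)
    mi = system.entropy(a) + system.entropy(b) - system.entropy(tuple(a) + tuple(b))
    return max(0.0, float(mi))


def conditional_mutual_information(
    system: DynSystem, a: Sequence[int], b: Sequence[int], c: Sequence[int]
) -> float:
    """I(X_a ; X_b | X_c) = I(a; b u c) - I(a; c), in bits."""
    _check_disjoint(a, b, c)
    return mutual_information(system, a, tuple(b) + tuple(c)) - mutual_information(
        system, a, c
    )


def stationary_lagged_cov(
    coupling: np.ndarray, noise_cov: np.ndarray
) -> GaussianDynSystem:
    """Stationary joint covariance of the AR(1) process x_{t+1} = A x_t + eps.

    Solves the discrete Lyapunov equation S = A S A^T + Sigma and returns the
    4x4 covariance [[S, S A^T], [A S, S]] of (x_t, x_{t+1}).
    """
    A = np.asarray(coupling, dtype=float)
    S_noise = np.asarray(noise_cov, dtype=float)
    if A.shape != (2, 2) or S_noise.shape != (2, 2):
        raise ValueError("coupling and noise_cov must be 2x2")
    if not np.allclose(S_noise, S_noise.T, atol=1e-12):
        raise ValueError("noise_cov must be symmetric")
    if np.any(np.linalg.eigvalsh(S_noise) <= 0):
        raise ValueError("noise_cov must be positive definite")
    rho = float(np.max(np.abs(np.linalg.eigvals(A))))
    if rho >= 1.0:
        raise NonstationarySystemError(
            f"coupling spectral radius {rho:.6g} >= 1: no stationary distribution"
        )
    S = solve_discrete_lyapunov(A, S_noise)
    S = (S + S.T) / 2
    joint = np.block([[S, S @ A.T], [A @ S, S]])
    return GaussianDynSystem(joint)


def _stacked_pairs(
    series: np.ndarray, lag: int, step: int, min_pairs: int = 10
) -> np.ndarray:
    series = np.asarray(series)
    if series.ndim != 2 or series.shape[1] != 2:
        raise ValueError("series must be a T x 2 matrix")
    if not isinstance(lag, int) or lag < 1:
        raise ValueError("lag must be a positive integer")
    T = series.shape[0]
    if T - lag < min_pairs:
        raise ValueError(f"need T - lag >= {min_pairs} observations, got {T - lag}")
    t_idx = np.arange(0, T - lag, step)
    return np.column_stack([series[t_idx], series[t_idx + lag]])


def estimate_gaussian(
    series: np.ndarray, lag: int = 1, *, step: int = 1
) -> GaussianDynSystem:
    """Gaussian model of a T x 2 series: sample covariance (denominator n-1)
    of the stacked pairs (x_t, x_{t+lag})."""
    stacked = _stacked_pairs(np.asarray(series, dtype=float), lag, step)
    if np.any(stacked.std(axis=0) == 0):
        raise NumericalDegeneracyError("constant column in series")
    return GaussianDynSystem(np.cov(stacked, rowvar=False, ddof=1))


def estimate_discrete(
    series: np.ndarray, lag: int = 1, *, step: int = 1
) -> DiscreteDynSystem:
    """Plug-in empirical pmf of (x_t, x_{t+lag}) pairs of an integer T x 2
    series; alphabet sizes inferred from the observed values.

    ``step`` strides the pair start times: use step=2 for series emitted as
    consecutive (past, future) row pairs, where sliding pairs would mix in
    spurious future->next-past transitions.
    """
    series = np.asarray(series)
    if not np.issubdtype(series.dtype, np.integer):
        if not np.all(series == np.round(series)):
            raise ValueError("discrete estimation requires integer-valued series")
        series = series.astype(np.int64)
    if np.any(series < 0):
        raise ValueError("discrete series entries must be nonnegative integers")
    # a single observed pair is already a (degenerate) pmf, so min_pairs=1
    stacked = _stacked_pairs(series, lag, step, min_pairs=1)
    k = [int(series[:, 0].max()) + 1, int(series[:, 1].max()) + 1]
    shape = (k[0], k[1], k[0], k[1])
    counts = np.zeros(shape, dtype=float)
    np.add.at(counts, tuple(stacked.T), 1.0)
    return DiscreteDynSystem(counts / counts.sum())
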