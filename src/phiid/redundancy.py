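"""Double-redundancy backends: MMI (discrete + Gaussian) and CCS (discrete).

A redundancy backend assigns a value in bits to every node of the product
lattice.  Both backends honour the compatibility axiom: on nodes whose past
and future antichains are singletons the value is the plain mutual
information between the corresponding variable groups, so the top node
always equals the time-delayed mutual information.

* **MMI** (minimum mutual information): the redundancy at node alpha->beta is
  the minimum of I(X^a_t ; X^b_{t+1}) over all member pairs (a in alpha,
  b in beta), where X^a is the joint of the parts in a.  This is the unique
  reading consistent with the compatibility axiom and with the closed-form
  revised-Phi expression min_{i,j} I(X^i_t ; X^j_{t+1}).

* **CCS** (common change in surprisal): a pointwise measure for discrete
  systems.  A local co-information term is credited as redundancy only when
  all its constituent local information changes and the co-information
  itself share one sign.  The double node uses the inclusion-exclusion
  "double co-information" over both decompositions, which collapses to the
  single-target rule whenever the two past (or two future) groups coincide.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np

from .errors import UnsupportedBackendError
from .lattice import ProductLattice, ProductNode
from .systems import (
    DiscreteDynSystem,
    DynSystem,
    GaussianDynSystem,
    mutual_information,
    slots_for,
)

__all__ = [
    "mmi_redundancy",
    "ccs_redundancy",
    "assemble_redundancies",
    "get_backend",
    "BACKENDS",
]


def _member_slots(node: ProductNode) -> Tuple[list, list]:
    past = [slots_for(m, "past") for m in node.past.members]
    future = [slots_for(m, "future") for m in node.future.members]
    return past, future


def mmi_redundancy(system: DynSystem, node: ProductNode) -> float:
    """Minimum over member pairs (a, b) of I(X^a_t ; X^b_{t+1}), in bits."""
    past, future = _member_slots(node)
    return min(mutual_information(system, a, b) for a in past for b in future)


# ---------------------------------------------------------------------------
# CCS: pointwise (local) computations on the discrete joint pmf
# ---------------------------------------------------------------------------


def _local_mi(system: DiscreteDynSystem, a: Sequence[int], b: Sequence[int]) -> np.ndarray:
    """Table of local mutual informations i(x_a ; x_b), shaped like the pmf.

    States of zero probability get a local value of 0 (they carry no mass).
    """
    p = system.pmf
    slots_ab = tuple(sorted(set(a) | set(b)))

    def expand(slots: Sequence[int]) -> np.ndarray:
        m = system.marginal(slots)
        shape = [system.pmf.shape[ax] if ax in slots else 1 for ax in range(4)]
        return m.reshape(shape)

    pa, pb, pab = expand(tuple(a)), expand(tuple(b)), expand(slots_ab)
    with np.errstate(divide="ignore", invalid="ignore"):
        i = np.log2(pab) - np.log2(pa) - np.log2(pb)
    i = np.broadcast_to(i, p.shape).copy()
    i[p == 0] = 0.0
    return i


def _signs_agree(terms: Sequence[np.ndarray], tol: float = 1e-12) -> np.ndarray:
    """Mask of states where every local term has the same strict sign."""
    signs = [np.where(np.abs(t) < tol, 0.0, np.sign(t)) for t in terms]
    first = signs[0]
    agree = first != 0
    for s in signs[1:]:
        agree &= s == first
    return agree


def _ccs_single_target(
    system: DiscreteDynSystem, s1: Sequence[int], s2: Sequence[int], t: Sequence[int]
) -> float:
    """CCS redundancy of two source groups about one target group."""
    i1 = _local_mi(system, s1, t)
    i2 = _local_mi(system, s2, t)
    i12 = _local_mi(system, tuple(s1) + tuple(s2), t)
    c = i1 + i2 - i12  # local co-information
    mask = _signs_agree([i1, i2, i12, c])
    return float((system.pmf * np.where(mask, c, 0.0)).sum())


def _ccs_double(system: DiscreteDynSystem) -> float:
    """CCS double-redundancy at the bottom node ({1}{2} -> {1}{2}).

    The local "double co-information" is the inclusion-exclusion combination
    of the pairwise, one-joint and both-joint local informations; it reduces
    to the single-target local co-information when the two future (or two
    past) groups are duplicated, as subset-equality requires.
    """
    x1, x2 = slots_for([1], "past"), slots_for([2], "past")
    y1, y2 = slots_for([1], "future"), slots_for([2], "future")
    X, Y = x1 + x2, y1 + y2
    i11 = _local_mi(system, x1, y1)
    i12 = _local_mi(system, x1, y2)
    i21 = _local_mi(system, x2, y1)
    i22 = _local_mi(system, x2, y2)
    ix_Y = _local_mi(system, x1, Y)
    iy_Y = _local_mi(system, x2, Y)
    iX_a = _local_mi(system, X, y1)
    iX_b = _local_mi(system, X, y2)
    iX_Y = _local_mi(system, X, Y)
    c = (i11 + i12 + i21 + i22) - (ix_Y + iy_Y + iX_a + iX_b) + iX_Y
    mask = _signs_agree([i11, i12, i21, i22, iX_Y, c])
    return float((system.pmf * np.where(mask, c, 0.0)).sum())


def ccs_redundancy(system: DynSystem, node: ProductNode) -> float:
    """CCS value at a product-lattice node of a discrete 2-part system."""
    if isinstance(system, GaussianDynSystem):
        raise UnsupportedBackendError(
            "CCS redundancy is defined for discrete systems only; "
            "use the MMI backend for Gaussian systems"
        )
    past, future = _member_slots(node)
    if len(past) == 1 and len(future) == 1:
        # compatibility axiom: plain mutual information
        return mutual_information(system, past[0], future[0])
    if len(future) == 1:
        return _ccs_single_target(system, past[0], past[1], future[0])
    if len(past) == 1:
        # backward decomposition: future groups as sources about the past
        return _ccs_single_target(system, future[0], future[1], past[0])
    return _ccs_double(system)


BACKENDS = {
    "mmi": {
        "fn": mmi_redundancy,
        "supports": (DiscreteDynSystem, GaussianDynSystem),
    },
    "ccs": {
        "fn": ccs_redundancy,
        "supports": (DiscreteDynSystem,),
    },
}


def get_backend(name: str):
    """Resolve a backend token ('mmi' or 'ccs') to its redundancy function."""
    try:
        return BACKENDS[name.lower()]["fn"]
    except KeyError:
        raise ValueError(
            f"unknown redundancy backend {name!r}; choose from {sorted(BACKENDS)}"
        ) from None


def assemble_redundancies(
    system: DynSystem, backend: str, lattice: ProductLattice
) -> Dict[ProductNode, float]:
    """Evaluate the chosen backend on every node of the product lattice."""
    if lattice.n_parts != 2:
        raise ValueError("numeric redundancies are defined for 2-part systems only")
    if isinstance(system, GaussianDynSystem) and backend.lower() == "ccs":
        raise UnsupportedBackendError(
            "CCS redundancy is defined for discrete systems only"
        )
    fn = get_backend(backend)
    return {node: fn(system, node) for node in lattice.nodes}
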