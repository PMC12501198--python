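"""Redundancy lattice, product (double-redundancy) lattice, and Moebius inversion.

The nodes of a partial-information decomposition are *antichains*: collections
of nonempty subsets of the part indices {1..N} in which no member contains
another.  For a bipartite process (N=2) there are four antichains --
{1}{2} (redundancy), {1} and {2} (unique), and {12} (synergy) -- and the
integrated-information decomposition lives on the Cartesian product of two
such lattices, one for the past and one for the future, giving 16 nodes.

Atoms are obtained from redundancies by Moebius inversion over the product
partial order: the atom at a node is the redundancy at that node minus the
atoms of every node strictly below it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Tuple

__all__ = [
    "Antichain",
    "ProductNode",
    "ProductLattice",
    "enumerate_antichains",
    "is_below",
    "product_is_below",
    "build_product_lattice",
    "moebius_atoms",
    "PID_TOKENS",
]

# canonical single-lattice tokens for N=2, in label-grammar order
PID_TOKENS = ("red", "un1", "un2", "syn")


@dataclass(frozen=True)
class Antichain:
    """An antichain of nonempty part-index subsets, in canonical form.

    Members are stored as a tuple of tuples, each member sorted, and members
    ordered by (size, lexicographic) -- so equal antichains compare equal.
    """

    members: Tuple[Tuple[int, ...], ...]

    def __init__(self, members: Iterable[Iterable[int]]):
        canon = tuple(
            sorted((tuple(sorted(set(m))) for m in members), key=lambda m: (len(m), m))
        )
        if not canon:
            raise ValueError("an antichain must have at least one member")
        for m in canon:
            if not m:
                raise ValueError("antichain members must be nonempty")
            if any(i < 1 for i in m):
                raise ValueError("part indices are 1-based positive integers")
        for a, b in combinations(canon, 2):
            if set(a) <= set(b) or set(b) <= set(a):
                raise ValueError(f"members {a} and {b} violate the antichain property")
        object.__setattr__(self, "members", canon)

    @property
    def token(self) -> str:
        """Canonical ASCII token: red/un1/un2/syn for N=2, set notation otherwise."""
        two_part = {
            ((1,), (2,)): "red",
            ((1,),): "un1",
            ((2,),): "un2",
            ((1, 2),): "syn",
        }
        if self.members in two_part:
            return two_part[self.members]
        return "".join("{" + "".join(map(str, m)) + "}" for m in self.members)

    def swap_parts(self) -> "Antichain":
        """Relabel parts 1<->2 (only meaningful for a 2-part universe)."""
        swap = {1: 2, 2: 1}
        return Antichain(tuple(tuple(swap.get(i, i) for i in m) for m in self.members))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Antichain({self.token})"


@dataclass(frozen=True)
class ProductNode:
    """An ordered pair of antichains: past sources -> future targets."""

    past: Antichain
    future: Antichain

    @property
    def label(self) -> str:
        return f"{self.past.token}->{self.future.token}"

    def swap_parts(self) -> "ProductNode":
        return ProductNode(self.past.swap_parts(), self.future.swap_parts())

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ProductNode({self.label})"


def enumerate_antichains(n_parts: int) -> List[Antichain]:
    """All antichains of nonempty subsets of {1..n_parts}, canonically ordered.

    Ordered by (number of members, member keys): for ``n_parts=2`` this yields
    {1}, {2}, {12}, {1}{2}.  The count for n_parts=1,2,3 is 1, 4, 18 (the
    Dedekind numbers minus the empty antichain).
    """
    if not isinstance(n_parts, int) or n_parts < 1:
        raise ValueError(f"n_parts must be a positive integer, got {n_parts!r}")
    parts = range(1, n_parts + 1)
    subsets = [
        tuple(c) for r in range(1, n_parts + 1) for c in combinations(parts, r)
    ]
    out: List[Antichain] = []
    # brute-force filter of all collections of nonempty subsets
    for r in range(1, len(subsets) + 1):
        for combo in combinations(subsets, r):
            if all(
                not (set(a) <= set(b) or set(b) <= set(a))
                for a, b in combinations(combo, 2)
            ):
                out.append(Antichain(combo))
    out.sort(key=lambda ac: (len(ac.members), [(len(m), m) for m in ac.members]))
    return out


def is_below(a: Antichain, b: Antichain) -> bool:
    """Partial order of the redundancy lattice: a <= b iff every member of b
    contains some member of a (containment taken non-strictly, so the order
    is reflexive)."""
    return all(any(set(m) <= set(n) for m in a.members) for n in b.members)


def product_is_below(p: ProductNode, q: ProductNode) -> bool:
    """Componentwise order on the product lattice."""
    return is_below(p.past, q.past) and is_below(p.future, q.future)


@dataclass
class ProductLattice:
    """The product of two redundancy lattices over the same part universe.

    ``nodes`` are ordered bottom-up (by strict-down-set size, ties broken by
    canonical label), which is also a valid topological order for Moebius
    inversion.  ``strict_downsets[n]`` holds every node strictly below n.
    """

    n_parts: int
    nodes: List[ProductNode]
    strict_downsets: Dict[ProductNode, frozenset] = field(repr=False)

    @property
    def bottom(self) -> ProductNode:
        return self.nodes[0]

    @property
    def top(self) -> ProductNode:
        return self.nodes[-1]

    def labels(self) -> List[str]:
        return [n.label for n in self.nodes]


def build_product_lattice(n_parts: int) -> ProductLattice:
    """Construct the product lattice (16 nodes for a bipartite system)."""
    chains = enumerate_antichains(n_parts)
    nodes = [ProductNode(p, f) for p in chains for f in chains]
    downsets: Dict[ProductNode, frozenset] = {}
    for n in nodes:
        downsets[n] = frozenset(
            m for m in nodes if m != n and product_is_below(m, n)
        )
    nodes.sort(key=lambda n: (len(downsets[n]), n.label))
    return ProductLattice(n_parts=n_parts, nodes=nodes, strict_downsets=downsets)


def moebius_atoms(
    lattice: ProductLattice, redundancies: Mapping[ProductNode, float]
) -> Dict[ProductNode, float]:
    """Invert redundancies into atoms over the lattice.

    Bottom-up recursion: atom(n) = redundancy(n) - sum of atoms strictly
    below n.  Summing atoms over any node's non-strict down-set recovers the
    input redundancy exactly (up to float round-off).
    """
    missing = [n for n in lattice.nodes if n not in redundancies]
    if missing:
        raise ValueError(f"redundancy value missing for node(s) {missing}")
    atoms: Dict[ProductNode, float] = {}
    for n in lattice.nodes:  # node order is topological
        atoms[n] = float(redundancies[n]) - sum(
            atoms[m] for m in lattice.strict_downsets[n]
        )
    return atoms
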