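"""The 16-atom decomposition of a bipartite process and derived measures.

``phiid_decompose`` evaluates a redundancy backend on the 16 product-lattice
nodes and Moebius-inverts them into atoms.  The classical information-
dynamics measures are then either direct mutual-information expressions
(numerically robust, the default here) or aggregates of atoms; the two
routes agree to float precision for any backend that satisfies the
compatibility axiom, and the tests assert exactly that.

Atom aggregates (labels ``<past>-><future>`` with tokens red/un1/un2/syn):

* AIS(1)      = red->red + red->un1 + un1->red + un1->un1
* TE(1->2)    = un1->red + un1->un2 + syn->red + syn->un2
* Phi_WMS     = -red->red + un1->un2 + un2->un1 + every syn-involving atom
* Phi_R       = Phi_WMS + double-redundancy (bottom-node redundancy)
* uCD         = TE(1->2) + TE(2->1); corrected CD subtracts the
                double-counted syn->red atom.

The six-mode taxonomy partitions the 16 atoms into storage (4), copy (2),
transfer (2), erasure (2), downward causation (3) and upward causation (3).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, Iterable, List, Mapping

from .lattice import ProductLattice, build_product_lattice, moebius_atoms
from .redundancy import assemble_redundancies
from .systems import (
    DynSystem,
    PART1_FUTURE,
    PART1_PAST,
    PART2_FUTURE,
    PART2_PAST,
    PAST,
    FUTURE,
    conditional_mutual_information,
    mutual_information,
)

__all__ = [
    "ATOM_LABELS",
    "AIS_ATOMS",
    "TE_ATOMS",
    "PHI_WMS_COEFFS",
    "TAXONOMY_MODES",
    "AtomTable",
    "MeasureReport",
    "phiid_decompose",
    "ais_from_atoms",
    "te_from_atoms",
    "tdmi",
    "phi_wms",
    "phi_r",
    "double_redundancy",
    "causal_density",
    "taxonomy_modes",
    "measure_report",
]

_TOKENS = ("red", "un1", "un2", "syn")
#: canonical label order: past token outer, future token inner
ATOM_LABELS = tuple(f"{p}->{f}" for p in _TOKENS for f in _TOKENS)

_MIRROR = {"red": "red", "syn": "syn", "un1": "un2", "un2": "un1"}

AIS_ATOMS = {
    1: ("red->red", "red->un1", "un1->red", "un1->un1"),
    2: ("red->red", "red->un2", "un2->red", "un2->un2"),
}

TE_ATOMS = {
    (1, 2): ("un1->red", "un1->un2", "syn->red", "syn->un2"),
    (2, 1): ("un2->red", "un2->un1", "syn->red", "syn->un1"),
}

#: coefficients of Phi_WMS as an atom aggregate
PHI_WMS_COEFFS = {
    label: (
        -1.0
        if label == "red->red"
        else 1.0
        if ("syn" in label or label in ("un1->un2", "un2->un1"))
        else 0.0
    )
    for label in ATOM_LABELS
}

TAXONOMY_MODES = {
    "storage": ("red->red", "un1->un1", "un2->un2", "syn->syn"),
    "copy": ("un1->red", "un2->red"),
    "transfer": ("un1->un2", "un2->un1"),
    "erasure": ("red->un1", "red->un2"),
    "downward": ("syn->un1", "syn->un2", "syn->red"),
    "upward": ("un1->syn", "un2->syn", "red->syn"),
}

_NONZERO_TOL = 1e-10


def _mirror_label(label: str) -> str:
    p, f = label.split("->")
    return f"{_MIRROR[p]}->{_MIRROR[f]}"


@dataclass(frozen=True)
class AtomTable:
    """Map from the 16 canonical node labels to atom values in bits."""

    values: Dict[str, float]

    def __post_init__(self):
        missing = [lab for lab in ATOM_LABELS if lab not in self.values]
        if missing:
            raise ValueError(f"atom table missing labels {missing}")
        ordered = {lab: float(self.values[lab]) for lab in ATOM_LABELS}
        object.__setattr__(self, "values", ordered)

    def __getitem__(self, label: str) -> float:
        return self.values[label]

    def aggregate(self, labels: Iterable[str]) -> float:
        return sum(self.values[lab] for lab in labels)

    def total(self) -> float:
        """Sum of all atoms; equals the TDMI for a compliant backend."""
        return sum(self.values.values())

    def nonzero(self, tol: float = _NONZERO_TOL) -> List[str]:
        """Labels of atoms with magnitude above ``tol``."""
        return [lab for lab, v in self.values.items() if abs(v) > tol]

    def swap_parts(self) -> "AtomTable":
        """Atom table of the part-relabelled (1<->2) system."""
        return AtomTable({_mirror_label(lab): v for lab, v in self.values.items()})


def phiid_decompose(
    system: DynSystem,
    backend: str = "mmi",
    lattice: ProductLattice | None = None,
) -> AtomTable:
    """Full 16-atom decomposition of a 2-part system."""
    if lattice is None:
        lattice = build_product_lattice(2)
    reds = assemble_redundancies(system, backend, lattice)
    atoms = moebius_atoms(lattice, reds)
    return AtomTable({node.label: v for node, v in atoms.items()})


def ais_from_atoms(atoms: AtomTable, part: int) -> float:
    """Active information storage of a part as an atom aggregate."""
    return atoms.aggregate(AIS_ATOMS[part])


def te_from_atoms(atoms: AtomTable, source: int, target: int) -> float:
    """Transfer entropy source->target as an atom aggregate."""
    if source == target:
        raise ValueError("source and target must differ")
    return atoms.aggregate(TE_ATOMS[(source, target)])


def tdmi(system: DynSystem) -> float:
    """Time-delayed mutual information I(X_t ; X_{t+1}), in bits."""
    return mutual_information(system, PAST, FUTURE)


def _ais_direct(system: DynSystem, part: int) -> float:
    past = PART1_PAST if part == 1 else PART2_PAST
    future = PART1_FUTURE if part == 1 else PART2_FUTURE
    return mutual_information(system, past, future)


def _te_direct(system: DynSystem, source: int, target: int) -> float:
    src = PART1_PAST if source == 1 else PART2_PAST
    tgt_future = PART1_FUTURE if target == 1 else PART2_FUTURE
    tgt_past = PART1_PAST if target == 1 else PART2_PAST
    return conditional_mutual_information(system, src, tgt_future, tgt_past)


def phi_wms(system: DynSystem) -> float:
    """Whole-minus-sum integrated information: TDMI minus the two self-MIs."""
    return tdmi(system) - _ais_direct(system, 1) - _ais_direct(system, 2)


def double_redundancy(system: DynSystem, backend: str = "mmi") -> float:
    """Bottom-node redundancy ({1}{2} -> {1}{2}) under the chosen backend."""
    lattice = build_product_lattice(2)
    fn_table = assemble_redundancies(system, backend, lattice)
    return fn_table[lattice.bottom]


def phi_r(system: DynSystem, backend: str = "mmi") -> float:
    """Revised integrated information: Phi_WMS plus the double-redundancy.

    Under MMI this equals the closed form
    TDMI - sum_i I(X^i_t; X^i_{t+1}) + min_{i,j} I(X^i_t; X^j_{t+1}).
    """
    return phi_wms(system) + double_redundancy(system, backend)


def causal_density(system: DynSystem, backend: str = "mmi"):
    """(uCD, corrected CD): sum of both TEs, and the same with the
    double-counted syn->red atom removed."""
    ucd = _te_direct(system, 1, 2) + _te_direct(system, 2, 1)
    atoms = phiid_decompose(system, backend)
    return ucd, ucd - atoms["syn->red"]


def taxonomy_modes(atoms: AtomTable) -> Dict[str, float]:
    """Six-mode aggregates (storage/copy/transfer/erasure/downward/upward)."""
    return {mode: atoms.aggregate(labels) for mode, labels in TAXONOMY_MODES.items()}


@dataclass
class MeasureReport:
    """All derived measures of one system plus its atom table, in bits."""

    tdmi: float
    ais_1: float
    ais_2: float
    te_1to2: float
    te_2to1: float
    phi_wms: float
    phi_r: float
    ucd: float
    cd_corrected: float
    storage: float
    copy: float
    transfer: float
    erasure: float
    downward: float
    upward: float
    atoms: Dict[str, float] = field(default_factory=dict)
    backend: str = "mmi"

    def to_dict(self) -> Dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping) -> "MeasureReport":
        return cls(**d)


def measure_report(system: DynSystem, backend: str = "mmi") -> MeasureReport:
    """Compute every measure of a system: direct MI expressions for the
    classical quantities, atoms for the decomposition-specific ones."""
    atoms = phiid_decompose(system, backend)
    ucd, cd_corr = causal_density(system, backend)
    modes = taxonomy_modes(atoms)
    return MeasureReport(
        tdmi=tdmi(system),
        ais_1=_ais_direct(system, 1),
        ais_2=_ais_direct(system, 2),
        te_1to2=_te_direct(system, 1, 2),
        te_2to1=_te_direct(system, 2, 1),
        phi_wms=phi_wms(system),
        phi_r=phi_r(system, backend),
        ucd=ucd,
        cd_corrected=cd_corr,
        atoms=dict(atoms.values),
        backend=backend,
        **modes,
    )
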