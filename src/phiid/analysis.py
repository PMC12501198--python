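"""Batch pairwise decomposition and the storage-transfer correlation analysis.

For a multivariate series, every unordered pair of variables is modelled as
a two-part system and decomposed; each ordered pair then contributes one
observation of (AIS of the source, TE source->target, un1->red atom).
Correlating AIS with TE across ordered pairs, and then partialling out the
duplication atom un1->red that both measures contain, quantifies how much of
the apparent storage-transfer association is mere information duplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .decompose import AtomTable, ais_from_atoms, phiid_decompose, te_from_atoms
from .errors import (
    DegenerateConditioningError,
    InsufficientDataError,
    NumericalDegeneracyError,
)
from .systems import estimate_discrete, estimate_gaussian

__all__ = [
    "PairwiseResult",
    "AisTeSummary",
    "pairwise_decompose",
    "partial_correlation",
    "ais_te_analysis",
]


@dataclass
class PairwiseResult:
    """Decompositions of every valid variable pair of a multivariate series.

    ``table`` has one row per ordered pair with columns
    (source, target, ais_source, te, un_to_red) -- the un_to_red column is
    the duplication atom with the source playing part 1.
    """

    table: pd.DataFrame
    atom_tables: Dict[Tuple[int, int], AtomTable] = field(default_factory=dict)
    skipped: List[Tuple[int, int]] = field(default_factory=list)
    backend: str = "mmi"
    model: str = "gaussian"


def _infer_model(series: np.ndarray) -> str:
    if np.issubdtype(series.dtype, np.integer):
        return "discrete"
    return "discrete" if np.all(series == np.round(series)) else "gaussian"


def pairwise_decompose(
    series: np.ndarray,
    lag: int = 1,
    backend: str = "mmi",
    model: Optional[str] = None,
) -> PairwiseResult:
    """Estimate and decompose a two-part system for every unordered pair of
    columns; degenerate pairs are skipped with a warning, not a crash."""
    series = np.asarray(series)
    if series.ndim != 2 or series.shape[1] < 2:
        raise ValueError("series must be a T x V matrix with V >= 2")
    if model is None:
        model = _infer_model(series)
    estimate = estimate_discrete if model == "discrete" else estimate_gaussian
    V = series.shape[1]
    rows = []
    atom_tables: Dict[Tuple[int, int], AtomTable] = {}
    skipped: List[Tuple[int, int]] = []
    for i in range(V):
        for j in range(i + 1, V):
            try:
                system = estimate(series[:, [i, j]], lag)
                atoms = phiid_decompose(system, backend)
            except (NumericalDegeneracyError, ValueError) as exc:
                warnings.warn(f"skipping pair ({i}, {j}): {exc}", stacklevel=2)
                skipped.append((i, j))
                continue
            atom_tables[(i, j)] = atoms
            mirrored = atoms.swap_parts()
            for src, tgt, tab in ((i, j, atoms), (j, i, mirrored)):
                # in ``tab`` the source is always part 1
                rows.append(
                    {
                        "source": src,
                        "target": tgt,
                        "ais_source": ais_from_atoms(tab, 1),
                        "te": te_from_atoms(tab, 1, 2),
                        "un_to_red": tab["un1->red"],
                    }
                )
    table = pd.DataFrame(rows, columns=["source", "target", "ais_source", "te", "un_to_red"])
    return PairwiseResult(
        table=table, atom_tables=atom_tables, skipped=skipped, backend=backend, model=model
    )


def partial_correlation(x, y, z) -> float:
    """First-order partial Pearson correlation r_{xy.z}.

    r_{xy.z} = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    """
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    if not (len(x) == len(y) == len(z)):
        raise ValueError("x, y, z must have equal lengths")
    if len(x) < 4:
        raise InsufficientDataError("need at least 4 observations")
    if min(x.std(), y.std(), z.std()) == 0:
        raise ValueError("x, y, z must have nonzero variance")
    r_xy = stats.pearsonr(x, y).statistic
    r_xz = stats.pearsonr(x, z).statistic
    r_yz = stats.pearsonr(y, z).statistic
    if min(1 - r_xz**2, 1 - r_yz**2) <= 1e-12:
        raise DegenerateConditioningError(
            "conditioning variable is perfectly correlated with an argument"
        )
    return float((r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2)))


@dataclass
class AisTeSummary:
    """AIS-TE association across ordered pairs, before and after removing
    the shared duplication atom."""

    correlation: float
    partial_correlation: float
    n_pairs: int
    table: pd.DataFrame

    def to_dict(self) -> Dict:
        return {
            "correlation": self.correlation,
            "partial_correlation": self.partial_correlation,
            "n_pairs": self.n_pairs,
        }


def ais_te_analysis(
    series: np.ndarray,
    lag: int = 1,
    backend: str = "mmi",
    model: Optional[str] = None,
) -> AisTeSummary:
    """Correlate per-source AIS with per-ordered-pair TE, then partial out
    the un1->red duplication atom shared by both measures."""
    result = pairwise_decompose(series, lag=lag, backend=backend, model=model)
    t = result.table
    if len(t) < 4:
        raise InsufficientDataError(
            f"only {len(t)} valid ordered pairs; need at least 4"
        )
    r = float(stats.pearsonr(t["ais_source"], t["te"]).statistic)
    pr = partial_correlation(t["ais_source"], t["te"], t["un_to_red"])
    return AisTeSummary(
        correlation=r, partial_correlation=pr, n_pairs=len(t), table=t
    )
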