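"""Balanced full-factorial sample designs and treatment-coded model matrices.

The experiment this package models is a 2x2x2 factorial mesocosm exposure:
three two-level stressors (Salinity, Sediment, Flow; each ambient vs
treated) crossed with eight replicate channels per cell, giving 64 RNA-seq
libraries.  Samples are ordered deterministically: cells in lexicographic
order of factor levels (ambient before treated, first factor slowest),
replicates numbered within each cell.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_FACTORS = ("Salinity", "Sediment", "Flow")

#: level labels; treatment coding maps ambient -> 0, treated -> 1
AMBIENT, TREATED = "ambient", "treated"


@dataclass(frozen=True)
class DesignSpec:
    """Specification of a balanced two-level full-factorial design.

    Parameters
    ----------
    factors : tuple of str
        Ordered factor names (1-4 factors, each with levels ambient/treated).
    replicates_per_cell : int
        Number of replicate samples per factor-level combination.
    factor_metadata : dict
        Optional free-form descriptors of the physical levels (e.g. chloride
        18.2 vs 312.2 mg/l); carried through for provenance only.
    """

    factors: tuple[str, ...] = DEFAULT_FACTORS
    replicates_per_cell: int = 8
    factor_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (1 <= len(self.factors) <= 4):
            raise ValueError(f"need 1-4 factors, got {len(self.factors)}")
        if len(set(self.factors)) != len(self.factors):
            raise ValueError("duplicate factor names")
        if self.replicates_per_cell < 1:
            raise ValueError(
                f"replicates_per_cell must be >= 1, got {self.replicates_per_cell}"
            )

    @property
    def n_samples(self) -> int:
        return self.replicates_per_cell * 2 ** len(self.factors)


def make_design(spec: DesignSpec) -> pd.DataFrame:
    """Expand a :class:`DesignSpec` into a per-sample factor table.

    Returns a DataFrame indexed by ``sample_id`` with one column per factor
    holding ``"ambient"`` or ``"treated"``.  The layout is deterministic:
    cells in lexicographic factor-level order, replicates numbered from 1.
    """
    rows = []
    for levels in itertools.product((AMBIENT, TREATED), repeat=len(spec.factors)):
        cell = "_".join(
            f"{f[:3]}{'1' if lv == TREATED else '0'}"
            for f, lv in zip(spec.factors, levels)
        )
        for rep in range(1, spec.replicates_per_cell + 1):
            rows.append({"sample_id": f"{cell}_r{rep}", **dict(zip(spec.factors, levels))})
    design = pd.DataFrame(rows).set_index("sample_id")
    assert len(design) == spec.n_samples
    return design


def factorial_terms(factors: tuple[str, ...] = DEFAULT_FACTORS) -> list[str]:
    """Names of all model terms of the full-factorial expansion.

    Order: Intercept, main effects, pairwise interactions, ..., highest-order
    interaction; interactions named ``A:B`` in factor order.
    """
    terms = ["Intercept"]
    for k in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, k):
            terms.append(":".join(combo))
    return terms


def build_model_matrix(
    design: pd.DataFrame,
    surrogates: pd.DataFrame | np.ndarray | None = None,
    factors: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Treatment-coded model matrix for ``~ F1 * F2 * ... * Fk`` plus surrogates.

    Columns are ordered Intercept, mains, pairwise, ..., top interaction,
    then SV1..SVk.  Interaction columns are elementwise products of their
    parent main-effect columns.  Raises ``ValueError`` on rank deficiency.
    """
    if factors is None:
        factors = tuple(c for c in design.columns if c in DEFAULT_FACTORS) or tuple(
            c for c in design.columns if design[c].isin([AMBIENT, TREATED]).all()
        )
    if not factors:
        raise ValueError("no two-level factors found in design")
    coded = {"Intercept": np.ones(len(design))}
    for f in factors:
        levels = set(design[f].unique())
        if not levels <= {AMBIENT, TREATED}:
            raise ValueError(f"factor {f!r} has levels {levels}, expected ambient/treated")
        coded[f] = (design[f] == TREATED).to_numpy(dtype=float)
    for term in factorial_terms(factors)[1 + len(factors):]:
        parents = term.split(":")
        col = np.ones(len(design))
        for p in parents:
            col = col * coded[p]
        coded[term] = col
    mm = pd.DataFrame(coded, index=design.index)
    if surrogates is not None:
        sv = np.asarray(surrogates, dtype=float)
        if sv.ndim == 1:
            sv = sv[:, None]
        if sv.shape[0] != len(design):
            raise ValueError("surrogate rows do not match design samples")
        for j in range(sv.shape[1]):
            mm[f"SV{j + 1}"] = sv[:, j]
    if np.linalg.matrix_rank(mm.to_numpy()) < mm.shape[1]:
        raise ValueError(f"model matrix is rank deficient (columns: {list(mm.columns)})")
    return mm
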