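"""Synergistic/antagonistic interaction classification and DE-set accounting.

For a pair of stressors A and B under treatment coding, the expected
combined log2 fold change of the A+B treatment (relative to ambient) is
``beta_A + beta_B`` — additivity on the log scale, i.e. multiplicative
effects on the count scale.  The fitted interaction coefficient is the
deviation of the observed combined response from that expectation, and its
sign relative to the sign of the expectation defines four classes:

========  ==================  =====================  =========================
class     expected combined   interaction coeff.     reading
========  ==================  =====================  =========================
S+        >= 0                > 0                    more upregulated than expected
A+        > 0                 < 0                    less upregulated than expected
S-        <= 0                < 0                    more downregulated than expected
A-        < 0                 > 0                    less downregulated than expected
========  ==================  =====================  =========================

For the three-way combination the expectation sums all lower-order terms
(three mains and three pairwise interactions) and the three-way coefficient
plays the interaction role.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

#: stressor combinations in report order
COMBINATIONS = (
    "Salinity:Flow",
    "Salinity:Sediment",
    "Sediment:Flow",
    "Salinity:Sediment:Flow",
)

CLASS_LABELS = ("S+", "S-", "A+", "A-")


def expected_combined_lfc(coefs: pd.Series | dict, combo: str) -> float:
    """Expected combined LFC of a stressor combination: the sum of all
    lower-order coefficients among its factors (term names as in the model
    matrix, e.g. ``Salinity``, ``Salinity:Sediment``)."""
    if combo not in COMBINATIONS:
        raise ValueError(f"unknown combination {combo!r}; expected one of {COMBINATIONS}")
    parents = combo.split(":")
    total = sum(float(coefs[p]) for p in parents)
    if len(parents) == 3:
        for pair in itertools.combinations(parents, 2):
            key = ":".join(pair)
            key = key if key in coefs else ":".join(reversed(pair))
            total += float(coefs[key])
    return total


def classify_interaction(expected: float, interaction: float, eps: float = 1e-6) -> str:
    """Classify one significant interaction into S+/S-/A+/A-.

    ``expected`` is the combined LFC predicted from lower-order terms;
    ``interaction`` the fitted interaction coefficient.  An interaction
    within ``eps`` of zero is a caller error (only significant interactions
    should be classified).  When the expectation itself is within ``eps`` of
    zero, any deviation is synergistic by convention (S+ if the interaction
    is positive, S- if negative).
    """
    if abs(interaction) <= eps:
        raise ValueError("interaction coefficient is ~0; classify only significant interactions")
    if expected >= eps:
        return "S+" if interaction > 0 else "A+"
    if expected <= -eps:
        return "S-" if interaction < 0 else "A-"
    return "S+" if interaction > 0 else "S-"


@dataclass(frozen=True)
class InteractionCall:
    gene: str
    combination: str
    expected_lfc: float
    interaction_lfc: float
    label: str
    padj: float


def call_interactions(
    coef: pd.DataFrame,
    padj: pd.DataFrame,
    fdr: float = 0.1,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """Classify every gene x combination whose interaction term is significant.

    Parameters
    ----------
    coef, padj : DataFrame
        Genes x model-term tables of fitted log2 coefficients and
        BH-adjusted p-values (term names as in the model matrix).
    fdr : float
        Significance threshold on the interaction term's adjusted p.

    Returns a tidy DataFrame (gene, combination, expected_lfc,
    interaction_lfc, class, padj).
    """
    records = []
    for combo in COMBINATIONS:
        sig = padj.index[padj[combo] < fdr]
        for gene in sig:
            inter = float(coef.at[gene, combo])
            if abs(inter) <= eps:
                continue
            exp = expected_combined_lfc(coef.loc[gene], combo)
            records.append(
                (gene, combo, exp, inter, classify_interaction(exp, inter, eps),
                 float(padj.at[gene, combo]))
            )
    return pd.DataFrame(
        records,
        columns=["gene", "combination", "expected_lfc", "interaction_lfc", "class", "padj"],
    )


def tabulate_interactions(calls: pd.DataFrame) -> pd.DataFrame:
    """Count classified genes per class x combination (report layout: one
    row per class plus a total row; combination columns in report order)."""
    table = pd.DataFrame(0, index=list(CLASS_LABELS), columns=list(COMBINATIONS))
    if len(calls):
        counts = calls.groupby(["class", "combination"]).size()
        for (cls, combo), n in counts.items():
            table.at[cls, combo] = n
    table.loc["total"] = table.sum(axis=0)
    return table


def exclusive_intersections(sets: dict[str, set]) -> pd.DataFrame:
    """Partition the union of named gene sets into exclusive membership regions.

    Each gene is assigned to exactly one signature — the full set of input
    sets containing it — mirroring the exclusive intersections of an UpSet
    plot.  Returns non-empty regions sorted by count descending (signature
    as an ``&``-joined string in input-set order), with member gene lists.
    """
    if len(sets) > 16:
        raise ValueError("at most 16 sets supported")
    names = list(sets)
    membership: dict[str, tuple] = {}
    for gene in set().union(*sets.values()) if sets else set():
        membership[gene] = tuple(n for n in names if gene in sets[n])
    regions: dict[tuple, list] = {}
    for gene, sig in membership.items():
        regions.setdefault(sig, []).append(gene)
    rows = [
        ("&".join(sig), len(genes), sorted(genes)) for sig, genes in regions.items()
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return pd.DataFrame(rows, columns=["signature", "count", "genes"])


def lfc_treatment_tree(shrunken: pd.DataFrame) -> np.ndarray:
    """Average-linkage dendrogram over treatment columns from Euclidean
    distances of (shrunken) LFC profiles across genes.

    Non-significant entries should be zeroed by the caller beforehand.
    Returns the scipy linkage matrix; leaf order follows column order, which
    also fixes tie-breaking.
    """
    if shrunken.shape[1] < 2:
        raise ValueError("need at least 2 treatment columns")
    if shrunken.isna().any().any():
        raise ValueError("missing values; zero non-significant entries first")
    dist = pdist(shrunken.to_numpy().T, metric="euclidean")
    return linkage(dist, method="average")
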