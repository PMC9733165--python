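"""Surrogate-variable estimation and frozen correction.

Hidden (batch-like) variation is estimated from the part of the expression
matrix not explained by the factorial design: the design is regressed out
of each gene's VST profile, and the leading right-singular vectors of the
residual matrix are candidate surrogates.  Their number k is chosen by a
permutation ("parallel analysis") test: a component is kept while its
variance share exceeds the (1 - alpha) quantile of the share obtained
after independently permuting each gene's residuals across samples, which
destroys any shared sample structure.  This is a deliberately simplified,
fully deterministic variant of iterative surrogate-variable analysis.

``freeze_correct`` removes the surrogate-attributable signal for
visualisation/clustering: per gene, an OLS fit on [design | surrogates]
is computed and only the fitted surrogate contribution is subtracted, so
design-attributable signal is retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import build_model_matrix


@dataclass
class SurrogateSet:
    """k estimated surrogate vectors (samples x k, zero mean, orthogonal)
    plus the permutation evidence that selected them."""

    values: pd.DataFrame
    variance_share: np.ndarray = field(default_factory=lambda: np.empty(0))
    null_quantile: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def k(self) -> int:
        return self.values.shape[1]

    @classmethod
    def empty(cls, samples) -> "SurrogateSet":
        return cls(pd.DataFrame(index=samples))


def _residualise(mat: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Project each row of ``mat`` (genes x samples) off the column space of
    X (samples x p)."""
    coef, *_ = np.linalg.lstsq(X, mat.T, rcond=None)
    return mat - (X @ coef).T


def _variance_shares(resid: np.ndarray, k: int) -> np.ndarray:
    sv = np.linalg.svd(resid, compute_uv=False)
    total = np.sum(sv**2)
    if total <= 0:
        return np.zeros(k)
    shares = sv**2 / total
    return np.pad(shares[:k], (0, max(0, k - len(shares))))


def estimate_surrogates(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
) -> SurrogateSet:
    """Estimate surrogate variables from expression residuals.

    Parameters
    ----------
    expr : DataFrame
        Genes x samples VST matrix; columns must match the design rows.
    design : DataFrame
        Per-sample factor table (full model is the factorial expansion of
        its factors; the reduced model is the intercept alone).
    n_perm : int
        Number of row-wise permutations for the null (>= 20).
    alpha : float
        Significance level: a component is kept while its variance share
        exceeds the (1 - alpha) permutation quantile.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    if list(expr.columns) != list(design.index):
        raise ValueError("expr columns must match design samples (same order)")
    if seed is None:
        raise ValueError("seed is required")
    rng = np.random.default_rng(seed)

    X = build_model_matrix(design).to_numpy()
    mat = expr.to_numpy(dtype=float)
    resid = _residualise(mat, X)
    max_k = max(0, min(resid.shape) - X.shape[1])
    if max_k == 0 or not np.any(np.abs(resid) > 1e-12):
        return SurrogateSet.empty(expr.columns)

    shares = _variance_shares(resid, max_k)
    null = np.empty((n_perm, max_k))
    n = resid.shape[1]
    for p in range(n_perm):
        perm = resid.copy()
        # independent permutation of each gene's residuals across samples
        keys = rng.random(perm.shape)
        order = np.argsort(keys, axis=1)
        perm = np.take_along_axis(perm, order, axis=1)
        null[p] = _variance_shares(_residualise(perm, X), max_k)
    quantiles = np.quantile(null, 1.0 - alpha, axis=0)

    k = 0
    while k < max_k and shares[k] > quantiles[k]:
        k += 1
    if k == 0:
        return SurrogateSet.empty(expr.columns)

    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    sv = vt[:k].T  # samples x k right-singular vectors
    values = pd.DataFrame(sv, index=expr.columns, columns=[f"SV{i+1}" for i in range(k)])
    return SurrogateSet(values, shares[:k], quantiles[:k])


def freeze_correct(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    sv: SurrogateSet,
) -> pd.DataFrame:
    """Remove the fitted surrogate contribution from each gene's profile.

    Per gene, fit OLS on [factorial design | surrogates] and subtract only
    the surrogate columns' fitted values.  With k = 0 the input is returned
    unchanged.
    """
    if sv.k == 0:
        return expr.copy()
    X = build_model_matrix(design).to_numpy()
    S = sv.values.reindex(expr.columns).to_numpy()
    M = np.hstack([X, S])
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError(
            "design and surrogate columns are collinear; cannot separate "
            "surrogate signal from design signal"
        )
    coef, *_ = np.linalg.lstsq(M, expr.to_numpy().T, rcond=None)
    sv_part = S @ coef[X.shape[1]:]
    return pd.DataFrame(
        expr.to_numpy() - sv_part.T, index=expr.index, columns=expr.columns
    )
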