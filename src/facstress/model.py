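"""Model/Results interface for the factorial stressor analysis.

`StressFactorialModel` bundles a gene-level count table with the factorial
sample design; its :meth:`fit` runs normalisation, expression filtering,
surrogate-variable estimation and per-gene negative-binomial GLMs, and
returns a :class:`StressFactorialResults` carrying coefficients, standard
errors, adjusted p-values, shrunken log fold changes and the downstream
analyses (interaction classification, DE-set intersections, treatment
dendrogram, profile clustering, enrichment) as methods.

Example
-------
>>> from facstress import simulate, preprocess, StressFactorialModel
>>> design, truth, tx, sf = simulate.simulate_dataset(n_genes=500, seed=7)
>>> model = StressFactorialModel.from_transcripts(tx, design)
>>> res = model.fit(seed=7)
>>> print(res.summary())                      # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import glm, interactions, preprocess, profiles
from .covariates import SurrogateSet, estimate_surrogates, freeze_correct
from .design import DEFAULT_FACTORS, build_model_matrix, factorial_terms
from .enrichment import OntologyDAG, elim_enrichment
from .preprocess import GeneCounts


class StressFactorialModel:
    """Negative-binomial GLM model of a 2^k factorial stressor experiment.

    Parameters
    ----------
    gene_counts : GeneCounts
        Gene-level estimated counts (non-negative reals allowed).
    design : DataFrame
        Per-sample factor table with levels ambient/treated; extra columns
        (e.g. a known batch) are carried along but not modelled.
    min_count, min_samples : filtering rule — keep genes with at least
        ``min_count`` normalised counts in at least ``min_samples`` samples.
    """

    def __init__(
        self,
        gene_counts: GeneCounts,
        design: pd.DataFrame,
        min_count: float = 10.0,
        min_samples: int = 8,
    ):
        if list(gene_counts.samples) != list(design.index):
            raise ValueError("count columns and design rows must match (same order)")
        self.gene_counts = gene_counts
        self.design = design
        self.factors = tuple(f for f in DEFAULT_FACTORS if f in design.columns) or tuple(
            c for c in design.columns if set(design[c].unique()) <= {"ambient", "treated"}
        )
        self.min_count = min_count
        self.min_samples = min_samples

    @classmethod
    def from_transcripts(cls, tx: pd.DataFrame, design: pd.DataFrame, **kw):
        """Build from a transcript-level table (transcript_id, gene_id,
        effective_length, one column per sample)."""
        return cls(preprocess.summarise_to_gene(tx), design, **kw)

    @classmethod
    def from_tsv(cls, counts_path, design_path, **kw):
        from .io import read_design, read_transcripts

        return cls.from_transcripts(read_transcripts(counts_path), read_design(design_path), **kw)

    def fit(
        self,
        fdr: float = 0.1,
        estimate_sv: bool = True,
        n_perm: int = 100,
        sv_alpha: float = 0.05,
        refine_dispersion: bool = True,
        shrink: bool = True,
        seed: int = 0,
    ) -> "StressFactorialResults":
        """Run the full inference chain and return results.

        Steps: median-of-ratios size factors; expression filter; VST;
        surrogate estimation on the VST matrix (optional); NB GLM per gene
        on [factorial design | surrogates] with per-gene moment dispersions;
        Wald tests with per-term BH adjustment; adaptive shrinkage of the
        factorial log fold changes (optional).
        """
        sf = preprocess.size_factors(self.gene_counts)
        filtered = preprocess.filter_genes(
            self.gene_counts, sf, self.min_count, self.min_samples
        )
        expr = preprocess.vst(filtered, sf)
        if estimate_sv:
            sv = estimate_surrogates(
                expr, self.design[list(self.factors)], n_perm=n_perm,
                alpha=sv_alpha, seed=seed,
            )
        else:
            sv = SurrogateSet.empty(expr.columns)
        mm = build_model_matrix(
            self.design, sv.values if sv.k else None, factors=self.factors
        )
        fit = glm.fit_all_genes(filtered.counts, mm, sf, refine_dispersion)

        fac_terms = factorial_terms(self.factors)[1:]
        if shrink:
            shrunken = {}
            for term in fac_terms:  # per-term shrinkage families
                ok = fit.se[term] > 0
                res = glm.shrink_lfc(fit.coef.loc[ok, term], fit.se.loc[ok, term])
                col = pd.Series(np.nan, index=fit.coef.index)
                col[ok] = res.posterior_mean
                shrunken[term] = col
            shrunken = pd.DataFrame(shrunken)
        else:
            shrunken = fit.coef[fac_terms].copy()
        return StressFactorialResults(
            model=self, fit=fit, shrunken_lfc=shrunken, size_factors=sf,
            surrogates=sv, vst=expr, filtered=filtered, fdr=fdr,
        )


@dataclass
class StressFactorialResults:
    """Fitted results of a :class:`StressFactorialModel`."""

    model: StressFactorialModel
    fit: glm.GeneFitTable
    shrunken_lfc: pd.DataFrame
    size_factors: pd.Series
    surrogates: SurrogateSet
    vst: pd.DataFrame
    filtered: GeneCounts
    fdr: float = 0.1
    _cache: dict = field(default_factory=dict, repr=False)

    # -- basic accessors ---------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.fit.coef.index

    @property
    def factorial_terms(self) -> list[str]:
        return factorial_terms(self.model.factors)[1:]

    def de_genes(self, term: str, direction: str | None = None) -> pd.Index:
        """Genes significant for ``term`` at the fitted FDR, optionally
        restricted to up- or down-regulation (sign of the coefficient)."""
        sig = self.fit.padj[term] < self.fdr
        if direction == "up":
            sig &= self.fit.coef[term] > 0
        elif direction == "down":
            sig &= self.fit.coef[term] < 0
        elif direction is not None:
            raise ValueError("direction must be 'up', 'down' or None")
        return self.genes[sig.fillna(False)]

    def de_sets(self) -> dict[str, dict[str, set]]:
        return {
            t: {"up": set(self.de_genes(t, "up")), "down": set(self.de_genes(t, "down"))}
            for t in self.factorial_terms
        }

    # -- interactions ------------------------------------------------------
    def interaction_calls(self, use_shrunken: bool = False) -> pd.DataFrame:
        key = ("calls", use_shrunken)
        if key not in self._cache:
            coef = self.shrunken_lfc if use_shrunken else self.fit.coef
            self._cache[key] = interactions.call_interactions(
                coef, self.fit.padj, fdr=self.fdr
            )
        return self._cache[key]

    def interaction_table(self, use_shrunken: bool = False) -> pd.DataFrame:
        """Class x combination counts of significant interactions."""
        return interactions.tabulate_interactions(self.interaction_calls(use_shrunken))

    def exclusive_intersections(self, direction: str | None = None) -> pd.DataFrame:
        """UpSet-style exclusive intersections of per-treatment DE sets."""
        sets = {
            t: set(self.de_genes(t, direction)) for t in self.factorial_terms
        }
        return interactions.exclusive_intersections(sets)

    def treatment_tree(self) -> np.ndarray:
        """Average-linkage dendrogram of the 7 treatment terms from Euclidean
        distances over shrunken LFCs, non-significant entries zeroed."""
        lfc = self.shrunken_lfc.copy()
        for t in lfc.columns:
            lfc.loc[~(self.fit.padj[t] < self.fdr).fillna(False), t] = 0.0
        return interactions.lfc_treatment_tree(lfc.fillna(0.0))

    # -- profiles ----------------------------------------------------------
    def corrected_vst(self) -> pd.DataFrame:
        """VST matrix with the frozen surrogate contribution removed."""
        if "corrected" not in self._cache:
            self._cache["corrected"] = freeze_correct(
                self.vst, self.model.design[list(self.model.factors)], self.surrogates
            )
        return self._cache["corrected"]

    def cluster_interaction_profiles(
        self, min_size: int = 10, k_max: int = 8, seed: int = 0
    ) -> profiles.ProfileClustering:
        """Cluster genes with any significant interaction by z-scored,
        surrogate-corrected profiles."""
        calls = self.interaction_calls()
        genes = sorted(set(calls["gene"]))
        if not genes:
            return profiles.ProfileClustering(
                pd.Series(dtype=int, name="cluster"), pd.DataFrame()
            )
        z, _ = profiles.zscore_profiles(self.corrected_vst(), genes)
        return profiles.cluster_profiles(
            z, self.model.design, min_size=min_size, k_max=k_max, seed=seed
        )

    # -- enrichment --------------------------------------------------------
    def enrich(
        self,
        dag: OntologyDAG,
        term: str,
        direction: str = "up",
        alpha_elim: float = 0.01,
    ) -> pd.DataFrame:
        """elim enrichment of the up- or down-regulated DE set of a model
        term; universe = all genes tested for differential expression."""
        study = set(self.de_genes(term, direction)) & set(self.genes)
        return elim_enrichment(dag, study, set(self.genes), alpha_elim)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        """Human-readable overview of the fit."""
        lines = [
            "Factorial stressor NB-GLM results",
            "=" * 48,
            f"genes tested:       {len(self.genes)}",
            f"samples:            {self.vst.shape[1]}",
            f"surrogates (k):     {self.surrogates.k}",
            f"FDR threshold:      {self.fdr}",
            f"non-converged fits: {int((~self.fit.converged).sum())}",
            "",
            f"{'term':<28}{'DE':>6}{'up':>6}{'down':>6}",
        ]
        for t in self.factorial_terms:
            up = len(self.de_genes(t, "up"))
            dn = len(self.de_genes(t, "down"))
            lines.append(f"{t:<28}{up + dn:>6}{up:>6}{dn:>6}")
        tab = self.interaction_table()
        lines += ["", "interaction classes (genes per combination):", tab.to_string()]
        return "\n".join(lines)

    def results_frame(self) -> pd.DataFrame:
        """Tidy per-gene x term table (beta, se, z, p, padj, shrunken_lfc,
        converged)."""
        rows = []
        for t in self.fit.terms:
            rows.append(
                pd.DataFrame(
                    {
                        "gene": self.genes,
                        "term": t,
                        "beta": self.fit.coef[t],
                        "se": self.fit.se[t],
                        "z": self.fit.z[t],
                        "pvalue": self.fit.pvalue[t],
                        "padj": self.fit.padj[t],
                        "shrunken_lfc": self.shrunken_lfc[t]
                        if t in self.shrunken_lfc
                        else np.nan,
                        "converged": self.fit.converged,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)
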