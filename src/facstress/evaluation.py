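"""Seeded benchmark routines scoring the pipeline against simulated truth.

Each function simulates data under stated study conditions, runs the
package's own machinery, and returns the recovery/calibration metrics as a
plain dict.  They are used both by the test suite and by the acceptance
script; all randomness flows from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from . import preprocess
from .design import DesignSpec, make_design
from .model import StressFactorialModel
from .simulate import (
    EffectConfig,
    sample_truth,
    simulate_dataset,
    true_expected_lfc,
)

NULL_CONFIG = EffectConfig(frac_de=0.0, frac_interaction=0.0, batch_frac=0.0)
#: the standard simulation: 10% non-null genes, |log2 effects| ~ N(1, 0.25^2)
STANDARD_CONFIG = EffectConfig()


def _spawn(seed: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % 2**31)
            for c in np.random.SeedSequence(seed).spawn(n)]


def _fit(seed: int, n_genes: int, config: EffectConfig, **fit_kw):
    design, truth, tx, _ = simulate_dataset(
        n_genes=n_genes, effect_config=config, seed=seed
    )
    model = StressFactorialModel.from_transcripts(tx, design)
    res = model.fit(seed=seed, shrink=fit_kw.pop("shrink", False), **fit_kw)
    return truth, res


def null_calibration(
    seed: int,
    n_genes: int = 2000,
    n_reps: int = 20,
    fdr: float = 0.1,
) -> dict:
    """Global-null simulation: p-value uniformity and false-call rates.

    One ``n_genes`` x 64 draw supplies per-term Kolmogorov-Smirnov tests of
    the raw p-values against U(0,1); ``n_reps`` further draws record the
    fraction of genes called DE (any factorial term, BH-adjusted p < fdr).
    """
    seeds = _spawn(seed, n_reps + 1)
    truth, res = _fit(seeds[0], n_genes, NULL_CONFIG)
    ks = {
        t: float(stats.kstest(res.fit.pvalue[t].dropna(), "uniform").pvalue)
        for t in res.factorial_terms
    }
    rates = []
    for s in seeds[1:]:
        _, r = _fit(s, n_genes, NULL_CONFIG)
        called = (r.fit.padj[r.factorial_terms] < fdr).any(axis=1)
        rates.append(float(called.mean()))
    return {
        "ks_pvalues": ks,
        "min_ks_pvalue": min(ks.values()),
        "de_call_rates": rates,
        "reps_within_1pct": int(sum(r <= 0.01 for r in rates)),
        "n_reps": n_reps,
        "n_genes": n_genes,
    }


def standard_sim_metrics(
    seed: int,
    n_genes: int = 1000,
    n_reps: int = 20,
    fdr: float = 0.1,
    high_mean: float = 50.0,
) -> dict:
    """FDR control, sensitivity and interaction-class recovery under the
    standard simulation, pooled over ``n_reps`` replicates.

    - empirical FDR: genes x terms called at BH-adjusted p < fdr whose true
      coefficient is zero, over all calls;
    - sensitivity: fraction of truly non-null genes with mean normalised
      count >= ``high_mean`` that are detected on at least one of their
      truly non-zero terms;
    - class recovery: fraction of injected interaction genes reaching
      interaction padj < fdr whose fitted classification matches the
      injected label.
    """
    seeds = _spawn(seed, n_reps)
    false_calls = total_calls = 0
    detected_high = nonnull_high = 0
    class_hits = class_total = 0
    for s in seeds:
        truth, res = _fit(s, n_genes, STANDARD_CONFIG)
        terms = res.factorial_terms
        tested = truth.loc[res.genes]
        true_beta = tested[["beta_" + t for t in terms]].to_numpy()
        called = (res.fit.padj[terms] < fdr).to_numpy()
        nonnull = true_beta != 0.0
        false_calls += int((called & ~nonnull).sum())
        total_calls += int(called.sum())

        norm = res.filtered.counts.to_numpy() / res.size_factors.to_numpy()[None, :]
        high = norm.mean(axis=1) >= high_mean
        gene_nonnull = nonnull.any(axis=1)
        gene_hit = (called & nonnull).any(axis=1)
        detected_high += int((gene_hit & gene_nonnull & high).sum())
        nonnull_high += int((gene_nonnull & high).sum())

        calls = res.interaction_calls()
        lookup = {(g, c): lab for g, c, lab in
                  zip(calls["gene"], calls["combination"], calls["class"])}
        for combo in ("Salinity:Flow", "Salinity:Sediment", "Sediment:Flow",
                      "Salinity:Sediment:Flow"):
            injected = tested[tested[f"class_{combo}"] != ""]
            sig = injected.index[
                (res.fit.padj.loc[injected.index, combo] < fdr).fillna(False)
            ]
            for g in sig:
                class_total += 1
                if lookup.get((g, combo)) == injected.at[g, f"class_{combo}"]:
                    class_hits += 1
    return {
        "empirical_fdr": false_calls / total_calls if total_calls else 0.0,
        "sensitivity_high_expression": detected_high / nonnull_high
        if nonnull_high else float("nan"),
        "class_recovery": class_hits / class_total if class_total else float("nan"),
        "n_classified": class_total,
        "n_calls": total_calls,
        "n_reps": n_reps,
        "n_genes": n_genes,
    }


def signflip_symmetry_exact(seed: int, n_genes: int = 300) -> bool:
    """Noiseless sign-flip equivariance: classifying from the true
    coefficients after negating them swaps S+ with S- and A+ with A-."""
    from .interactions import COMBINATIONS, classify_interaction

    truth = sample_truth(
        n_genes, EffectConfig(frac_de=0.0, frac_interaction=1.0), seed=seed
    )
    swap = {"S+": "S-", "S-": "S+", "A+": "A-", "A-": "A+"}
    for combo in COMBINATIONS:
        lab = truth[truth[f"class_{combo}"] != ""]
        for g, row in lab.iterrows():
            flipped = classify_interaction(
                -true_expected_lfc(row, combo), -row[f"beta_{combo}"]
            )
            if flipped != swap[row[f"class_{combo}"]]:
                return False
    return True


def surrogate_recovery(seed: int, n_genes: int = 800) -> dict:
    """Batch recovery and frozen-correction fidelity.

    Simulates the standard dataset (latent batch on 30% of genes, loading
    ~1 log2 unit), estimates surrogates, and measures (i) |Pearson r|
    between the first surrogate and the true batch, (ii) the shrinkage of
    the between-batch mean difference of loaded genes after frozen
    correction, and (iii) the relative change of true design-group
    differences for genes with a true Salinity effect.
    """
    from .covariates import freeze_correct

    design, truth, tx, _ = simulate_dataset(n_genes=n_genes, seed=seed)
    model = StressFactorialModel.from_transcripts(tx, design)
    sf = preprocess.size_factors(model.gene_counts)
    filtered = preprocess.filter_genes(model.gene_counts, sf)
    expr = preprocess.vst(filtered, sf)
    from .covariates import estimate_surrogates

    factors = design[list(model.factors)]
    sv = estimate_surrogates(expr, factors, n_perm=100, seed=seed)
    batch = design["batch"].to_numpy(dtype=float)
    r = (
        float(np.corrcoef(sv.values.iloc[:, 0], batch)[0, 1]) if sv.k else 0.0
    )
    corrected = freeze_correct(expr, factors, sv)

    tested = truth.loc[expr.index]
    loaded = (tested["gamma"].abs() >= 1.0).to_numpy()

    def batch_sep(mat):
        m = mat.to_numpy()[loaded]
        return float(np.abs(m[:, batch == 1].mean(1) - m[:, batch == 0].mean(1)).mean())

    sal = (design["Salinity"] == "treated").to_numpy()
    de = (tested["beta_Salinity"].abs() > 0).to_numpy()

    def design_diff(mat):
        m = mat.to_numpy()[de]
        return m[:, sal].mean(1) - m[:, ~sal].mean(1)

    before, after = batch_sep(expr), batch_sep(corrected)
    d_before, d_after = design_diff(expr), design_diff(corrected)
    return {
        "k": int(sv.k),
        "abs_corr_batch": abs(r),
        "batch_separation_removed": 1.0 - after / before if before else float("nan"),
        "design_contrast_change": float(
            np.mean(np.abs(d_after - d_before) / np.maximum(np.abs(d_before), 1e-9))
        ),
        "n_genes": n_genes,
    }


def clustering_recovery(seed: int, noise_sd: float = 0.2) -> dict:
    """Two 20-gene profile groups plus one 5-gene group below the minimum
    cluster size: adjusted Rand index on the recoverable groups and the
    fate of the undersized group."""
    from .profiles import cluster_profiles

    rng = np.random.default_rng(seed)
    design = make_design(DesignSpec())
    key = design[["Salinity", "Sediment", "Flow"]].agg("|".join, axis=1)
    cells = sorted(key.unique())
    shapes = [
        [1, 1, 1, 1, -1, -1, -1, -1],
        [1, -1, 1, -1, 1, -1, 1, -1],
        [1, 1, -1, -1, 1, 1, -1, -1],
    ]
    sizes = [20, 20, 5]
    rows, names, labels = [], [], []
    for gi, (n, signs) in enumerate(zip(sizes, shapes)):
        lookup = dict(zip(cells, signs))
        base = np.array([lookup[k] for k in key])
        for j in range(n):
            rows.append(base + rng.normal(0, noise_sd, len(design)))
            names.append(f"grp{gi}_g{j:03d}")
            labels.append(gi)
    z = pd.DataFrame(rows, index=names, columns=design.index)
    res = cluster_profiles(z, design, min_size=10, seed=seed)
    truth = pd.Series(labels, index=z.index).loc[res.assignments.index]
    big = truth < 2
    ari = float(adjusted_rand_score(truth[big], res.assignments[big]))
    small_unassigned = set(truth.index[truth == 2]) <= set(res.unassigned)
    return {
        "ari_two_groups": ari,
        "small_group_unassigned": bool(small_unassigned),
        "n_clusters": int(res.n_clusters),
    }
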