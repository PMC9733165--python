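"""Synthetic factorial RNA-seq data with known ground truth.

Generates transcript-level estimated counts under the same model the
inference machinery fits: per-gene negative-binomial counts whose log2 mean
is linear in the treatment-coded 2x2x2 factorial design, plus a latent
binary batch.  Every gene carries a ground-truth record (coefficients,
dispersion, batch loading, injected interaction class) so that recovery of
differential expression, interaction classes, surrogates and clusters can
be scored exactly.

The generator is the stand-in for the study system it emulates: 64
libraries (8 replicates per cell), multi-isoform transcripts with
estimated (real-valued) counts, library-size variation via size factors,
and a batch crossed with — not confounded with — the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DEFAULT_FACTORS, DesignSpec, factorial_terms, make_design
from .interactions import COMBINATIONS, classify_interaction

#: gene status labels in the truth table
NULL, DE_ONLY, INTERACTION = "null", "DE-only", "interaction"

CLASSES = ("S+", "S-", "A+", "A-")


@dataclass(frozen=True)
class EffectConfig:
    """Distributional parameters of the ground truth.

    Defaults describe the standard simulation: 10% of genes non-null with
    log2 effect magnitudes ~ N(1, 0.25^2), dispersions log-normal with
    median 0.1, baseline means log-uniform in [5, 5000] (spanning the
    expression filter boundary), and a batch loading on 30% of genes.
    """

    frac_de: float = 0.05          # main-effects-only genes
    frac_interaction: float = 0.05  # genes with one injected interaction
    effect_mean: float = 1.0       # |log2 effect| location
    effect_sd: float = 0.25
    min_effect: float = 0.3        # keep injected effects bounded away from 0
    dispersion_median: float = 0.1
    dispersion_sigma: float = 0.5  # sdlog of the log-normal dispersion
    mean_low: float = 5.0          # baseline mean counts, log-uniform
    mean_high: float = 5000.0
    batch_frac: float = 0.3        # fraction of genes loaded on the batch
    batch_strength: float = 1.0    # |gamma| location (log2 units)
    class_mix: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)  # S+, S-, A+, A-
    combo_mix: tuple[float, ...] = (0.3, 0.3, 0.3, 0.1)  # order of COMBINATIONS

    def __post_init__(self) -> None:
        for name in ("frac_de", "frac_interaction", "batch_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.frac_de + self.frac_interaction > 1.0 + 1e-12:
            raise ValueError("frac_de + frac_interaction exceeds 1")
        if abs(sum(self.class_mix) - 1) > 1e-9 or abs(sum(self.combo_mix) - 1) > 1e-9:
            raise ValueError("class_mix and combo_mix must each sum to 1")


@dataclass(frozen=True)
class IsoformConfig:
    """Isoform structure: 1-4 isoforms per gene, lengths log-uniform in
    [300, 5000] bases, usage weights Dirichlet(1)."""

    max_isoforms: int = 4
    length_low: float = 300.0
    length_high: float = 5000.0
    dirichlet_alpha: float = 1.0


BETA_COLUMNS = ["beta_" + t for t in factorial_terms(DEFAULT_FACTORS)[1:]]


def _draw_magnitude(rng: np.random.Generator, cfg: EffectConfig, size=None) -> np.ndarray:
    m = rng.normal(cfg.effect_mean, cfg.effect_sd, size=size)
    return np.maximum(np.abs(m), cfg.min_effect)


def sample_truth(
    n_genes: int,
    effect_config: EffectConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw a ground-truth table for ``n_genes`` genes.

    Returns a DataFrame indexed by gene id with the 7 factorial log2
    coefficients, baseline ``beta0`` (log2 mean at all-ambient), dispersion,
    batch loading ``gamma``, a ``status`` column (null / DE-only /
    interaction) and one ``class_<combo>`` column per stressor combination
    holding the injected class (S+/S-/A+/A-) or the empty string.

    Injected classes satisfy the interaction classification rule by
    construction: the class is re-derivable from the true coefficients.
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    cfg = effect_config or EffectConfig()
    rng = np.random.default_rng(seed)

    genes = [f"g{i:06d}" for i in range(1, n_genes + 1)]
    truth = pd.DataFrame(0.0, index=pd.Index(genes, name="gene_id"), columns=BETA_COLUMNS)
    truth.insert(
        0, "beta0",
        np.log2(np.exp(rng.uniform(np.log(cfg.mean_low), np.log(cfg.mean_high), n_genes))),
    )
    truth["dispersion"] = rng.lognormal(np.log(cfg.dispersion_median), cfg.dispersion_sigma, n_genes)
    loaded = rng.random(n_genes) < cfg.batch_frac
    gamma = np.where(
        loaded,
        rng.choice([-1.0, 1.0], n_genes) * np.maximum(
            np.abs(rng.normal(cfg.batch_strength, cfg.effect_sd, n_genes)), cfg.min_effect
        ),
        0.0,
    )
    truth["gamma"] = gamma
    truth["status"] = NULL
    for combo in COMBINATIONS:
        truth[f"class_{combo}"] = ""

    u = rng.random(n_genes)
    de_mask = u < cfg.frac_de
    int_mask = (u >= cfg.frac_de) & (u < cfg.frac_de + cfg.frac_interaction)
    truth.loc[de_mask, "status"] = DE_ONLY
    truth.loc[int_mask, "status"] = INTERACTION

    # DE-only genes: one random main effect of random sign
    idx_de = np.flatnonzero(de_mask)
    for i in idx_de:
        factor = DEFAULT_FACTORS[rng.integers(len(DEFAULT_FACTORS))]
        truth.iloc[i, truth.columns.get_loc(f"beta_{factor}")] = (
            rng.choice([-1.0, 1.0]) * _draw_magnitude(rng, cfg)
        )

    # interaction genes: pick combination and class, set signed coefficients
    idx_int = np.flatnonzero(int_mask)
    for i in idx_int:
        combo = COMBINATIONS[rng.choice(len(COMBINATIONS), p=cfg.combo_mix)]
        cls = CLASSES[rng.choice(len(CLASSES), p=cfg.class_mix)]
        exp_sign = 1.0 if cls in ("S+", "A+") else -1.0
        int_sign = 1.0 if cls in ("S+", "A-") else -1.0
        parents = combo.split(":")
        for p in parents:
            truth.iloc[i, truth.columns.get_loc(f"beta_{p}")] = exp_sign * _draw_magnitude(rng, cfg)
        truth.iloc[i, truth.columns.get_loc(f"beta_{combo}")] = int_sign * _draw_magnitude(rng, cfg)
        truth.iloc[i, truth.columns.get_loc(f"class_{combo}")] = cls

    _check_class_consistency(truth)
    return truth


def _check_class_consistency(truth: pd.DataFrame) -> None:
    """Injected labels must satisfy the classification rule exactly."""
    for combo in COMBINATIONS:
        labelled = truth[truth[f"class_{combo}"] != ""]
        for gene, row in labelled.iterrows():
            expected = true_expected_lfc(row, combo)
            derived = classify_interaction(expected, row[f"beta_{combo}"])
            if derived != row[f"class_{combo}"]:
                raise AssertionError(
                    f"injected class {row[f'class_{combo}']} for {gene}/{combo} "
                    f"re-derives as {derived}"
                )


def true_expected_lfc(row: pd.Series, combo: str) -> float:
    """Expected combined LFC of ``combo`` from true coefficients: the sum of
    all lower-order terms among the combination's factors."""
    parents = combo.split(":")
    total = sum(row[f"beta_{p}"] for p in parents)
    if len(parents) == 3:
        import itertools

        for pair in itertools.combinations(parents, 2):
            total += row["beta_" + ":".join(pair)]
    return float(total)


def assign_batch(design: pd.DataFrame) -> pd.Series:
    """Latent binary batch crossed with the design: replicate parity within
    each cell, so the batch is orthogonal to every design contrast."""
    rep = design.index.str.extract(r"_r(\d+)$")[0].astype(int).to_numpy()
    return pd.Series((rep % 2).astype(int), index=design.index, name="batch")


def draw_size_factors(n: int, sigma: float = 0.2, seed: int | None = None) -> np.ndarray:
    """Library-size factors: log-normal, rescaled to geometric mean 1."""
    rng = np.random.default_rng(seed)
    s = rng.lognormal(0.0, sigma, n)
    return s / np.exp(np.mean(np.log(s)))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Negative-binomial via gamma-Poisson mixture; Poisson limit as alpha -> 0.

    var = mu + alpha * mu^2; alpha is per-gene (rows of mu).
    """
    alpha = np.asarray(alpha, dtype=float)[:, None]
    out = np.empty_like(mu)
    poisson_like = np.broadcast_to(alpha <= 1e-10, mu.shape)
    out[poisson_like] = rng.poisson(mu[poisson_like])
    nb = ~poisson_like
    if nb.any():
        shape = np.broadcast_to(1.0 / np.where(alpha <= 1e-10, 1.0, alpha), mu.shape)
        lam = rng.gamma(shape[nb], (mu * np.broadcast_to(alpha, mu.shape))[nb])
        out[nb] = rng.poisson(lam)
    return out


def simulate_counts(
    truth: pd.DataFrame,
    design: pd.DataFrame,
    size_factors: np.ndarray | None = None,
    isoform_config: IsoformConfig | None = None,
    seed: int | None = None,
    batch: pd.Series | None = None,
) -> pd.DataFrame:
    """Simulate a transcript-level estimated-count table.

    The gene-level mean for sample ``j`` is ``s_j * 2**(x_j' beta + gamma *
    batch_j)``; counts are negative-binomial with the gene's dispersion and
    are partitioned across isoforms by fixed Dirichlet usage weights, so the
    emitted transcript counts are non-negative reals whose per-gene sums are
    the integer gene counts.

    Returns a DataFrame with columns ``transcript_id, gene_id,
    effective_length`` followed by one column per sample.
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    iso = isoform_config or IsoformConfig()
    rng = np.random.default_rng(seed)
    n_genes, n_samples = len(truth), len(design)
    if size_factors is None:
        size_factors = draw_size_factors(n_samples, seed=rng.integers(2**31))
    size_factors = np.asarray(size_factors, dtype=float)
    if size_factors.shape != (n_samples,):
        raise ValueError("size_factors length does not match design")
    if np.any(size_factors <= 0):
        raise ValueError("size factors must be strictly positive")
    if batch is None:
        batch = assign_batch(design)
    batch = batch.reindex(design.index).to_numpy(dtype=float)

    # treatment-coded factorial covariates (non-intercept terms)
    from .design import build_model_matrix

    mm = build_model_matrix(design).drop(columns="Intercept")
    betas = truth[["beta_" + c for c in mm.columns]].to_numpy()
    log2_mu = (
        truth["beta0"].to_numpy()[:, None]
        + betas @ mm.to_numpy().T
        + truth["gamma"].to_numpy()[:, None] * batch[None, :]
    )
    mu = size_factors[None, :] * np.exp2(np.clip(log2_mu, -30, 30))
    gene_counts = _nb_draw(rng, mu, truth["dispersion"].to_numpy()).astype(float)

    # isoform structure: fixed per-gene usage weights across samples
    n_iso = rng.integers(1, iso.max_isoforms + 1, n_genes)
    rows = []
    mat = []
    for g, gene in enumerate(truth.index):
        k = int(n_iso[g])
        lengths = np.exp(rng.uniform(np.log(iso.length_low), np.log(iso.length_high), k))
        weights = rng.dirichlet(np.full(k, iso.dirichlet_alpha))
        for t in range(k):
            rows.append((f"{gene}_i{t + 1}", gene, float(lengths[t])))
            mat.append(gene_counts[g] * weights[t])
    tx = pd.DataFrame(rows, columns=["transcript_id", "gene_id", "effective_length"])
    tx = pd.concat(
        [tx, pd.DataFrame(np.asarray(mat), columns=list(design.index))], axis=1
    )
    return tx


def simulate_dataset(
    n_genes: int = 2000,
    spec: DesignSpec | None = None,
    effect_config: EffectConfig | None = None,
    isoform_config: IsoformConfig | None = None,
    seed: int = 0,
):
    """Convenience wrapper: design + truth + counts with one master seed.

    Returns ``(design_with_batch, truth, transcript_table, size_factors)``.
    """
    ss = np.random.SeedSequence(seed)
    s_truth, s_sf, s_counts = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3)]
    design = make_design(spec or DesignSpec())
    truth = sample_truth(n_genes, effect_config, seed=s_truth)
    sf = draw_size_factors(len(design), seed=s_sf)
    tx = simulate_counts(truth, design, sf, isoform_config, seed=s_counts)
    design = design.copy()
    design["batch"] = assign_batch(design)
    return design, truth, tx, sf
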