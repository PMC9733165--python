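"""Transcript-to-gene summarisation, normalisation, filtering and VST.

Gene counts are the per-sample sums of member-transcript estimated counts
(total conserved); gene effective length is the transcript-abundance
weighted mean of member lengths, with weights proportional to
count/length.  Size factors use the median-of-ratios estimator rescaled
to geometric mean 1.  The expression filter keeps genes with at least
``min_count`` normalised counts in at least ``min_samples`` samples
(defaults 10 and 8, as applied to the 64-library study design).  The
variance-stabilising transform is the shifted log of normalised counts,
``log2(count/s + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

META_COLS = ("transcript_id", "gene_id", "effective_length")


@dataclass
class GeneCounts:
    """Gene-level estimated counts plus per-gene per-sample effective length.

    ``counts``: genes x samples DataFrame of non-negative reals.
    ``lengths``: matching DataFrame of average effective lengths (bases).
    """

    counts: pd.DataFrame
    lengths: pd.DataFrame

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def subset(self, genes) -> "GeneCounts":
        return GeneCounts(self.counts.loc[genes], self.lengths.loc[genes])


def summarise_to_gene(tx: pd.DataFrame) -> GeneCounts:
    """Summarise a transcript table to gene level.

    ``tx`` must have columns transcript_id, gene_id, effective_length and
    one column per sample.  Gene count is the sum of member transcript
    counts; gene effective length is the weighted mean of transcript
    lengths with weights proportional to count/length (isoform-abundance
    weights), falling back to the unweighted mean where all member counts
    in a sample are zero.
    """
    missing = [c for c in META_COLS if c not in tx.columns]
    if missing:
        raise ValueError(f"transcript table lacks columns {missing}")
    orphan = tx["gene_id"].isna() | (tx["gene_id"].astype(str).str.len() == 0)
    if orphan.any():
        raise ValueError(
            "transcripts without a gene id: "
            + ", ".join(tx.loc[orphan, "transcript_id"].astype(str).head(10))
        )
    if (tx["effective_length"] <= 0).any():
        bad = tx.loc[tx["effective_length"] <= 0, "transcript_id"].head(10)
        raise ValueError("non-positive effective lengths: " + ", ".join(bad.astype(str)))

    samples = [c for c in tx.columns if c not in META_COLS]
    cmat = tx[samples].to_numpy(dtype=float)
    if (cmat < 0).any():
        raise ValueError("negative transcript counts")
    lens = tx["effective_length"].to_numpy(dtype=float)

    gene_ids, inverse = np.unique(tx["gene_id"].to_numpy(), return_inverse=True)
    n_genes = len(gene_ids)
    counts = np.zeros((n_genes, len(samples)))
    np.add.at(counts, inverse, cmat)

    # abundance weights w = count/length; weighted length = sum(w*L)/sum(w)
    w = cmat / lens[:, None]
    wsum = np.zeros_like(counts)
    np.add.at(wsum, inverse, w)
    wl = np.zeros_like(counts)
    np.add.at(wl, inverse, w * lens[:, None])
    # unweighted fallback for all-zero gene/sample cells
    nper = np.zeros(n_genes)
    np.add.at(nper, inverse, 1.0)
    lsum = np.zeros(n_genes)
    np.add.at(lsum, inverse, lens)
    mean_len = (lsum / nper)[:, None]
    with np.errstate(invalid="ignore", divide="ignore"):
        eff = np.where(wsum > 0, wl / np.where(wsum > 0, wsum, 1.0), mean_len)

    idx = pd.Index(gene_ids, name="gene_id")
    return GeneCounts(
        counts=pd.DataFrame(counts, index=idx, columns=samples),
        lengths=pd.DataFrame(eff, index=idx, columns=samples),
    )


def size_factors(gc: GeneCounts | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    The reference profile is the per-gene geometric mean over samples,
    using only genes with strictly positive counts in every sample; the
    raw factor for sample j is the median ratio count_gj / reference_g.
    """
    counts = gc.counts if isinstance(gc, GeneCounts) else gc
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; pre-filter low-count genes"
        )
    logm = np.log(mat[allpos])
    ref = logm.mean(axis=1)  # log geometric mean
    s = np.exp(np.median(logm - ref[:, None], axis=0))
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.columns, name="size_factor")


def filter_genes(
    gc: GeneCounts,
    sf: pd.Series,
    min_count: float = 10.0,
    min_samples: int = 8,
) -> GeneCounts:
    """Keep genes with >= ``min_count`` normalised counts in >= ``min_samples``
    samples; gene order preserved."""
    if min_samples > gc.counts.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds sample count {gc.counts.shape[1]}"
        )
    norm = gc.counts.to_numpy() / sf.reindex(gc.samples).to_numpy()[None, :]
    keep = (norm >= min_count).sum(axis=1) >= min_samples
    return gc.subset(gc.genes[keep])


def vst(gc: GeneCounts | pd.DataFrame, sf: pd.Series) -> pd.DataFrame:
    """Shifted-log transform of normalised counts: log2(count/s + 1)."""
    counts = gc.counts if isinstance(gc, GeneCounts) else gc
    norm = counts.to_numpy(dtype=float) / sf.reindex(counts.columns).to_numpy()[None, :]
    return pd.DataFrame(np.log2(norm + 1.0), index=counts.index, columns=counts.columns)
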