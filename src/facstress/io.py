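"""TSV dialects used across the pipeline (UTF-8, tab-separated, header row)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_transcripts(tx: pd.DataFrame, path) -> None:
    tx.to_csv(path, sep="\t", index=False)


def read_transcripts(path) -> pd.DataFrame:
    tx = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "gene_id", "effective_length"}
    if not required <= set(tx.columns):
        raise ValueError(f"transcript TSV lacks columns {required - set(tx.columns)}")
    return tx


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=True, index_label="sample_id")


def read_design(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_table(df: pd.DataFrame, path, index: bool = True, **kw) -> None:
    df.to_csv(path, sep="\t", index=index, **kw)


def read_table(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def read_annotations(gene_term_path, edges_path):
    """Read gene->term annotations and child->parent DAG edges.

    ``gene_term_path``: TSV with columns gene, term.
    ``edges_path``: TSV with columns child, parent.
    Returns (annotations dict term -> set of genes, edge list).
    """
    gt = pd.read_csv(gene_term_path, sep="\t")
    ed = pd.read_csv(edges_path, sep="\t")
    ann: dict[str, set] = {}
    for gene, term in gt.itertuples(index=False):
        ann.setdefault(str(term), set()).add(str(gene))
    edges = [(str(c), str(p)) for c, p in ed.itertuples(index=False)]
    return ann, edges


def write_intersections(partition: pd.DataFrame, path) -> None:
    out = partition.copy()
    out["genes"] = out["genes"].map(",".join)
    out.to_csv(path, sep="\t", index=False)


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
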