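"""Seeded, logged orchestration of the full analysis chain.

simulate (or load) -> preprocess/fit -> interactions -> profiles ->
enrichment -> report.  Every stage writes its artifact as TSV; a
``manifest.json`` records the configuration, seed, package version and
per-stage row counts, and is bit-identical across runs with the same
config and seed.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io
from .enrichment import OntologyDAG, propagate_annotations
from .model import StressFactorialModel
from .simulate import DesignSpec, EffectConfig, simulate_dataset

log = logging.getLogger("facstress")


@dataclass
class RunConfig:
    """Validated configuration of a pipeline run."""

    seed: int = 0
    # simulation inputs (used when counts_path is None)
    n_genes: int = 2000
    replicates_per_cell: int = 8
    # or real inputs
    counts_path: str | None = None
    design_path: str | None = None
    annotations_path: str | None = None
    dag_path: str | None = None
    # thresholds
    fdr: float = 0.1
    min_count: float = 10.0
    min_samples: int = 8
    min_cluster: int = 10
    alpha_elim: float = 0.01
    sv_alpha: float = 0.05
    n_perm: int = 100
    # stage toggles
    run_interactions: bool = True
    run_profiles: bool = True
    run_enrichment: bool = True
    enrich_term: str = "Salinity"

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, lo, hi in [
            ("fdr", 0, 1), ("alpha_elim", 0, 1), ("sv_alpha", 0, 1),
        ]:
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.min_cluster < 2:
            raise ValueError("min_cluster must be >= 2")
        n_samples = (
            self.replicates_per_cell * 8 if self.counts_path is None else None
        )
        if n_samples is not None and self.min_samples > n_samples:
            raise ValueError(
                f"min_samples={self.min_samples} exceeds sample count {n_samples}"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s [%(name)s] %(message)s")
    for h in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "run.log")):
        h.setFormatter(fmt)
        log.addHandler(h)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages; returns the result bundle.

    Any stage failure writes a ``FAILED`` marker naming the stage and
    re-raises; artifacts of completed stages are preserved.
    """
    config.validate()
    out = io.ensure_dir(outdir)
    _setup_logging(out)
    bundle: dict = {"config": config}
    counts: dict[str, int] = {}
    stage = "setup"
    try:
        if config.counts_path is None:
            stage = "simulate"
            log.info("stage %s: %d genes, seed %d", stage, config.n_genes, config.seed)
            design, truth, tx, sf = simulate_dataset(
                n_genes=config.n_genes,
                spec=DesignSpec(replicates_per_cell=config.replicates_per_cell),
                seed=config.seed,
            )
            io.write_transcripts(tx, out / "transcripts.tsv")
            io.write_design(design, out / "design.tsv")
            io.write_table(truth, out / "truth.tsv")
            bundle["truth"] = truth
            counts["simulate_transcripts"] = len(tx)
        else:
            stage = "load"
            log.info("stage %s: %s", stage, config.counts_path)
            tx = io.read_transcripts(config.counts_path)
            design = io.read_design(config.design_path)
            counts["load_transcripts"] = len(tx)

        stage = "fit"
        model = StressFactorialModel.from_transcripts(
            tx, design, min_count=config.min_count, min_samples=config.min_samples
        )
        res = model.fit(
            fdr=config.fdr, n_perm=config.n_perm, sv_alpha=config.sv_alpha,
            seed=config.seed,
        )
        log.info("stage %s: %d genes tested, k=%d surrogates", stage, len(res.genes), res.surrogates.k)
        bundle["results"] = res
        io.write_table(res.results_frame(), out / "results.tsv", index=False)
        io.write_table(res.surrogates.values, out / "surrogates.tsv")
        io.write_table(
            pd.DataFrame({"gene_id": res.genes}), out / "filtered_genes.tsv", index=False
        )
        counts["fit_genes"] = len(res.genes)
        counts["surrogates"] = res.surrogates.k

        if config.run_interactions:
            stage = "interactions"
            calls = res.interaction_calls()
            io.write_table(calls, out / "interaction_calls.tsv", index=False)
            io.write_table(res.interaction_table(), out / "interaction_table.tsv")
            for direction in ("up", "down"):
                io.write_intersections(
                    res.exclusive_intersections(direction),
                    out / f"intersections_{direction}.tsv",
                )
            counts["interaction_calls"] = len(calls)
            log.info("stage %s: %d calls", stage, len(calls))

        if config.run_profiles:
            stage = "profiles"
            clustering = res.cluster_interaction_profiles(
                min_size=config.min_cluster, seed=config.seed
            )
            io.write_table(clustering.assignments.to_frame(), out / "clusters.tsv")
            io.write_table(clustering.cluster_means, out / "cluster_means.tsv")
            bundle["clustering"] = clustering
            counts["clusters"] = clustering.n_clusters
            log.info("stage %s: %d clusters", stage, clustering.n_clusters)

        if config.run_enrichment and config.annotations_path and config.dag_path:
            stage = "enrichment"
            ann, edges = io.read_annotations(config.annotations_path, config.dag_path)
            dag = propagate_annotations(OntologyDAG.from_edges(edges, ann))
            for direction in ("up", "down"):
                enr = res.enrich(
                    dag, config.enrich_term, direction, alpha_elim=config.alpha_elim
                )
                io.write_table(enr, out / f"enrichment_{config.enrich_term}_{direction}.tsv", index=False)
                bundle[f"enrichment_{direction}"] = enr
            counts["enrichment_terms"] = len(bundle["enrichment_up"])
            log.info("stage %s: %d terms", stage, counts["enrichment_terms"])

        stage = "report"
        manifest = {
            "config": {k: v for k, v in asdict(config).items()},
            "seed": config.seed,
            "version": __version__,
            "stage_counts": counts,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        bundle["manifest"] = manifest
        report = summarise_run(bundle)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        bundle["report"] = report
        return bundle
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def summarise_run(bundle: dict) -> dict:
    """Machine-readable run report: DE counts per treatment, interaction
    class table, intersections, cluster summary, top enriched terms.
    Missing stages are marked skipped, never silently omitted."""
    report: dict = {}
    res = bundle.get("results")
    if res is None:
        return {"fit": "stage skipped"}
    report["n_genes_tested"] = int(len(res.genes))
    report["n_surrogates"] = int(res.surrogates.k)
    report["de_counts"] = {
        t: {"up": len(res.de_genes(t, "up")), "down": len(res.de_genes(t, "down"))}
        for t in res.factorial_terms
    }
    tab = res.interaction_table()
    report["interaction_table"] = {
        cls: {combo: int(tab.at[cls, combo]) for combo in tab.columns}
        for cls in tab.index
    }
    inter = res.exclusive_intersections()
    report["exclusive_intersections"] = {
        sig: int(n) for sig, n in zip(inter["signature"], inter["count"])
    }
    if "clustering" in bundle:
        cl = bundle["clustering"]
        report["clusters"] = {
            "n_clusters": int(cl.n_clusters),
            "sizes": {str(cid): len(m) for cid, m in cl.members.items()},
            "n_unassigned": int(len(cl.unassigned)),
        }
    else:
        report["clusters"] = "stage skipped"
    for direction in ("up", "down"):
        key = f"enrichment_{direction}"
        if key in bundle:
            top = bundle[key].nsmallest(5, "p_elim")
            report[key] = [
                {"term": r.term, "p_elim": float(r.p_elim)} for r in top.itertuples()
            ]
        else:
            report[key] = "stage skipped"
    return report


def format_report(report: dict) -> str:
    lines = ["facstress run report", "=" * 40]
    for key, val in report.items():
        lines.append(f"{key}: {json.dumps(val, sort_keys=True) if isinstance(val, (dict, list)) else val}")
    return "\n".join(lines)
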