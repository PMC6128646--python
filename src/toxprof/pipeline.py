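"""End-to-end reproducible pipeline over the synthetic screen.

Ties the stages together: simulate a pooled screen -> count -> GI score ->
robust-z / tail-FDR calls -> term enrichment of the hits -> two-dimensional
clustering of the GI matrix, writing every table, tree and a recovery
report into one run directory together with the fully-resolved
configuration and a structured log. Runs are idempotent given an identical
config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import cluster_bidimensional, to_newick, write_cluster3
from .enrichment import enrich_terms, write_gmt
from .fitness import call_sensitive, classify_expressivity, score_screen
from .synthetic import PlantedTerm, PoolSimConfig, simulate_annotations, simulate_screen_counts

logger = logging.getLogger("toxprof")

#: fields a config file must state explicitly — growth depth and seed drive
#: everything downstream, so silent defaults are not accepted for them
REQUIRED_FIELDS = ("pool_doublings", "seed")


@dataclass
class PipelineConfig:
    """Fully-resolved parameters of one synthetic screen run."""

    pool_doublings: float = 5.0
    seed: int = 0
    n_mutants: int = 2000
    n_sensitive: int = 30
    sensitive_rho: float = 0.5
    depth: int = 2_000_000
    n_screens: int = 2
    rho_jitter_sigma: float = 0.02
    pseudocount: float = 0.5
    pi0: float = 1.0
    fdr_cutoff: float = 0.1
    n_terms: int = 50
    term_size_range: tuple = (5, 50)
    def __post_init__(self):
        if self.n_sensitive > self.n_mutants:
            raise ValueError("n_sensitive cannot exceed n_mutants")
        if not (0 < self.fdr_cutoff < 1):
            raise ValueError("fdr_cutoff must lie in (0, 1)")

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        for name in REQUIRED_FIELDS:
            if name not in mapping:
                raise ValueError(f"config is missing required field: {name}")
        unknown = set(mapping) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        mapping = dict(mapping)
        if "term_size_range" in mapping:
            mapping["term_size_range"] = tuple(mapping["term_size_range"])
        return cls(**mapping)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            with open(path) as fh:
                data = yaml.safe_load(fh)
        elif path.suffix == ".toml":
            import tomllib

            with open(path, "rb") as fh:
                data = tomllib.load(fh)
        else:
            raise ValueError(f"unsupported config format: {path.suffix}")
        return cls.from_mapping(data or {})


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute simulate -> score -> call -> enrich -> cluster into ``outdir``.

    Returns a dict of output paths. Never overwrites its inputs; refuses a
    run directory that already holds a provenance file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if (outdir / "provenance.yaml").exists():
        raise FileExistsError(f"{outdir} already holds a completed run")
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    paths: dict[str, Path] = {}
    try:
        rng = np.random.default_rng(config.seed)
        width = len(str(config.n_mutants))
        mutants = [f"mut{i + 1:0{width}d}" for i in range(config.n_mutants)]
        genes = [f"gene{i + 1:0{width}d}" for i in range(config.n_mutants)]
        rho = np.ones(config.n_mutants)
        sensitive_idx = rng.choice(config.n_mutants, size=config.n_sensitive, replace=False)
        rho[sensitive_idx] = config.sensitive_rho
        truth = pd.DataFrame({"mutant_id": mutants, "gene": genes, "rho": rho})
        truth["planted_sensitive"] = rho < 1
        paths["truth"] = outdir / "truth.tsv"
        truth.to_csv(paths["truth"], sep="\t", index=False)
        logger.info("simulated pool: %d mutants, %d planted sensitive", config.n_mutants, config.n_sensitive)

        pool = PoolSimConfig(
            n_mutants=config.n_mutants,
            relative_growth_rates=rho,
            pool_doublings=config.pool_doublings,
        )
        q_cols = {}
        gi_cols = {}
        for s in range(config.n_screens):
            ctrl, trt = simulate_screen_counts(
                pool, config.depth, rng, rho_jitter_sigma=config.rho_jitter_sigma
            )
            scores = score_screen(
                ctrl,
                trt,
                doublings=config.pool_doublings,
                pseudocount=config.pseudocount,
                pi0=config.pi0,
                index=mutants,
                screen_id=f"screen{s + 1}",
            )
            p = outdir / f"scores_screen{s + 1}.tsv"
            scores.rename_axis("mutant_id").to_csv(p, sep="\t", float_format="%.10g")
            paths[f"scores_screen{s + 1}"] = p
            q_cols[f"screen{s + 1}"] = scores["q"]
            gi_cols[f"screen{s + 1}"] = scores["gi"]
            logger.info("screen %d scored: %d mutants at depth %d", s + 1, config.n_mutants, config.depth)

        q_df = pd.DataFrame(q_cols)
        gi_df = pd.DataFrame(gi_cols)
        calls = call_sensitive(q_df, cutoff=config.fdr_cutoff, rule="both")
        calls["expressivity"] = classify_expressivity(calls, gi_df.mean(axis=1))
        paths["calls"] = outdir / "calls.tsv"
        calls.rename_axis("mutant_id").to_csv(paths["calls"], sep="\t", float_format="%.10g")
        called = calls.index[calls["selected"]]
        logger.info("calls: %d selected at FDR %.2f", len(called), config.fdr_cutoff)

        # enrichment: random terms plus one planted from the true sensitives
        gene_of = dict(zip(mutants, genes))
        planted_genes = tuple(gene_of[mutants[i]] for i in sorted(sensitive_idx))
        planted = PlantedTerm(
            term_id="planted_sensitivity",
            list_genes=planted_genes,
            overlap=min(len(planted_genes), 8),
            term_size=max(9, min(len(planted_genes), 8) + 1),
        )
        annotations = simulate_annotations(
            genes,
            n_terms=config.n_terms,
            term_size_range=config.term_size_range,
            planted_term=planted,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        paths["annotations"] = outdir / "annotations.gmt"
        write_gmt(annotations, paths["annotations"])
        hit_genes = [gene_of[m] for m in called]
        if hit_genes:
            enr = enrich_terms(hit_genes, annotations)
            paths["enrichment"] = outdir / "enrichment.tsv"
            enr.to_csv(paths["enrichment"], sep="\t", index=False, float_format="%.6g")
            logger.info("enrichment: %d/%d terms significant", int(enr["significant"].sum()), len(enr))
        else:
            logger.warning("no mutants called; enrichment skipped")

        # cluster the called mutants' GI profiles (top scorers if too few)
        rows = list(called) if len(called) >= 2 else list(gi_df.mean(axis=1).nlargest(20).index)
        if gi_df.shape[1] >= 1 and len(rows) >= 2:
            result = cluster_bidimensional(gi_df.loc[rows])
            paths.update(write_cluster3(result, outdir / "gi_cluster"))
            (outdir / "gi_cluster_rows.nwk").write_text(to_newick(result.row_tree) + "\n")
            paths["row_newick"] = outdir / "gi_cluster_rows.nwk"
            if result.col_tree.n_leaves > 1:
                (outdir / "gi_cluster_cols.nwk").write_text(to_newick(result.col_tree) + "\n")
                paths["col_newick"] = outdir / "gi_cluster_cols.nwk"
            logger.info("clustered %d mutants x %d screens", len(rows), gi_df.shape[1])

        truth_set = set(truth.loc[truth["planted_sensitive"], "mutant_id"])
        called_set = set(called)
        recovered = len(truth_set & called_set)
        report = {
            "n_mutants": config.n_mutants,
            "n_planted": len(truth_set),
            "n_called": len(called_set),
            "n_recovered": recovered,
            "recall": recovered / len(truth_set) if truth_set else None,
            "false_positives": len(called_set - truth_set),
        }
        paths["recovery"] = outdir / "recovery.json"
        with open(paths["recovery"], "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info("recovery: %s", report)

        resolved = asdict(config)
        resolved["term_size_range"] = list(config.term_size_range)
        digest = hashlib.sha256(
            json.dumps(resolved, sort_keys=True).encode()
        ).hexdigest()[:16]
        provenance = {
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "config_hash": digest,
            "config": resolved,
        }
        paths["provenance"] = outdir / "provenance.yaml"
        with open(paths["provenance"], "w") as fh:
            yaml.safe_dump(provenance, fh, sort_keys=False)
        return {k: str(v) for k, v in paths.items()}
    except Exception:
        logger.exception("pipeline failed; partial outputs preserved in %s", outdir)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
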