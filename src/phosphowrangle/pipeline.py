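"""End-to-end pipeline runner driven by a YAML/JSON config.

Wires the stages (simulate/ingest -> dissimilarity -> embed -> cluster ->
evaluate -> wrangle -> network) into one run that writes each stage's
standard output format plus a provenance JSON (parameters, derived seed,
input hashes).  One global seed fans out deterministically to per-stage
seeds, so a rerun with the same config reproduces every artifact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dissimilarity as dmod
from . import evaluate as emod
from . import ingest as imod
from . import network as nmod
from . import synthetic as smod
from .embed_cluster import EmbeddingConfig, classical_mds, kmeans_cluster, mst_cluster, tsne_embed
from .matrix import PhosphoMatrix, read_matrix, write_matrix
from .wrangle import FilterRules, combine_clusters, filter_cluster

__all__ = ["run_pipeline", "derive_seed"]


def derive_seed(global_seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(np.random.SeedSequence([global_seed, stage_index]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _provenance(outdir: Path, stage: str, params: dict, inputs: list[Path]) -> None:
    prov = {
        "stage": stage,
        "params": params,
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
    }
    (outdir / f"{stage}.provenance.json").write_text(json.dumps(prov, indent=1, default=str))


def _require(config: dict, stage: str, key: str):
    if key not in config:
        raise ValueError(f"config stage {stage!r}: missing required key {key!r}")
    return config[key]


def run_pipeline(config_file: str | Path, outdir: str | Path) -> Path:
    """Run the configured stages, writing artifacts into ``outdir``.

    The config is a mapping with an optional global ``seed`` and one
    section per stage; stages present in the config are run in pipeline
    order.  A stage failure raises with the stage name.
    """
    config_file = Path(config_file)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = yaml.safe_load(config_file.read_text())
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of stage sections")
    seed = int(cfg.get("seed", 0))

    matrix: PhosphoMatrix | None = None
    truth = None

    try:
        stage = "simulate"
        if stage in cfg:
            sc = dict(cfg[stage] or {})
            sc.setdefault("seed", derive_seed(seed, 0))
            sim_cfg = smod.SimulationConfig(**sc)
            matrix, truth = smod.simulate_phospho_matrix(sim_cfg)
            write_matrix(matrix, outdir / "matrix.tsv")
            truth.to_csv(outdir / "truth.tsv", sep="\t")
            _provenance(outdir, stage, sc, [config_file])

        stage = "ingest"
        if stage in cfg:
            sc = dict(cfg[stage])
            spectrum = Path(_require(sc, stage, "spectrum"))
            records = imod.parse_spectrum_table(
                spectrum,
                protein_col=sc.get("protein_col", "protein"),
                sample_col=sc.get("sample_col", "sample"),
                count_col=sc.get("count_col", "count"),
            )
            if "mapping" in sc:
                gene_map = imod.read_gene_map(sc["mapping"])
                records = imod.map_gene_symbols(
                    records, gene_map, policy=sc.get("policy", "passthrough")
                )
            matrix = imod.build_matrix(records)
            write_matrix(matrix, outdir / "matrix.tsv")
            (outdir / "matrix.summary.json").write_text(json.dumps(matrix.summary(), indent=1))
            _provenance(outdir, stage, sc, [spectrum])

        if matrix is None and "matrix" in cfg:
            matrix = read_matrix(cfg["matrix"])

        stage = "dissim"
        D = None
        if stage in cfg:
            if matrix is None:
                raise ValueError("dissim stage needs a matrix (simulate/ingest/matrix)")
            sc = dict(cfg[stage] or {})
            method = sc.get("method", "sed")
            policy = sc.get("missing_policy", "pairwise")
            fill = float(sc.get("fill_factor", 100.0))
            if method == "sed":
                D = dmod.sed(
                    matrix,
                    corr_method=sc.get("corr_method", "spearman"),
                    min_overlap=int(sc.get("min_overlap", 2)),
                    missing_policy=policy,
                    fill_factor=fill,
                )
            elif method in ("pearson", "spearman"):
                D = dmod.fill_missing_distances(
                    dmod.correlation_distance(
                        matrix, method,
                        min_overlap=int(sc.get("min_overlap", 2)),
                        missing_policy=policy,
                    ),
                    fill,
                )
            elif method == "euclidean":
                D = dmod.fill_missing_distances(
                    dmod.euclidean_distance(matrix, missing_policy=policy), fill
                )
            else:
                raise ValueError(f"unknown dissimilarity method {method!r}")
            dmod.write_dissimilarity(D, outdir / "dissimilarity.tsv")
            _provenance(outdir, stage, sc, [outdir / "matrix.tsv"])

        stage = "embed"
        embedding = None
        if stage in cfg:
            if D is None:
                raise ValueError("embed stage needs a dissimilarity matrix")
            sc = dict(cfg[stage] or {})
            method = sc.get("method", "tsne")
            k = int(sc.get("k", 2))
            if method == "tsne":
                ecfg = EmbeddingConfig(
                    method="tsne",
                    k=k,
                    perplexity=float(sc.get("perplexity", 30.0)),
                    initial_dims=int(sc.get("initial_dims", 30)),
                    max_iter=int(sc.get("max_iter", 1000)),
                    whiten=bool(sc.get("whiten", True)),
                    seed=int(sc.get("seed", derive_seed(seed, 2))),
                )
                embedding = tsne_embed(D, ecfg)
            elif method == "mds":
                embedding = classical_mds(D, k)
            else:
                raise ValueError(f"unknown embedding method {method!r}")
            embedding.coords.to_csv(outdir / "embedding.tsv", sep="\t", index_label="gene")
            _provenance(outdir, stage, sc, [outdir / "dissimilarity.tsv"])

        stage = "cluster"
        cluster_set = None
        if stage in cfg:
            sc = dict(cfg[stage] or {})
            method = sc.get("method", "mst")
            if method == "mst":
                if embedding is None:
                    raise ValueError("mst clustering needs an embedding")
                if "target_k" in sc:
                    cluster_set = mst_cluster(
                        embedding, "target_k", target_k=int(sc["target_k"])
                    )
                else:
                    cluster_set = mst_cluster(
                        embedding, "radius", radius=float(sc.get("radius", 3.5))
                    )
            elif method == "kmeans":
                if D is None:
                    raise ValueError("kmeans needs the dissimilarity feature matrix")
                cluster_set = kmeans_cluster(
                    D,
                    int(sc.get("k", 100)),
                    seed=int(sc.get("seed", derive_seed(seed, 3))),
                    n_restarts=int(sc.get("n_restarts", 10)),
                )
            else:
                raise ValueError(f"unknown clustering method {method!r}")
            cluster_set.assignments.to_csv(
                outdir / "clusters.tsv", sep="\t", index_label="gene", header=["cluster"]
            )
            _provenance(outdir, stage, sc, [outdir / "embedding.tsv"])

        stage = "evaluate"
        if stage in cfg and cluster_set is not None:
            sc = dict(cfg[stage] or {})
            table, summary = emod.rank_clusters(matrix, cluster_set)
            table.to_csv(outdir / "evaluation.tsv", sep="\t", index=False)
            (outdir / "evaluation.summary.json").write_text(json.dumps(summary, indent=1))
            _provenance(outdir, stage, sc, [outdir / "clusters.tsv"])

        stage = "wrangle"
        wrangled_genes = None
        if stage in cfg and cluster_set is not None:
            sc = dict(cfg[stage] or {})
            cluster_ids = sc.get("clusters")
            if cluster_ids is None:
                raise ValueError("config stage 'wrangle': missing required key 'clusters'")
            sets = [set(cluster_set.members(int(c))) for c in cluster_ids]
            union, provenance = (
                combine_clusters(*sets) if len(sets) > 1 else (sets[0], {})
            )
            rules = FilterRules(
                anchor=sc.get("anchor"),
                min_gene_occurrence=sc.get("min_gene_occurrence"),
                drop_single_sample_genes=bool(sc.get("drop_single_sample_genes", False)),
                drop_single_gene_samples=bool(sc.get("drop_single_gene_samples", False)),
                keep_pattern_conformers=bool(sc.get("keep_pattern_conformers", False)),
            )
            genes_f, samples_f = filter_cluster(matrix, union, rules)
            wrangled_genes = genes_f
            out = {
                "genes": sorted(genes_f),
                "samples": sorted(samples_f),
                "combined_from": {g: p for g, p in provenance.items()},
            }
            (outdir / "wrangled.json").write_text(json.dumps(out, indent=1))
            _provenance(outdir, stage, sc, [outdir / "clusters.tsv"])

        stage = "network"
        if stage in cfg:
            sc = dict(cfg[stage] or {})
            records = []
            for f in sc.get("edges", []):
                records.extend(nmod.read_edge_table(f))
            if not records and truth is not None:
                records, _ = smod.simulate_interaction_network(
                    truth, seed=derive_seed(seed, 6)
                )
            merged = nmod.merge_edges(records, psp_weight=float(sc.get("psp_weight", 0.25)))
            tp = matrix.total_phosphorylation() if matrix is not None else None
            nmod.export_network(
                merged, outdir / "network.graphml", "graphml", total_phosphorylation=tp
            )
            genes = wrangled_genes
            if genes is None and cluster_set is not None and cluster_set.n_clusters:
                genes = set(cluster_set.members(1))
            if genes:
                universe = sorted(matrix.genes) if matrix is not None else sorted(merged.nodes)
                bg = nmod.random_background(
                    merged,
                    universe,
                    size_min=int(sc.get("size_min", 11)),
                    size_max=int(min(sc.get("size_max", 34), len(universe))),
                    reps_per_size=int(sc.get("reps_per_size", 2)),
                    seed=int(sc.get("seed", derive_seed(seed, 7))),
                )
                enrich = nmod.cluster_network_enrichment(genes, merged, bg)
                genes_in_net = set(genes) & merged.undirected.nodes
                if len(genes_in_net) >= 2:
                    enrich["expected_edges"] = nmod.expected_edges(
                        genes_in_net, merged, model=sc.get("expected_model", "density")
                    )
                (outdir / "network.enrichment.json").write_text(
                    json.dumps(enrich, indent=1)
                )
            _provenance(outdir, stage, sc, [])
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return outdir
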