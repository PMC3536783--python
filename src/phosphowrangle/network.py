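"""Interaction-evidence merging, random backgrounds, and GO enrichment.

Protein-protein interaction evidence from several databases is merged so
each gene pair carries a single undirected edge whose weight is the total
evidence for interaction; kinase-substrate records are kept as a separate
directed edge class with a small fixed weight.  Clusters are judged
against this external evidence by (a) fold enrichment of induced edges
and edge weight over random gene-set backgrounds, (b) observed minus
expected edge counts under a null model of the whole network, and (c)
hypergeometric over-representation of GO terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
from scipy.stats import hypergeom

__all__ = [
    "EdgeRecord",
    "MergedNetwork",
    "BackgroundStats",
    "AnnotationTable",
    "EnrichmentResult",
    "read_edge_table",
    "merge_edges",
    "random_background",
    "cluster_network_enrichment",
    "expected_edges",
    "go_overrepresentation",
    "export_network",
]

PSP_WEIGHT_DEFAULT = 0.25  # fixed evidence weight of a kinase-substrate edge


@dataclass(frozen=True)
class EdgeRecord:
    """One raw interaction-evidence row from a database export."""

    source: str
    target: str
    weight: float
    evidence: str = ""
    database: str = ""
    directed: bool = False

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValueError("source and target must be non-empty")
        if not np.isfinite(self.weight) or self.weight < 0:
            raise ValueError(f"weight must be finite and >= 0, got {self.weight}")


def read_edge_table(path: str | Path, *, database: str | None = None) -> list[EdgeRecord]:
    """Read a TSV edge table: source, target, weight[, evidence, database, directed]."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    for need in ("source", "target", "weight"):
        if need not in cols:
            raise ValueError(f"{path}: missing column {need!r}")
    records = []
    for _, row in df.iterrows():
        directed = bool(row[cols["directed"]]) if "directed" in cols else False
        records.append(
            EdgeRecord(
                source=str(row[cols["source"]]),
                target=str(row[cols["target"]]),
                weight=float(row[cols["weight"]]),
                evidence=str(row[cols["evidence"]]) if "evidence" in cols else "",
                database=database or (str(row[cols["database"]]) if "database" in cols else ""),
                directed=directed,
            )
        )
    return records


@dataclass
class MergedNetwork:
    """Merged interaction evidence: undirected summed edges + directed KS edges."""

    undirected: nx.Graph
    directed: nx.DiGraph

    @property
    def nodes(self) -> set[str]:
        return set(self.undirected.nodes) | set(self.directed.nodes)

    def total_weight(self) -> float:
        w = sum(d["weight"] for _, _, d in self.undirected.edges(data=True))
        w += sum(d["weight"] for _, _, d in self.directed.edges(data=True))
        return float(w)

    def n_edges(self) -> int:
        return self.undirected.number_of_edges() + self.directed.number_of_edges()

    def pair_evidence(self, a: str, b: str) -> float:
        """Total evidence for a pair: undirected sum + directed weight(s)."""
        w = 0.0
        if self.undirected.has_edge(a, b):
            w += self.undirected[a][b]["weight"]
        for u, v in ((a, b), (b, a)):
            if self.directed.has_edge(u, v):
                w += self.directed[u][v]["weight"]
        return w

    def induced(self, genes) -> tuple[int, float]:
        """(edge count, total weight) induced by a gene set (both classes)."""
        gs = set(genes)
        n_edges = 0
        weight = 0.0
        for u, v, d in self.undirected.edges(data=True):
            if u in gs and v in gs:
                n_edges += 1
                weight += d["weight"]
        for u, v, d in self.directed.edges(data=True):
            if u in gs and v in gs:
                n_edges += 1
                weight += d["weight"]
        return n_edges, weight


def merge_edges(records, psp_weight: float = PSP_WEIGHT_DEFAULT) -> MergedNetwork:
    """Merge raw evidence rows into single edges per pair.

    Undirected rows for the same unordered pair are summed into one edge
    (contributing databases recorded).  Each directed (kinase-substrate)
    row becomes a directed edge valued at ``psp_weight`` — a fixed nominal
    weight that keeps these edges visible next to quantitative PPI scores
    — kept as a separate class, summed over duplicate ordered pairs.
    Self-loops are rejected.  The merge is order-invariant and conserves
    total weight (with each directed record valued at ``psp_weight``).
    """
    und = nx.Graph()
    dir_ = nx.DiGraph()
    for rec in records:
        if rec.source == rec.target:
            raise ValueError(f"self-loop not allowed: {rec.source}")
        if rec.directed:
            u, v = rec.source, rec.target
            if dir_.has_edge(u, v):
                dir_[u][v]["weight"] += psp_weight
            else:
                dir_.add_edge(u, v, weight=psp_weight, interaction="kinase-substrate")
        else:
            a, b = sorted((rec.source, rec.target))
            if und.has_edge(a, b):
                und[a][b]["weight"] += rec.weight
                und[a][b]["databases"] = ",".join(
                    sorted(set(und[a][b]["databases"].split(",")) | {rec.database})
                )
            else:
                und.add_edge(a, b, weight=rec.weight, databases=rec.database,
                             interaction="pp")
    return MergedNetwork(undirected=und, directed=dir_)


@dataclass(frozen=True)
class BackgroundStats:
    """Random gene-set baseline for edge counts and weights."""

    size_min: int
    size_max: int
    reps_per_size: int
    seed: int
    mean_edges_per_node: float
    sd_edges_per_node: float
    mean_weight_per_node: float
    sd_weight_per_node: float
    mean_go_terms_per_gene: float | None = None
    sd_go_terms_per_gene: float | None = None
    n_sets: int = 0


def random_background(
    network: MergedNetwork,
    universe,
    *,
    size_min: int = 11,
    size_max: int = 34,
    reps_per_size: int = 2,
    seed: int = 0,
    annotation: "AnnotationTable | None" = None,
    alpha: float = 0.01,
    min_genes: int = 2,
) -> BackgroundStats:
    """Edge/weight (and optionally GO) background from random gene sets.

    For each size in ``[size_min, size_max]``, ``reps_per_size`` gene sets
    are drawn without replacement from the universe (defaults give 24
    sizes x 2 = 48 sets); for each set the induced edges per node and
    induced weight per node are recorded, and the mean and sample sd over
    all sets reported.  Genes with no edges are legitimate draws.
    """
    universe = sorted(set(universe))
    if size_max > len(universe):
        raise ValueError(f"size_max={size_max} exceeds universe size {len(universe)}")
    if size_min < 1 or size_min > size_max:
        raise ValueError("need 1 <= size_min <= size_max")
    rng = np.random.default_rng(seed)
    epn, wpn, gopg = [], [], []
    for size in range(size_min, size_max + 1):
        for _ in range(reps_per_size):
            genes = rng.choice(universe, size=size, replace=False)
            n_edges, weight = network.induced(genes)
            epn.append(n_edges / size)
            wpn.append(weight / size)
            if annotation is not None:
                res = go_overrepresentation(
                    set(genes) & set(annotation.universe), annotation,
                    alpha=alpha, min_genes=min_genes,
                )
                gopg.append(sum(r.retained for r in res) / size)
    epn, wpn = np.asarray(epn), np.asarray(wpn)
    kw = {}
    if annotation is not None:
        g = np.asarray(gopg)
        kw = {
            "mean_go_terms_per_gene": float(g.mean()),
            "sd_go_terms_per_gene": float(g.std(ddof=1)) if len(g) > 1 else 0.0,
        }
    return BackgroundStats(
        size_min=size_min,
        size_max=size_max,
        reps_per_size=reps_per_size,
        seed=seed,
        mean_edges_per_node=float(epn.mean()),
        sd_edges_per_node=float(epn.std(ddof=1)) if len(epn) > 1 else 0.0,
        mean_weight_per_node=float(wpn.mean()),
        sd_weight_per_node=float(wpn.std(ddof=1)) if len(wpn) > 1 else 0.0,
        n_sets=len(epn),
        **kw,
    )


def cluster_network_enrichment(
    cluster_genes, network: MergedNetwork, background: BackgroundStats
) -> dict:
    """Fold enrichment of a cluster's induced edges/weight over background."""
    genes = sorted(set(cluster_genes))
    if not genes:
        raise ValueError("cluster is empty")
    n = len(genes)
    n_edges, weight = network.induced(genes)
    out = {"edges_per_node": n_edges / n, "weight_per_node": weight / n}
    for key, obs, mean in (
        ("edge_fold", out["edges_per_node"], background.mean_edges_per_node),
        ("weight_fold", out["weight_per_node"], background.mean_weight_per_node),
    ):
        if mean > 0:
            out[key] = obs / mean
            out[key + "_undefined"] = False
        else:
            out[key] = float("inf") if obs > 0 else 0.0
            out[key + "_undefined"] = True
    return out


def expected_edges(
    cluster_genes, network: MergedNetwork, model: str = "density"
) -> dict:
    """Expected induced edge count for a gene set under a null model.

    ``density``: edges fall uniformly over all pairs — E_total *
    C(n,2)/C(N,2).  ``configuration``: degree-preserving null —
    sum over cluster pairs of k_i*k_j / (2*E_total).  Undirected merged
    edges only (degree-based nulls are not defined for the mixed classes).
    Reports observed and observed - expected alongside.
    """
    genes = sorted(set(cluster_genes))
    g = network.undirected
    unknown = set(genes) - set(g.nodes)
    if unknown:
        raise KeyError(f"cluster genes not in network: {sorted(unknown)}")
    N = g.number_of_nodes()
    if N < 2:
        raise ValueError("network must have at least 2 nodes")
    E = g.number_of_edges()
    n = len(genes)
    if model == "density":
        expected = E * (n * (n - 1) / 2.0) / (N * (N - 1) / 2.0)
    elif model == "configuration":
        if E == 0:
            expected = 0.0
        else:
            deg = dict(g.degree())
            ks = [deg[v] for v in genes]
            tot = sum(ks)
            expected = (tot * tot - sum(k * k for k in ks)) / 2.0 / (2.0 * E)
    else:
        raise ValueError("model must be 'density' or 'configuration'")
    observed = sum(1 for u, v in g.edges if u in set(genes) and v in set(genes))
    return {
        "expected": float(expected),
        "observed": int(observed),
        "excess": float(observed - expected),
        "model": model,
    }


@dataclass(frozen=True)
class AnnotationTable:
    """Gene -> GO term annotations over a fixed gene universe."""

    gene_terms: dict[str, frozenset[str]]
    term_names: dict[str, str]
    universe: tuple[str, ...]

    def __post_init__(self) -> None:
        uni = set(self.universe)
        stray = set(self.gene_terms) - uni
        if stray:
            raise ValueError(f"annotated genes outside the universe: {sorted(stray)[:5]}")

    @classmethod
    def from_tsv(cls, path: str | Path, universe=None) -> "AnnotationTable":
        """Load ``gene<TAB>term_id[<TAB>term_name]`` rows; universe defaults
        to the annotated genes."""
        gene_terms: dict[str, set[str]] = {}
        term_names: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected >= 2 columns")
                gene, term = parts[0].strip(), parts[1].strip()
                if lineno == 1 and term.lower() in {"term", "term_id"}:
                    continue
                gene_terms.setdefault(gene, set()).add(term)
                if len(parts) >= 3 and parts[2].strip():
                    term_names[term] = parts[2].strip()
        uni = tuple(sorted(universe)) if universe is not None else tuple(sorted(gene_terms))
        return cls(
            gene_terms={g: frozenset(t) for g, t in gene_terms.items()},
            term_names=term_names,
            universe=uni,
        )

    def term_members(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, terms in self.gene_terms.items():
            for t in terms:
                out.setdefault(t, set()).add(gene)
        return out


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    term_name: str
    cluster_hits: int
    universe_hits: int
    cluster_size: int
    universe_size: int
    p_value: float
    retained: bool


def go_overrepresentation(
    cluster_genes,
    annotation: AnnotationTable,
    *,
    alpha: float = 0.01,
    min_genes: int = 2,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of GO terms in a cluster.

    For each term the upper-tail probability P(X >= hits) of drawing the
    observed number of annotated genes in a cluster-sized sample from the
    universe is computed.  A term is retained iff p < alpha and at least
    ``min_genes`` cluster genes carry it (a single gene is membership, not
    enrichment).  P-values are raw by default; ``bh_correct`` applies
    Benjamini-Hochberg before thresholding.
    """
    cluster = sorted(set(cluster_genes))
    universe = set(annotation.universe)
    if not universe:
        raise ValueError("annotation universe is empty")
    stray = set(cluster) - universe
    if stray:
        raise KeyError(f"cluster genes outside universe: {sorted(stray)[:5]}")
    N = len(universe)
    n = len(cluster)
    results = []
    for term, members in sorted(annotation.term_members().items()):
        K = len(members)
        hits = len(members & set(cluster))
        if hits == 0:
            continue
        p = float(hypergeom.sf(hits - 1, N, K, n))
        results.append([term, annotation.term_names.get(term, ""), hits, K, p])
    if bh_correct and results:
        ps = np.array([r[4] for r in results])
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        running = 1.0
        for rank_i, idx in enumerate(order[::-1]):
            i = m - rank_i  # 1-based rank from largest p
            running = min(running, ps[idx] * m / i)
            adj[idx] = running
        for r, a in zip(results, adj):
            r[4] = float(a)
    out = [
        EnrichmentResult(
            term=term,
            term_name=name,
            cluster_hits=hits,
            universe_hits=K,
            cluster_size=n,
            universe_size=N,
            p_value=p,
            retained=bool(p < alpha and hits >= min_genes),
        )
        for term, name, hits, K, p in results
    ]
    out.sort(key=lambda r: (r.p_value, r.term))
    return out


def export_network(
    merged: MergedNetwork,
    path: str | Path,
    fmt: str = "graphml",
    *,
    total_phosphorylation: pd.Series | None = None,
) -> None:
    """Export a merged network as GraphML, SIF, or a TSV edge list.

    Output is deterministic (edges sorted).  When a per-gene total
    phosphorylation series is supplied it is attached as a node attribute
    (drives node size/colour in external viewers).
    """
    if merged.n_edges() == 0:
        raise ValueError("network is empty")
    path = Path(path)
    und = sorted(
        (min(u, v), max(u, v), d) for u, v, d in merged.undirected.edges(data=True)
    )
    dire = sorted((u, v, d) for u, v, d in merged.directed.edges(data=True))
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\tevidence\tdatabase\tdirected\n")
            for u, v, d in und:
                fh.write(
                    f"{u}\t{v}\t{d['weight']:.6g}\tpp\t{d.get('databases', '')}\tFalse\n"
                )
            for u, v, d in dire:
                fh.write(f"{u}\t{v}\t{d['weight']:.6g}\tkinase-substrate\t\tTrue\n")
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, _ in und:
                fh.write(f"{u}\tpp\t{v}\n")
            for u, v, _ in dire:
                fh.write(f"{u}\tks\t{v}\n")
    elif fmt == "graphml":
        g = nx.DiGraph()
        for u, v, d in und:
            g.add_edge(u, v, weight=float(d["weight"]), directed=False,
                       interaction="pp", databases=d.get("databases", ""))
        for u, v, d in dire:
            g.add_edge(u, v, weight=float(d["weight"]), directed=True,
                       interaction="kinase-substrate")
        if total_phosphorylation is not None:
            for node in g.nodes:
                if node in total_phosphorylation.index:
                    g.nodes[node]["total_phosphorylation"] = float(
                        total_phosphorylation[node]
                    )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
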