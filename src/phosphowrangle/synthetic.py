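"""Synthetic sparse phospho-matrices with planted co-observation clusters.

The generator emulates the structural features of tyrosine
phosphoproteomic spectrum-count tables that drive the clustering problem:
extreme sparsity (~95% of cells missing at the defaults), right-skewed
nonnegative counts, and groups of genes co-observed in shared sample
subsets (co-activated pathways).  Planted cluster labels are returned so
recovery can be scored, and a companion toy interaction network with
within-cluster edge enrichment exercises the external-evaluation stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import PhosphoMatrix
from .network import EdgeRecord

__all__ = [
    "SimulationConfig",
    "simulate_phospho_matrix",
    "simulate_interaction_network",
    "expected_missingness",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-cluster matrix generator.

    Defaults give a 300 x 60 matrix with 10 disjoint 12-gene clusters,
    each active in 8 samples, observed with probability 0.8 inside a
    planted block and 0.01 elsewhere — about 95% missing overall, the
    sparsity regime of real spectrum tables.  Counts are
    ceil(log-normal(mu, sigma)) >= 1, heavy-tailed like phosphopeptide
    totals.
    """

    n_genes: int = 300
    n_samples: int = 60
    n_clusters: int = 10
    genes_per_cluster: int = 12
    samples_per_cluster: int = 8
    p_obs_in: float = 0.8
    p_obs_bg: float = 0.01
    count_mu: float = 1.0
    count_sigma: float = 1.0
    sample_layout: str = "cyclic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_obs_bg <= 1.0 and 0.0 <= self.p_obs_in <= 1.0):
            raise ValueError("observation probabilities must lie in [0, 1]")
        if self.n_clusters * self.genes_per_cluster > self.n_genes:
            raise ValueError("planted gene blocks exceed n_genes (blocks are disjoint)")
        if self.samples_per_cluster > self.n_samples:
            raise ValueError("samples_per_cluster exceeds n_samples")
        if self.p_obs_in == 0.0 and self.p_obs_bg == 0.0:
            raise ValueError("parameters imply an empty matrix")
        if self.sample_layout not in {"cyclic", "random"}:
            raise ValueError("sample_layout must be 'cyclic' or 'random'")


def expected_missingness(config: SimulationConfig) -> float:
    """Closed-form expected percent of missing cells (before resampling)."""
    planted = config.n_clusters * config.genes_per_cluster * config.samples_per_cluster
    total = config.n_genes * config.n_samples
    expected_obs = planted * config.p_obs_in + (total - planted) * config.p_obs_bg
    return 100.0 * (1.0 - expected_obs / total)


def _gene_name(i: int, width: int) -> str:
    return f"G{i:0{width}d}"


def _sample_name(j: int, width: int) -> str:
    return f"S{j:0{width}d}"


def simulate_phospho_matrix(
    config: SimulationConfig | None = None,
) -> tuple[PhosphoMatrix, pd.Series]:
    """Draw a sparse count matrix with planted clusters.

    Returns the matrix and a gene -> planted-cluster-id Series (1..K for
    planted genes, 0 for background genes).  Genes whose Bernoulli draws
    came up all-missing are redrawn (so the matrix invariant holds);
    still-empty rows/columns after bounded redraws get one forced
    observation at the highest-probability cell.  Same seed, same matrix.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    G, S = config.n_genes, config.n_samples
    gw, sw = len(str(G)), len(str(S))
    genes = [_gene_name(i + 1, gw) for i in range(G)]
    samples = [_sample_name(j + 1, sw) for j in range(S)]

    prob = np.full((G, S), config.p_obs_bg)
    labels = np.zeros(G, dtype=int)
    # planted gene blocks are disjoint; sample blocks are as close to
    # disjoint as the arithmetic allows.  With the defaults 10 clusters x 8
    # samples exceed the 60 samples, so the cyclic layout staggers blocks at
    # even offsets over a random sample permutation: each cluster overlaps
    # only its two cyclic neighbours (distinct pathways sharing a couple of
    # tumour samples), never arbitrary cluster pairs.  'random' draws each
    # block independently instead.
    perm = rng.permutation(S)
    stride = S / config.n_clusters
    for c in range(config.n_clusters):
        rows = np.arange(c * config.genes_per_cluster, (c + 1) * config.genes_per_cluster)
        if config.sample_layout == "cyclic":
            cols = perm[(np.arange(config.samples_per_cluster) + int(round(c * stride))) % S]
        else:
            cols = rng.choice(S, size=config.samples_per_cluster, replace=False)
        prob[np.ix_(rows, cols)] = config.p_obs_in
        labels[rows] = c + 1

    mask = rng.random((G, S)) < prob
    # resample empty gene rows from the same row probabilities
    for i in range(G):
        tries = 0
        while not mask[i].any() and tries < 1000:
            mask[i] = rng.random(S) < prob[i]
            tries += 1
        if not mask[i].any():
            mask[i, int(prob[i].argmax())] = True
    # force an observation into any still-empty sample column
    for j in range(S):
        if not mask[:, j].any():
            mask[int(prob[:, j].argmax()), j] = True

    counts = np.ceil(rng.lognormal(config.count_mu, config.count_sigma, size=(G, S)))
    counts = np.maximum(counts, 1.0)
    values = np.where(mask, counts, np.nan)
    matrix = PhosphoMatrix(pd.DataFrame(values, index=genes, columns=samples))
    truth = pd.Series(labels, index=genes, name="cluster").sort_index()
    return matrix, truth


def simulate_interaction_network(
    labels: pd.Series,
    *,
    p_edge_in: float = 0.3,
    p_edge_bg: float = 0.005,
    weight_mu: float = -1.0,
    weight_sigma: float = 0.5,
    seed: int = 0,
) -> tuple[list[EdgeRecord], pd.DataFrame]:
    """Toy interaction network enriched within planted clusters.

    Every within-cluster gene pair receives an edge with probability
    ``p_edge_in``, every other pair with ``p_edge_bg``; weights are
    log-normal (positive, mostly below 1, like database evidence scores).
    Returns the edge records and a truth table of drawn edges with their
    within-cluster flag.
    """
    if not p_edge_in > p_edge_bg:
        raise ValueError("p_edge_in must exceed p_edge_bg")
    rng = np.random.default_rng(seed)
    genes = list(labels.index)
    records: list[EdgeRecord] = []
    truth_rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            gi, gj = genes[i], genes[j]
            within = labels[gi] != 0 and labels[gi] == labels[gj]
            p = p_edge_in if within else p_edge_bg
            if rng.random() < p:
                w = float(rng.lognormal(weight_mu, weight_sigma))
                records.append(
                    EdgeRecord(
                        source=gi, target=gj, weight=w,
                        evidence="simulated", database="synthetic",
                    )
                )
                truth_rows.append({"source": gi, "target": gj, "within": bool(within)})
    truth = pd.DataFrame(truth_rows, columns=["source", "target", "within"])
    return records, truth
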