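"""Per-cluster statistics, slope culling, and the cluster-quality Index.

A good cluster is dense in the primary data: its genes are observed in
many shared samples with strong signal.  The Index rewards total observed
signal, samples contributing more than a lone gene, and genes that follow
the cluster's overall expression pattern, and punishes missing cells::

    intensity   = total_signal - total_signal * percent_NA / 100
    cleargenes  = n_genes - genes_culled_by_slope
    realsamples = n_samples - n_samples * percent_single_gene_samples / 100
    Index       = intensity * (1 + realsamples) * (1 + cleargenes)
                  / (1 + percent_NA)

"Culled by slope" sorts the cluster's samples by decreasing total signal
and regresses each gene's values (missing as 0) on sample position; a
positive slope means the gene peaks where the cluster is weak — it defies
the pattern and is culled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .matrix import PhosphoMatrix
from .embed_cluster import ClusterSet

__all__ = [
    "ClusterStats",
    "compute_cluster_stats",
    "cull_by_slope",
    "cluster_index",
    "rank_clusters",
    "heatmap_order",
    "render_heatmap",
]


@dataclass
class ClusterStats:
    """Per-cluster summary quantities feeding the Index."""

    n_genes: int
    n_samples: int
    total_signal: float
    percent_na: float
    percent_single_sample_genes: float
    percent_single_gene_samples: float
    n_culled: int = 0
    index: float | None = None

    @property
    def intensity(self) -> float:
        return self.total_signal - self.total_signal * self.percent_na / 100.0

    @property
    def cleargenes(self) -> float:
        return self.n_genes - self.n_culled

    @property
    def realsamples(self) -> float:
        return self.n_samples - self.n_samples * self.percent_single_gene_samples / 100.0

    def as_dict(self) -> dict:
        d = asdict(self)
        d.update(
            intensity=self.intensity,
            cleargenes=self.cleargenes,
            realsamples=self.realsamples,
        )
        return d


def _cluster_submatrix(matrix: PhosphoMatrix, gene_set) -> pd.DataFrame:
    genes = sorted(set(gene_set))
    if not genes:
        raise ValueError("gene_set must be non-empty")
    missing = set(genes) - set(matrix.genes)
    if missing:
        raise KeyError(f"genes not in matrix: {sorted(missing)}")
    sub = matrix.data.loc[genes]
    # included samples: those with >=1 observed cluster gene
    keep = sub.notna().any(axis=0)
    return sub.loc[:, keep]


def compute_cluster_stats(matrix: PhosphoMatrix, gene_set) -> ClusterStats:
    """Summary statistics of a cluster over its own informative samples.

    Samples included are exactly those in which at least one cluster gene
    is observed, so percentages are cluster-specific (a 9-gene cluster of
    a 233-sample dataset may span only 48 samples).
    """
    sub = _cluster_submatrix(matrix, gene_set)
    obs = sub.notna()
    n_genes, n_samples = sub.shape
    n_cells = n_genes * n_samples
    total_signal = float(np.nansum(sub.to_numpy()))
    percent_na = 100.0 * (n_cells - int(obs.to_numpy().sum())) / n_cells
    genes_per_sample = obs.sum(axis=0)
    samples_per_gene = obs.sum(axis=1)
    pct_ssg = 100.0 * float((samples_per_gene == 1).sum()) / n_genes
    pct_sgs = 100.0 * float((genes_per_sample == 1).sum()) / n_samples
    return ClusterStats(
        n_genes=n_genes,
        n_samples=n_samples,
        total_signal=total_signal,
        percent_na=percent_na,
        percent_single_sample_genes=pct_ssg,
        percent_single_gene_samples=pct_sgs,
    )


def cull_by_slope(matrix: PhosphoMatrix, gene_set) -> list[str]:
    """Genes whose regression slope against sorted samples is positive.

    The cluster's samples are ordered by decreasing per-sample totals of
    observed cluster signal; each gene's values (missing treated as 0 here
    only — absence in a high-signal sample counts against conformity) are
    regressed on sample position 1..m by ordinary least squares.  Slope
    > 0 means the gene is strongest where the cluster is weakest: culled.
    Slope <= 0 (including exactly 0, and the undefined single-sample case)
    keeps the gene.
    """
    sub = _cluster_submatrix(matrix, gene_set)
    m = sub.shape[1]
    if m < 2:
        return []
    totals = sub.sum(axis=0, skipna=True)
    order = totals.sort_values(ascending=False, kind="stable").index
    vals = sub.loc[:, order].fillna(0.0).to_numpy()
    x = np.arange(1, m + 1, dtype=float)
    xc = x - x.mean()
    slopes = (vals - vals.mean(axis=1, keepdims=True)) @ xc / (xc @ xc)
    return [g for g, s in zip(sub.index, slopes) if s > 0]


def cluster_index(stats: ClusterStats) -> float:
    """Apply the Index formula and store the result on ``stats``."""
    idx = (
        stats.intensity
        * (1.0 + stats.realsamples)
        * (1.0 + stats.cleargenes)
        / (1.0 + stats.percent_na)
    )
    stats.index = idx
    return idx


def evaluate_cluster(matrix: PhosphoMatrix, gene_set) -> ClusterStats:
    """Stats + slope culling + Index for one gene set."""
    stats = compute_cluster_stats(matrix, gene_set)
    stats.n_culled = len(cull_by_slope(matrix, gene_set))
    cluster_index(stats)
    return stats


def rank_clusters(matrix: PhosphoMatrix, cluster_set: ClusterSet):
    """Evaluate every cluster and rank by Index (descending).

    Returns
    -------
    table : DataFrame
        One row per cluster: group id, rank, gene/sample counts, the
        single-sample/single-gene percentages, total signal, percent NA,
        culled count and Index; sorted by descending Index.
    summary : dict
        ``sum_index``, ``max_index`` and the aggregate percentage sums
        used to compare clustering methods.
    """
    clusters = cluster_set.clusters()
    if not clusters:
        raise ValueError("cluster set is empty")
    rows = []
    for cid, genes in clusters.items():
        st = evaluate_cluster(matrix, genes)
        rows.append(
            {
                "group": cid,
                "n_genes": st.n_genes,
                "percent_single_sample_genes": st.percent_single_sample_genes,
                "n_samples": st.n_samples,
                "percent_single_gene_samples": st.percent_single_gene_samples,
                "total_signal": st.total_signal,
                "percent_na": st.percent_na,
                "n_culled": st.n_culled,
                "index": st.index,
            }
        )
    table = pd.DataFrame(rows).sort_values(
        ["index", "group"], ascending=[False, True], kind="stable"
    )
    table.insert(1, "rank", np.arange(1, len(table) + 1))
    table = table.reset_index(drop=True)
    summary = {
        "sum_index": float(table["index"].sum()),
        "max_index": float(table["index"].max()),
        "sum_percent_na": float(table["percent_na"].sum()),
        "sum_percent_single_sample_genes": float(
            table["percent_single_sample_genes"].sum()
        ),
        "sum_percent_single_gene_samples": float(
            table["percent_single_gene_samples"].sum()
        ),
        "n_clusters": int(len(table)),
    }
    return table, summary


def heatmap_order(matrix: PhosphoMatrix, gene_set) -> pd.DataFrame:
    """Cluster submatrix ordered for heat-map display.

    Genes sorted by decreasing observed row sums (top to bottom), samples
    by decreasing observed column sums (left to right); ties keep their
    original (sorted-label) order.  Missing cells are preserved (rendered
    black downstream).
    """
    sub = _cluster_submatrix(matrix, gene_set)
    row_order = sub.sum(axis=1, skipna=True).sort_values(
        ascending=False, kind="stable"
    ).index
    col_order = sub.sum(axis=0, skipna=True).sort_values(
        ascending=False, kind="stable"
    ).index
    return sub.loc[row_order, col_order]


def render_heatmap(ordered: pd.DataFrame, path, *, cmap: str = "cividis") -> None:
    """Render an ordered cluster submatrix; missing data drawn black."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * ordered.shape[1]), max(3, 0.25 * ordered.shape[0]))
    )
    cm = matplotlib.colormaps[cmap].copy()
    cm.set_bad("black")
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap=cm, interpolation="nearest")
    ax.set_xticks(range(ordered.shape[1]), ordered.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(ordered.shape[0]), ordered.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="peptide count")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
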