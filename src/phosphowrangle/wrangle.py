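"""Combining clusters across embeddings and filtering them ("wrangling").

Different dissimilarities resolve different genes, so clusters found for
the same kinase under, say, Spearman and Euclidean embeddings overlap but
differ.  Wrangling merges such clusters by union, then filters the merged
gene/sample sets with quantitative rules: anchor on a kinase of interest,
require genes to recur, and drop the single-sample genes and single-gene
samples that carry no co-observation evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .matrix import PhosphoMatrix
from .evaluate import cull_by_slope

__all__ = ["combine_clusters", "FilterRules", "filter_cluster"]


def combine_clusters(*gene_sets) -> tuple[set[str], dict[str, list[int]]]:
    """Union of two or more cluster gene sets with source provenance.

    Returns the union and, per gene, the indices of the source sets that
    contributed it.
    """
    if len(gene_sets) < 2:
        raise ValueError("need at least two gene sets to combine")
    provenance: dict[str, list[int]] = {}
    for i, gs in enumerate(gene_sets):
        for g in gs:
            provenance.setdefault(g, []).append(i)
    union = set(provenance)
    if not union:
        raise ValueError("union of clusters is empty")
    return union, provenance


@dataclass(frozen=True)
class FilterRules:
    """Filtering rules applied to a (gene set, sample set) pair.

    Attributes
    ----------
    anchor
        Keep only samples in which this gene is observed; the anchor gene
        itself is never dropped by any gene rule.
    min_gene_occurrence
        Drop genes observed in fewer than this many kept samples
        ("present at least twice" = 2).
    drop_single_sample_genes
        Drop genes observed in exactly one kept sample.
    drop_single_gene_samples
        Drop samples containing exactly one observed kept gene.
    keep_pattern_conformers
        Drop genes culled by the slope rule on the current submatrix.
    single_pass
        Apply the rule sequence once instead of iterating to a fixed
        point (for replicating single-pass narratives).
    """

    anchor: str | None = None
    min_gene_occurrence: int | None = None
    drop_single_sample_genes: bool = False
    drop_single_gene_samples: bool = False
    keep_pattern_conformers: bool = False
    single_pass: bool = False


def _observed(matrix: PhosphoMatrix, genes: list[str], samples: list[str]) -> pd.DataFrame:
    return matrix.data.loc[genes, samples].notna()


def filter_cluster(
    matrix: PhosphoMatrix,
    gene_set,
    rules: FilterRules,
    max_iter: int = 100,
) -> tuple[set[str], set[str]]:
    """Apply filtering rules iteratively to a fixed point.

    Starting from the cluster's genes and its informative samples (those
    with >= 1 observed cluster gene), rules are applied in a deterministic
    order — anchor sample restriction, then gene rules, then sample rules
    — and the sequence repeats until nothing changes (dropping a sample
    can create new single-sample genes and vice versa).  The anchor gene
    is never dropped.  Returns the filtered (gene set, sample set).
    """
    genes = sorted(set(gene_set))
    if not genes:
        raise ValueError("gene_set must be non-empty")
    unknown = set(genes) - set(matrix.genes)
    if unknown:
        raise KeyError(f"genes not in matrix: {sorted(unknown)}")
    if rules.anchor is not None and rules.anchor not in genes:
        raise ValueError(f"anchor gene {rules.anchor!r} not in the cluster")

    obs_full = matrix.data.loc[genes].notna()
    samples = sorted(obs_full.columns[obs_full.any(axis=0)])

    for _ in range(max_iter):
        prev = (tuple(genes), tuple(samples))

        # anchor: restrict samples to those where the anchor is observed
        if rules.anchor is not None:
            anchor_obs = matrix.data.loc[rules.anchor, samples].notna()
            samples = sorted(pd.Index(samples)[anchor_obs.to_numpy()])

        # gene rules
        obs = _observed(matrix, genes, samples)
        per_gene = obs.sum(axis=1)
        keep = pd.Series(True, index=obs.index)
        if rules.min_gene_occurrence is not None:
            keep &= per_gene >= rules.min_gene_occurrence
        if rules.drop_single_sample_genes:
            keep &= per_gene != 1
        keep &= per_gene > 0  # genes unobserved in kept samples drop out
        if rules.anchor is not None:
            keep[rules.anchor] = True
        genes = sorted(obs.index[keep])
        if rules.keep_pattern_conformers and len(samples) >= 2 and genes:
            sub = PhosphoMatrix(matrix.data.loc[genes, samples].dropna(how="all", axis=1))
            culled = set(cull_by_slope(sub, genes)) - {rules.anchor}
            genes = sorted(set(genes) - culled)

        # sample rules
        if genes:
            obs = _observed(matrix, genes, samples)
            per_sample = obs.sum(axis=0)
            keep_s = per_sample > 0
            if rules.drop_single_gene_samples:
                keep_s &= per_sample != 1
            samples = sorted(obs.columns[keep_s])

        if not genes or not samples:
            break
        if (tuple(genes), tuple(samples)) == prev or rules.single_pass:
            break

    return set(genes), set(samples)
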