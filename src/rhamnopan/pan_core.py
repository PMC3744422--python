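"""Shared-content and core-genome statistics, clustering and trees.

Percentages follow the truncation convention used when reporting ratios in
strain-cohort surveys of this kind: one decimal, floored rather than
rounded (31/77 prints as 40.2, 2918/3016 as 96.7).  The median over an
even number of strains is the lower median, so it is always an attainable
per-strain count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist
from scipy.stats import mannwhitneyu, pearsonr
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .align import SequenceSearcher
from .io_core import ReferenceAnnotation, StrainGenome
from .ortholog_calling import PresenceMatrix


def truncate_percent(numerator: int, denominator: int) -> float:
    """One-decimal percentage, truncated (floored), e.g. 31/77 -> 40.2."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be within [0, denominator]")
    return (1000 * numerator // denominator) / 10


@dataclass(frozen=True)
class SharedContentSummary:
    per_strain: dict[str, tuple[int, float]]   # strain -> (count, percent)
    min: tuple[int, float]
    median: tuple[int, float]
    max: tuple[int, float]
    n_reference_genes: int


def shared_content(matrix: PresenceMatrix) -> SharedContentSummary:
    """Per-strain shared gene counts (row sums) with truncated percentages."""
    if matrix.n_strains == 0:
        raise ValueError("empty matrix")
    counts = matrix.calls.sum(axis=1).astype(int)
    n = matrix.n_genes

    def pair(c: int) -> tuple[int, float]:
        return int(c), truncate_percent(int(c), n)

    ordered = np.sort(counts)
    lower_median = int(ordered[(len(ordered) - 1) // 2])
    return SharedContentSummary(
        per_strain={sid: pair(c) for sid, c in zip(matrix.strain_ids, counts)},
        min=pair(int(ordered[0])),
        median=pair(lower_median),
        max=pair(int(ordered[-1])),
        n_reference_genes=n)


@dataclass(frozen=True)
class CoreResult:
    core_tags: set[str]
    core_size: int
    core_percent: float


def core_genome(matrix: PresenceMatrix) -> CoreResult:
    """Genes called present in every strain (column-wise AND)."""
    if matrix.n_strains == 0:
        raise ValueError("empty matrix")
    core_mask = matrix.calls.all(axis=0)
    tags = {t for t, m in zip(matrix.locus_tags, core_mask) if m}
    return CoreResult(core_tags=tags, core_size=len(tags),
                      core_percent=truncate_percent(len(tags), matrix.n_genes))


def core_accumulation(matrix: PresenceMatrix, n_permutations: int = 100,
                      seed: int = 0, exhaustive: bool = False) -> np.ndarray:
    """Mean core-genome size after adding k = 1..n genomes in random order.

    For each permutation of the strains the running intersection of row
    supports is recorded; the returned curve is the mean over permutations
    (or over all n! orders with ``exhaustive=True``, feasible for small
    cohorts).  It is monotone non-increasing, and its value at k = n
    equals the core size regardless of permutation order.
    """
    n = matrix.n_strains
    if exhaustive:
        import itertools
        import math
        orders = itertools.permutations(range(n))
        n_orders = math.factorial(n)
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        orders = (rng.permutation(n) for _ in range(n_permutations))
        n_orders = n_permutations
    sums = np.zeros(n, dtype=float)
    for order in orders:
        running = np.ones(matrix.n_genes, dtype=bool)
        for k, idx in enumerate(order):
            running &= matrix.calls[idx].astype(bool)
            sums[k] += running.sum()
    return sums / n_orders


@dataclass
class DendrogramTree:
    """Ultrametric gene-content dendrogram with its linkage matrix."""

    leaves: list[str]
    linkage: np.ndarray
    tree: TreeNode

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> dict[str, int]:
        labels = sch.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return dict(zip(self.leaves, (int(x) for x in labels)))


def gene_content_clustering(matrix: PresenceMatrix, distance: str = "jaccard",
                            linkage: str = "average") -> DendrogramTree:
    """Hierarchical clustering of strains by binary gene-content profiles.

    Defaults are Jaccard distance with average linkage (UPGMA), the
    standard pairing for binary gene-content data.
    """
    if matrix.n_strains < 2:
        raise ValueError("clustering needs at least 2 strains")
    data = matrix.calls.astype(bool)
    dist = pdist(data, metric=distance)
    Z = sch.linkage(dist, method=linkage)
    tree = TreeNode.from_linkage_matrix(Z, matrix.strain_ids)
    return DendrogramTree(leaves=list(matrix.strain_ids), linkage=Z, tree=tree)


def snp_distance_matrix(strains: Sequence[StrainGenome],
                        annotation: ReferenceAnnotation, reference_seq: str,
                        core_tags: set[str],
                        max_genes: int | None = None,
                        seed: int = 0) -> DistanceMatrix:
    """Pairwise substitution distance over concatenated core genes.

    Each strain's copy of each core gene is located by local alignment;
    copies recovered without indels contribute their aligned bases.  The
    distance between two strains is the mismatch fraction over positions
    where both carry a cleanly aligned copy.
    """
    core_genes = [g for g in annotation.genes if g.locus_tag in core_tags]
    if len(core_genes) < 10:
        raise ValueError("strains must share at least 10 core genes")
    if max_genes is not None and len(core_genes) > max_genes:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(core_genes), size=max_genes, replace=False))
        core_genes = [core_genes[i] for i in idx]

    from .align import encode, revcomp

    rows = []
    for strain in strains:
        searcher = SequenceSearcher(strain.sequences)
        parts = []
        for gene in core_genes:
            gene_seq = annotation.gene_sequence(gene, reference_seq)
            hit = searcher.best_local(gene_seq)
            if (hit.substitution_only and not hit.empty
                    and hit.q_end - hit.q_start == len(gene_seq)):
                contig = strain.sequences[hit.contig_index]
                seq = contig[hit.t_start:hit.t_end]
                if hit.strand == "-":
                    seq = revcomp(seq)
                parts.append(encode(seq))
            else:
                parts.append(np.full(len(gene_seq), 4, dtype=np.uint8))
        rows.append(np.concatenate(parts))
    stack = np.vstack(rows)
    valid = stack < 4
    n = len(strains)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            total = int(both.sum())
            d = float((stack[i][both] != stack[j][both]).sum() / total) if total else 0.0
            dist[i, j] = dist[j, i] = d
    return DistanceMatrix(dist, ids=[s.strain_id for s in strains])


def snp_distance_tree(strains: Sequence[StrainGenome],
                      annotation: ReferenceAnnotation, reference_seq: str,
                      core_tags: set[str], max_genes: int | None = None,
                      seed: int = 0) -> TreeNode:
    """Neighbor-joining tree on core-gene substitution distances."""
    dm = snp_distance_matrix(strains, annotation, reference_seq, core_tags,
                             max_genes=max_genes, seed=seed)
    return nj(dm)


def tree_concordance(tree_a: TreeNode, tree_b: TreeNode) -> float:
    """Cophenetic concordance between two trees on the same leaf set.

    Pearson correlation of the two cophenetic (tip-to-tip) distance
    matrices, clamped at 0 so the score lies in [0, 1]; identical trees
    score 1, label-shuffled trees score near 0 on average.
    """
    tips_a = {t.name for t in tree_a.tips()}
    tips_b = {t.name for t in tree_b.tips()}
    shared = sorted(tips_a & tips_b)
    if len(shared) < 3:
        raise ValueError("trees share fewer than 3 leaves")
    dm_a = tree_a.tip_tip_distances(endpoints=shared)
    dm_b = tree_b.tip_tip_distances(endpoints=shared)
    a = dm_a.filter(shared).condensed_form()
    b = dm_b.filter(shared).condensed_form()
    if np.allclose(a, a[0]) or np.allclose(b, b[0]):
        # degenerate (star-like) trees: concordant iff both are degenerate
        return 1.0 if np.allclose(a, a[0]) and np.allclose(b, b[0]) else 0.0
    r = pearsonr(a, b).statistic
    return float(max(0.0, r))


@dataclass(frozen=True)
class CogCategorySummary:
    total: int
    non_core: int
    percent_non_core: float


def cog_partition(annotation: ReferenceAnnotation,
                  core_tags: set[str]) -> dict[str, CogCategorySummary]:
    """Per-COG-category tallies of total genes and non-core genes."""
    out: dict[str, CogCategorySummary] = {}
    categories = sorted({g.cog_category for g in annotation.genes
                         if g.cog_category})
    for cat in categories:
        genes = [g for g in annotation.genes if g.cog_category == cat]
        non_core = sum(1 for g in genes if g.locus_tag not in core_tags)
        out[cat] = CogCategorySummary(
            total=len(genes), non_core=non_core,
            percent_non_core=truncate_percent(non_core, len(genes)))
    return out


@dataclass(frozen=True)
class NicheComparison:
    group_means: dict[str, float]      # full precision shared_percent means
    group_sizes: dict[str, int]
    p_value: float


def niche_content_comparison(summary: SharedContentSummary,
                             niche_labels: Mapping[str, str],
                             groups: Mapping[str, Sequence[str]] | None = None,
                             exclude: Sequence[str] = ()) -> NicheComparison:
    """Compare mean shared-content percentage between strain groups.

    ``groups`` maps group name -> niches it covers (default: one group per
    niche); ``exclude`` drops niches entirely (e.g. clinical isolates).
    The test is a two-sided Mann-Whitney U over per-strain percentages.
    """
    excluded = set(exclude)
    values: dict[str, list[float]] = {}
    for strain, (_, percent) in summary.per_strain.items():
        niche = niche_labels.get(strain)
        if niche is None or niche in excluded:
            continue
        if groups is None:
            group = niche
        else:
            group = next((name for name, niches in groups.items()
                          if niche in niches), None)
            if group is None:
                continue
        values.setdefault(group, []).append(percent)
    empty = [g for g, v in values.items() if not v]
    if len(values) < 2 or empty:
        raise ValueError("need at least 2 non-empty groups after exclusion")
    names = sorted(values)
    means = {g: float(np.mean(values[g])) for g in names}
    sizes = {g: len(values[g]) for g in names}
    if len(names) == 2:
        stat = mannwhitneyu(values[names[0]], values[names[1]],
                            alternative="two-sided")
        p = float(stat.pvalue)
    else:
        from scipy.stats import kruskal
        p = float(kruskal(*(values[g] for g in names)).pvalue)
    return NicheComparison(group_means=means, group_sizes=sizes, p_value=p)
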