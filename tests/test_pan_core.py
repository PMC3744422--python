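"""Shared/core statistics, accumulation, clustering and tree comparisons,
each checked against a brute-force or closed-form oracle."""

import itertools
import io as _io

import numpy as np
import pytest
from skbio import TreeNode

from rhamnopan import pan_core
from rhamnopan.io_core import GeneModel, ReferenceAnnotation
from rhamnopan.ortholog_calling import PresenceMatrix


def _matrix(calls, tags=None):
    calls = np.asarray(calls, dtype=np.int8)
    return PresenceMatrix(
        strain_ids=[f"S{i}" for i in range(calls.shape[0])],
        locus_tags=tags or [f"G_{j:04d}" for j in range(calls.shape[1])],
        calls=calls)


@pytest.mark.parametrize("num,den,expected", [
    (2622, 3016, 86.9), (2918, 3016, 96.7), (3016, 3016, 100.0),
    (2419, 3016, 80.2), (31, 77, 40.2), (3, 23, 13.0), (9, 16, 56.2),
    (87, 288, 30.2), (0, 5, 0.0),
])
def test_truncate_percent_reproduces_reported_ratios(num, den, expected):
    """The one-decimal convention is truncation, not rounding: several of
    these ratios (31/77, 2918/3016) would round the other way."""
    assert pan_core.truncate_percent(num, den) == expected


def test_truncate_percent_rejects_bad_input():
    with pytest.raises(ValueError):
        pan_core.truncate_percent(1, 0)
    with pytest.raises(ValueError):
        pan_core.truncate_percent(6, 5)


def test_shared_content_matches_row_sums():
    rng = np.random.default_rng(8)
    calls = rng.integers(0, 2, size=(7, 30))
    summary = pan_core.shared_content(_matrix(calls))
    for i in range(7):
        count, percent = summary.per_strain[f"S{i}"]
        assert count == calls[i].sum()
        assert percent == pan_core.truncate_percent(count, 30)
    assert summary.min[0] == calls.sum(axis=1).min()
    assert summary.max[0] == calls.sum(axis=1).max()


def test_shared_content_uses_lower_median_for_even_n():
    calls = np.zeros((4, 10), dtype=np.int8)
    for i, c in enumerate((2, 3, 5, 7)):
        calls[i, :c] = 1
    summary = pan_core.shared_content(_matrix(calls))
    assert summary.median[0] == 3


def test_all_ones_matrix_summary():
    summary = pan_core.shared_content(_matrix(np.ones((5, 10))))
    assert summary.min == summary.median == summary.max == (10, 100.0)


def test_core_genome_equals_brute_force_intersection():
    rng = np.random.default_rng(5)
    calls = rng.integers(0, 2, size=(10, 50))
    matrix = _matrix(calls)
    result = pan_core.core_genome(matrix)
    expected = set(matrix.locus_tags)
    for row in calls:
        expected &= {t for t, v in zip(matrix.locus_tags, row) if v}
    assert result.core_tags == expected
    assert result.core_size == len(expected)


def test_single_strain_core_is_its_gene_set():
    result = pan_core.core_genome(_matrix(np.ones((1, 12))))
    assert result.core_size == 12
    assert result.core_percent == 100.0


def test_core_accumulation_exhaustive_matches_enumeration():
    rng = np.random.default_rng(9)
    calls = rng.integers(0, 2, size=(5, 20))
    matrix = _matrix(calls)
    curve = pan_core.core_accumulation(matrix, exhaustive=True)
    expected = np.zeros(5)
    for order in itertools.permutations(range(5)):
        running = np.ones(20, dtype=bool)
        for k, idx in enumerate(order):
            running &= calls[idx].astype(bool)
            expected[k] += running.sum()
    expected /= 120
    assert np.allclose(curve, expected)
    assert curve[0] == pytest.approx(calls.sum(axis=1).mean())
    assert curve[-1] == pan_core.core_genome(matrix).core_size


def test_core_accumulation_monotone_and_constant_cases():
    assert np.allclose(pan_core.core_accumulation(_matrix(np.ones((6, 15))),
                                                  n_permutations=5), 15)
    rng = np.random.default_rng(17)
    for _ in range(5):
        matrix = _matrix(rng.integers(0, 2, size=(8, 25)))
        curve = pan_core.core_accumulation(matrix, n_permutations=20, seed=1)
        assert np.all(np.diff(curve) <= 1e-9)
        assert curve[-1] == pan_core.core_genome(matrix).core_size


def _brute_upgma_heights(dist):
    """Plain agglomerative UPGMA, tracking merge heights only."""
    clusters = {i: 1 for i in range(len(dist))}          # cluster id -> size
    d = {(i, j): dist[i][j]
         for i in range(len(dist)) for j in range(i + 1, len(dist))}
    heights = []
    next_id = len(dist)
    while len(clusters) > 1:
        (a, b), h = min(d.items(), key=lambda kv: kv[1])
        heights.append(h)
        sa, sb = clusters[a], clusters[b]
        for k in list(clusters):
            if k in (a, b):
                continue
            da = d[tuple(sorted((a, k)))]
            db = d[tuple(sorted((b, k)))]
            d[(k, next_id)] = (da * sa + db * sb) / (sa + sb)
        d = {pair: v for pair, v in d.items()
             if a not in pair and b not in pair}
        del clusters[a], clusters[b]
        clusters[next_id] = sa + sb
        next_id += 1
    return sorted(heights)


def test_upgma_heights_match_brute_force():
    rng = np.random.default_rng(23)
    for _ in range(4):
        calls = rng.integers(0, 2, size=(6, 18))
        # avoid degenerate all-equal rows
        calls[0, 0] = 1
        calls[1, 0] = 0
        matrix = _matrix(calls)
        dendro = pan_core.gene_content_clustering(matrix)
        rows = calls.astype(bool)
        dist = [[0.0] * 6 for _ in range(6)]
        for i in range(6):
            for j in range(6):
                union = (rows[i] | rows[j]).sum()
                inter = (rows[i] & rows[j]).sum()
                dist[i][j] = 0.0 if union == 0 else 1 - inter / union
        assert np.allclose(sorted(dendro.heights), _brute_upgma_heights(dist))


def test_identical_strains_merge_at_height_zero():
    calls = np.array([[1, 0, 1, 1], [1, 0, 1, 1], [0, 1, 0, 0]])
    dendro = pan_core.gene_content_clustering(_matrix(calls))
    assert dendro.heights[0] == 0.0
    cut = dendro.cut(2)
    assert cut["S0"] == cut["S1"] != cut["S2"]


def _annotation_for(tags_cogs):
    genes = [GeneModel(locus_tag=t, start=10 + 100 * i, end=70 + 100 * i,
                       strand="+", cog_category=c)
             for i, (t, c) in enumerate(tags_cogs)]
    return ReferenceAnnotation(genome_id="R", genome_length=10_000,
                               genes=genes)


def test_cog_partition_hand_tally():
    annotation = _annotation_for([
        ("A_1", "G"), ("A_2", "G"), ("A_3", "G"), ("A_4", "K"), ("A_5", "K")])
    result = pan_core.cog_partition(annotation, core_tags={"A_1", "A_4", "A_5"})
    assert result["G"].total == 3
    assert result["G"].non_core == 2
    assert result["G"].percent_non_core == 66.6
    assert result["K"].percent_non_core == 0.0


def test_cog_partition_all_core_gives_zero_percents():
    annotation = _annotation_for([("A_1", "G"), ("A_2", "K")])
    result = pan_core.cog_partition(annotation, {"A_1", "A_2"})
    assert all(v.percent_non_core == 0.0 for v in result.values())


def test_niche_comparison_separated_groups_is_significant():
    rng = np.random.default_rng(2)
    per_strain = {}
    labels = {}
    for i in range(20):
        per_strain[f"D{i}"] = (0, float(rng.normal(90, 1)))
        labels[f"D{i}"] = "dairy"
    for i in range(20):
        per_strain[f"H{i}"] = (0, float(rng.normal(96, 1)))
        labels[f"H{i}"] = "intestinal"
    summary = pan_core.SharedContentSummary(
        per_strain=per_strain, min=(0, 0.0), median=(0, 0.0), max=(0, 0.0),
        n_reference_genes=100)
    result = pan_core.niche_content_comparison(summary, labels)
    assert result.p_value < 0.001
    assert result.group_means["dairy"] == pytest.approx(90, abs=1)
    assert result.group_means["intestinal"] == pytest.approx(96, abs=1)


def test_niche_comparison_identical_groups_not_significant():
    per_strain = {f"A{i}": (0, 95.0) for i in range(10)}
    per_strain.update({f"B{i}": (0, 95.0) for i in range(10)})
    labels = {k: ("g1" if k.startswith("A") else "g2") for k in per_strain}
    summary = pan_core.SharedContentSummary(
        per_strain=per_strain, min=(0, 0.0), median=(0, 0.0), max=(0, 0.0),
        n_reference_genes=100)
    result = pan_core.niche_content_comparison(summary, labels)
    assert result.p_value > 0.99


def test_niche_comparison_exclusion_and_empty_group_error():
    per_strain = {"A": (0, 90.0), "B": (0, 91.0), "C": (0, 96.0)}
    labels = {"A": "dairy", "B": "dairy", "C": "clinical"}
    summary = pan_core.SharedContentSummary(
        per_strain=per_strain, min=(0, 0.0), median=(0, 0.0), max=(0, 0.0),
        n_reference_genes=100)
    with pytest.raises(ValueError):
        pan_core.niche_content_comparison(summary, labels,
                                          exclude=["clinical"])


def _tree(newick: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(newick))


def test_tree_concordance_identical_and_rotated():
    a = _tree("((A:1,B:2):1,(C:1,D:1):2);")
    rotated = _tree("((D:1,C:1):2,(B:2,A:1):1);")
    assert pan_core.tree_concordance(a, a) == pytest.approx(1.0)
    assert pan_core.tree_concordance(a, rotated) == pytest.approx(1.0)


def test_tree_concordance_shuffled_labels_score_near_zero():
    rng = np.random.default_rng(31)
    calls = rng.integers(0, 2, size=(12, 40))
    tree = pan_core.gene_content_clustering(_matrix(calls)).tree
    leaves = [t.name for t in tree.tips()]
    scores = []
    for _ in range(60):
        shuffled = tree.copy()
        names = list(leaves)
        rng.shuffle(names)
        for tip, name in zip(shuffled.tips(), names):
            tip.name = name
        scores.append(pan_core.tree_concordance(tree, shuffled))
    assert np.mean(scores) < 0.3
    assert np.mean(scores) < pan_core.tree_concordance(tree, tree)
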