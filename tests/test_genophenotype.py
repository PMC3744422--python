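"""Growth-curve statistics, phenotype calls and the geno-phenotype classifier."""

import numpy as np
import pytest

from rhamnopan.crispr_typing import ABSENT, CONSERVED, CrisprProfile
from rhamnopan.genophenotype import (API50CH_SUBSTRATES, AxisConfig,
                                     GrowthCurve, NEGATIVE, POSITIVE,
                                     SUGAR_GROUP_I, SUGAR_GROUP_II,
                                     SUGAR_GROUP_III, PhenotypeRecord,
                                     cohort_genophenotype_report, compute_arp,
                                     group_contingency, mucus_binding_percent,
                                     pilosotype_call, read_phenotype_table,
                                     score_genophenotype, sugar_group_scores,
                                     trapezoid_auc, write_phenotype_table)


def _curve(t, od):
    return GrowthCurve(timepoints=np.asarray(t), od=np.asarray(od))


class TestGrowthCurves:
    def test_constant_and_linear_auc(self):
        t = np.arange(0.0, 15.01, 0.5)
        assert trapezoid_auc(_curve(t, np.ones_like(t))) == pytest.approx(15.0)
        t10 = np.linspace(0, 10, 21)
        assert trapezoid_auc(_curve(t10, t10 / 10)) == pytest.approx(5.0)

    def test_auc_matches_independent_recomputation(self):
        rng = np.random.default_rng(0)
        t = np.arange(0.0, 15.01, 0.5)
        od = 1.2 / (1 + np.exp(-0.8 * (t - 6))) + rng.normal(0, 0.01, len(t))
        od = np.clip(od, 0, None)
        expected = sum((od[i] + od[i + 1]) / 2 * (t[i + 1] - t[i])
                       for i in range(len(t) - 1))
        assert trapezoid_auc(_curve(t, od)) == pytest.approx(expected, abs=1e-9)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            _curve([0.0], [1.0])
        with pytest.raises(ValueError):
            _curve([0.0, 0.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            _curve([0.0, 1.0], [1.0, -0.1])

    def test_arp_identity_and_scaling(self):
        t = np.arange(0.0, 15.01, 0.5)
        od = 1.0 / (1 + np.exp(-(t - 7)))
        control = _curve(t, od)
        assert compute_arp(control, control) == pytest.approx(0.0)
        assert compute_arp(_curve(t, 0.5 * od), control) == pytest.approx(50.0)

    def test_arp_negative_for_growth_enhancement(self):
        t = np.arange(0.0, 10.01, 0.5)
        od = np.linspace(0.1, 1.0, len(t))
        arp = compute_arp(_curve(t, 1.3 * od), _curve(t, od))
        assert arp == pytest.approx(-30.0)

    def test_arp_invariant_to_common_scaling(self):
        rng = np.random.default_rng(1)
        t = np.arange(0.0, 12.01, 0.5)
        sample = np.abs(rng.normal(0.5, 0.1, len(t)))
        control = np.abs(rng.normal(0.8, 0.1, len(t)))
        base = compute_arp(_curve(t, sample), _curve(t, control))
        scaled = compute_arp(_curve(t, 3.7 * sample), _curve(t, 3.7 * control))
        assert scaled == pytest.approx(base, abs=1e-9)

    def test_arp_requires_common_grid_and_positive_control(self):
        t = np.arange(0.0, 5.01, 0.5)
        with pytest.raises(ValueError):
            compute_arp(_curve(t, np.ones_like(t)),
                        _curve(t + 0.25, np.ones_like(t)))
        with pytest.raises(ValueError):
            compute_arp(_curve(t, np.ones_like(t)),
                        _curve(t, np.zeros_like(t)))


class TestMucusAndPilosotype:
    def test_mucus_binding_bounds(self):
        assert mucus_binding_percent(0.0, 100.0) == 0.0
        assert mucus_binding_percent(100.0, 100.0) == 100.0
        assert mucus_binding_percent(29.9, 100.0) == pytest.approx(29.9)
        with pytest.raises(ValueError):
            mucus_binding_percent(101.0, 100.0)
        with pytest.raises(ValueError):
            mucus_binding_percent(1.0, 0.0)

    def test_pilosotype_requires_genes_and_evidence(self):
        tags = ("P_1", "P_2", "P_3")
        full = {"P_1": 1, "P_2": 1, "P_3": 1}
        assert pilosotype_call(full, tags, POSITIVE) == POSITIVE
        assert pilosotype_call(full, tags) == POSITIVE
        # intact cluster but negative binding evidence -> negative
        assert pilosotype_call(full, tags, NEGATIVE) == NEGATIVE
        assert pilosotype_call({**full, "P_2": 0}, tags, POSITIVE) == NEGATIVE
        with pytest.raises(ValueError):
            pilosotype_call(full, ())


def test_group_contingency_reproduces_reported_percentages():
    """Cohort-level pilosotype tallies print with truncated percentages:
    31/77 human -> 40.2, 3/23 dairy -> 13.0, 9/16 intestinal -> 56.2."""
    calls = {}
    labels = {}
    def add(prefix, group, pos, neg):
        for i in range(pos):
            calls[f"{prefix}p{i}"] = POSITIVE
            labels[f"{prefix}p{i}"] = group
        for i in range(neg):
            calls[f"{prefix}n{i}"] = NEGATIVE
            labels[f"{prefix}n{i}"] = group
    add("h", "human", 31, 46)
    add("d", "dairy", 3, 20)
    counts, p_value = group_contingency(calls, labels,
                                        test_pair=("human", "dairy"))
    assert counts["human"].percent == 40.2
    assert (counts["human"].positive, counts["human"].total) == (31, 77)
    assert counts["dairy"].percent == 13.0
    assert 0 < p_value <= 1
    from scipy.stats import fisher_exact
    assert p_value == pytest.approx(
        fisher_exact([[31, 46], [3, 20]])[1])
    calls2 = {f"i{i}": (POSITIVE if i < 9 else NEGATIVE) for i in range(16)}
    labels2 = {k: "intestinal" for k in calls2}
    labels2.update({k: "dairy" for k in list(calls)[:5]})
    counts2, _ = group_contingency(
        {**calls2, **{k: calls[k] for k in list(calls)[:5]}},
        {**labels2}, test_pair=("intestinal", "dairy"))
    assert counts2["intestinal"].percent == 56.2


def _api(positives=(), partials=()):
    calls = {s: NEGATIVE for s in API50CH_SUBSTRATES}
    calls.update({s: POSITIVE for s in positives})
    calls.update({s: "partial" for s in partials})
    return calls


def test_sugar_group_scores():
    assert sugar_group_scores(_api(SUGAR_GROUP_I)) == (1.0, 0.0, 0.0)
    assert sugar_group_scores(_api()) == (0.0, 0.0, 0.0)
    # one partial of 4 in group II scores 0.125
    scores = sugar_group_scores(_api(partials=("D-maltose",)))
    assert scores == (0.0, 0.125, 0.0)
    scores = sugar_group_scores(_api(SUGAR_GROUP_II + SUGAR_GROUP_III))
    assert scores == (0.0, 1.0, 1.0)


def _config(tags=("P_1", "P_2", "P_3")):
    return AxisConfig(pili_gene_tags=tuple(tags))


def _crispr(conserved, total=24):
    return CrisprProfile("s", [CONSERVED] * conserved
                         + [ABSENT] * (total - conserved), ["present"] * 4)


def _row(n=100, lost=(), tags=None):
    tags = tags or [f"G_{i}" for i in range(n - 3)] + ["P_1", "P_2", "P_3"]
    return {t: (0 if t in lost else 1) for t in tags}


class TestClassifier:
    def test_intestinal_like_strain_scores_b(self):
        record = PhenotypeRecord(
            strain_id="b-like", api_calls=_api(SUGAR_GROUP_I),
            bile="resistant", mucus_binding=20.0, pilosotype=POSITIVE)
        result = score_genophenotype(_row(), _crispr(24), record, _config())
        assert result.genophenotype_class == "B"
        assert result.axis_scores["pilosotype"] == 1.0
        assert result.mean_score >= 0.6

    def test_dairy_like_strain_scores_a(self):
        record = PhenotypeRecord(
            strain_id="a-like",
            api_calls=_api(SUGAR_GROUP_II + SUGAR_GROUP_III),
            bile="sensitive", mucus_binding=0.5, pilosotype=NEGATIVE)
        lost = {"P_1", "P_2", "P_3"} | {f"G_{i}" for i in range(40)}
        result = score_genophenotype(_row(lost=lost), _crispr(6), record,
                                     _config())
        assert result.genophenotype_class == "A"
        assert result.mean_score <= 0.4

    def test_b_traits_with_deleted_pili_island_scores_b_dspacba(self):
        record = PhenotypeRecord(
            strain_id="bd", api_calls=_api(SUGAR_GROUP_I),
            bile="resistant", mucus_binding=0.5, pilosotype=NEGATIVE)
        result = score_genophenotype(_row(lost={"P_1", "P_2", "P_3"}),
                                     _crispr(24), record, _config())
        assert result.genophenotype_class == "B_dspaCBA"

    def test_intermediate_strain_is_unassigned(self):
        record = PhenotypeRecord(
            strain_id="mid", api_calls=_api(SUGAR_GROUP_II),
            bile="moderately_resistant", mucus_binding=1.0,
            pilosotype=NEGATIVE)
        result = score_genophenotype(_row(lost={"P_1"}), _crispr(12), record,
                                     _config())
        assert result.genophenotype_class == "unassigned"
        assert 0.4 < result.mean_score < 0.6

    def test_classification_is_idempotent_and_exclusive(self):
        record = PhenotypeRecord(
            strain_id="x", api_calls=_api(SUGAR_GROUP_I), bile="resistant",
            mucus_binding=10.0, pilosotype=POSITIVE)
        first = score_genophenotype(_row(), _crispr(24), record, _config())
        second = score_genophenotype(_row(), _crispr(24), record, _config())
        assert first == second
        assert first.genophenotype_class in {"A", "B", "B_dspaCBA",
                                             "unassigned"}

    def test_missing_inputs_are_rejected(self):
        record = PhenotypeRecord(strain_id="x", api_calls=_api())
        with pytest.raises(ValueError):
            score_genophenotype({}, _crispr(24), record, _config())
        with pytest.raises(ValueError):
            score_genophenotype(_row(), _crispr(24), record, AxisConfig())


def test_cohort_report_counts_and_axes():
    record = PhenotypeRecord(
        strain_id="s", api_calls=_api(SUGAR_GROUP_I), bile="resistant",
        mucus_binding=10.0, pilosotype=POSITIVE)
    results = []
    niches = {}
    for i in range(6):
        rec = PhenotypeRecord(**{**record.__dict__, "strain_id": f"s{i}"})
        results.append(score_genophenotype(_row(), _crispr(24), rec,
                                           _config()))
        niches[f"s{i}"] = "intestinal" if i < 4 else "vaginal"
    counts, means = cohort_genophenotype_report(results, niches)
    assert list(counts.index) == ["intestinal", "vaginal"]
    assert counts.loc["intestinal", "B"] == 4
    assert counts.loc["vaginal", "B"] == 2
    assert set(counts.sum(axis=1)) == {4, 2}
    assert means.loc["intestinal", "pilosotype"] == 1.0


def test_phenotype_table_round_trip(tmp_path):
    records = [
        PhenotypeRecord(strain_id="s1", api_calls=_api(SUGAR_GROUP_I),
                        bile="resistant", mucus_binding=12.5,
                        pilosotype=POSITIVE, tlr2_fold=1.4,
                        arp={("E. coli", 5.0): 42.0, ("E. coli", 6.2): -3.0}),
        PhenotypeRecord(strain_id="s2", api_calls=_api(), bile="sensitive",
                        mucus_binding=0.2, pilosotype=NEGATIVE),
    ]
    path = tmp_path / "pheno.tsv"
    write_phenotype_table(records, path)
    back = read_phenotype_table(path)
    assert [r.strain_id for r in back] == ["s1", "s2"]
    assert back[0].bile == "resistant"
    assert back[0].api_calls["L-fucose"] == POSITIVE
    assert back[0].arp[("E. coli", 6.2)] == pytest.approx(-3.0)
    assert back[1].pilosotype == NEGATIVE
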