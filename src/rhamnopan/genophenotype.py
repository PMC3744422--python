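"""Phenotype data models and the integrated geno-phenotype classification.

Phenotypes carried per strain: the 49-substrate carbohydrate fermentation
panel (API 50CH), a four-level bile-salt resistance category, the human
mucus-binding percentage, pilosotype evidence (functional SpaCBA pili),
TLR2 fold-induction (carried as data, excluded from scoring, since it
tracks neither clustering nor niche), and growth-curve antagonism (ARP)
values against indicator pathogens.

The geno-phenotype classifier integrates genotype and phenotype into
seven axes, each scored in [0, 1] where 1 is "intestinal-adapted"
(geno-phenotype B) and 0 "dairy-adapted" (geno-phenotype A):

* ``gene_content``      shared-gene fraction with the reference, rescaled
  over configured bounds;
* ``crispr_oligotype``  fraction of reference spacers conserved;
* ``bile``              resistant 1, moderately resistant 0.67, poorly
  resistant 0.33, sensitive 0;
* ``pilosotype``        functional SpaCBA pili;
* ``sugar_I``           fermentation of dulcitol / D-arabinose / L-fucose
  (characteristic of intestinal-adapted strains);
* ``sugar_II``/``sugar_III``  inverted fermentation scores of the
  dairy-associated sugar groups (saccharose/maltose/Me-a-D-glucopyranoside/
  turanose and rhamnose/sorbose/ribose/lactose).

The mean axis score decides the class: >= 0.6 is the B family (split into
B and B_dspaCBA by presence of the genomic island carrying the spaCBA
pili cluster), <= 0.4 is A, anything between is unassigned.  The axis
weights and cut-offs are a package construction — they reproduce the
qualitative A/B/B_dspaCBA system, not published magnitudes — and are
exposed through :class:`AxisConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .crispr_typing import CONSERVED, CrisprProfile

POSITIVE = "positive"
PARTIAL = "partial"
NEGATIVE = "negative"

BILE_LEVELS = ("resistant", "moderately_resistant", "poorly_resistant",
               "sensitive")

SUGAR_GROUP_I = ("dulcitol", "D-arabinose", "L-fucose")
SUGAR_GROUP_II = ("D-saccharose", "D-maltose",
                  "methyl-alpha-D-glucopyranoside", "D-turanose")
SUGAR_GROUP_III = ("L-rhamnose", "L-sorbose", "D-ribose", "D-lactose")

#: the 49 substrates of the API 50CH fermentation panel (control well omitted)
API50CH_SUBSTRATES = (
    "glycerol", "erythritol", "D-arabinose", "L-arabinose", "D-ribose",
    "D-xylose", "L-xylose", "D-adonitol", "methyl-beta-D-xylopyranoside",
    "D-galactose", "D-glucose", "D-fructose", "D-mannose", "L-sorbose",
    "L-rhamnose", "dulcitol", "inositol", "D-mannitol", "D-sorbitol",
    "methyl-alpha-D-mannopyranoside", "methyl-alpha-D-glucopyranoside",
    "N-acetylglucosamine", "amygdalin", "arbutin", "esculin", "salicin",
    "D-cellobiose", "D-maltose", "D-lactose", "D-melibiose", "D-saccharose",
    "D-trehalose", "inulin", "D-melezitose", "D-raffinose", "starch",
    "glycogen", "xylitol", "gentiobiose", "D-turanose", "D-lyxose",
    "D-tagatose", "D-fucose", "L-fucose", "D-arabitol", "L-arabitol",
    "potassium gluconate", "potassium 2-ketogluconate",
    "potassium 5-ketogluconate",
)

CLASS_A = "A"
CLASS_B = "B"
CLASS_B_DSPACBA = "B_dspaCBA"
CLASS_UNASSIGNED = "unassigned"

AXES = ("gene_content", "crispr_oligotype", "bile", "pilosotype",
        "sugar_I", "sugar_II", "sugar_III")


@dataclass
class GrowthCurve:
    """An OD600 time series on a fixed grid (hours)."""

    timepoints: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.timepoints.ndim != 1 or len(self.timepoints) < 2:
            raise ValueError("growth curve needs at least 2 timepoints")
        if len(self.timepoints) != len(self.od):
            raise ValueError("timepoints and OD readings differ in length")
        if not np.all(np.diff(self.timepoints) > 0):
            raise ValueError("timepoints must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD readings must be non-negative")


@dataclass
class PhenotypeRecord:
    strain_id: str
    api_calls: dict[str, str] = field(default_factory=dict)
    bile: str = "sensitive"
    mucus_binding: float = 0.0
    pilosotype: str = NEGATIVE          # assay evidence for functional pili
    tlr2_fold: float = 1.0
    arp: dict[tuple[str, float], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.bile not in BILE_LEVELS:
            raise ValueError(f"bile must be one of {BILE_LEVELS}")
        if not 0 <= self.mucus_binding <= 100:
            raise ValueError("mucus_binding must be a percentage in [0, 100]")
        if self.pilosotype not in (POSITIVE, NEGATIVE):
            raise ValueError("pilosotype evidence must be positive/negative")
        if self.tlr2_fold < 0:
            raise ValueError("tlr2_fold must be non-negative")
        bad = {v for v in self.api_calls.values()
               if v not in (POSITIVE, PARTIAL, NEGATIVE)}
        if bad:
            raise ValueError(f"invalid API calls {bad}")


# ---------------------------------------------------------------------------
# growth-curve statistics
# ---------------------------------------------------------------------------

def trapezoid_auc(curve: GrowthCurve) -> float:
    """Area under the growth curve (OD*h), trapezoidal rule on its own grid."""
    return float(np.trapezoid(curve.od, curve.timepoints))


def compute_arp(sample_curve: GrowthCurve, control_curve: GrowthCurve) -> float:
    """Area reduction percentage of a pathogen grown with strain supernatant.

    100 x (AUC_control - AUC_sample) / AUC_control.  Negative values mean
    the sample grew above the control (inverse effect) and are returned
    as-is.
    """
    if (len(sample_curve.timepoints) != len(control_curve.timepoints)
            or not np.allclose(sample_curve.timepoints,
                               control_curve.timepoints)):
        raise ValueError("sample and control curves must share the time grid")
    auc_control = trapezoid_auc(control_curve)
    if auc_control <= 0:
        raise ValueError("control AUC must be positive")
    return 100.0 * (auc_control - trapezoid_auc(sample_curve)) / auc_control


def mucus_binding_percent(bound_signal: float, total_signal: float) -> float:
    """Percentage of radiolabel signal in the mucus-bound fraction."""
    if total_signal <= 0:
        raise ValueError("total signal must be positive")
    if bound_signal < 0 or bound_signal > total_signal:
        raise ValueError("bound signal must lie in [0, total]")
    return 100.0 * bound_signal / total_signal


# ---------------------------------------------------------------------------
# pilosotype
# ---------------------------------------------------------------------------

def pilosotype_call(matrix_row: Mapping[str, int],
                    pili_gene_tags: Sequence[str],
                    phenotype_evidence: str | None = None) -> str:
    """Functional-pili status from genotype plus optional assay evidence.

    Positive requires every pilin/sortase gene present; when assay
    evidence (immunoblot / EM / binding assay) is supplied it must also be
    positive — an intact cluster with negative binding evidence is called
    negative (pili production impaired by mutation or promoter decay).
    """
    if not pili_gene_tags:
        raise ValueError("pili_gene_tags must not be empty")
    genomic = all(matrix_row.get(tag, 0) == 1 for tag in pili_gene_tags)
    if not genomic:
        return NEGATIVE
    if phenotype_evidence is not None:
        return POSITIVE if phenotype_evidence == POSITIVE else NEGATIVE
    return POSITIVE


@dataclass(frozen=True)
class GroupCount:
    positive: int
    negative: int
    total: int
    percent: float


def group_contingency(calls: Mapping[str, str],
                      group_labels: Mapping[str, str],
                      test_pair: tuple[str, str] | None = None,
                      ) -> tuple[dict[str, GroupCount], float]:
    """Per-group positive/negative tallies plus a 2x2 association test.

    ``calls`` maps strain -> positive/negative; ``group_labels`` maps
    strain -> group.  The Fisher exact test (two-sided) compares
    ``test_pair`` (default: the two largest groups).
    """
    from .pan_core import truncate_percent

    missing = set(calls) - set(group_labels)
    if missing:
        raise ValueError(f"strains without group label: {sorted(missing)}")
    tallies: dict[str, list[int]] = {}
    for strain, call in calls.items():
        group = group_labels[strain]
        pos_neg = tallies.setdefault(group, [0, 0])
        pos_neg[0 if call == POSITIVE else 1] += 1
    counts = {g: GroupCount(positive=p, negative=n, total=p + n,
                            percent=truncate_percent(p, p + n))
              for g, (p, n) in tallies.items()}
    if test_pair is None:
        ordered = sorted(counts, key=lambda g: (-counts[g].total, g))
        if len(ordered) < 2:
            raise ValueError("need at least two groups for the association test")
        test_pair = (ordered[0], ordered[1])
    a, b = (counts[g] for g in test_pair)
    _, p_value = fisher_exact([[a.positive, a.negative],
                               [b.positive, b.negative]],
                              alternative="two-sided")
    return counts, float(p_value)


# ---------------------------------------------------------------------------
# sugar groups and the geno-phenotype classifier
# ---------------------------------------------------------------------------

_CALL_WEIGHT = {POSITIVE: 1.0, PARTIAL: 0.5, NEGATIVE: 0.0}


def sugar_group_scores(api_calls: Mapping[str, str]) -> tuple[float, float, float]:
    """Fraction of each sugar group fermented (partial counts 0.5)."""

    def score(group: Sequence[str]) -> float:
        return sum(_CALL_WEIGHT[api_calls.get(s, NEGATIVE)]
                   for s in group) / len(group)

    return (score(SUGAR_GROUP_I), score(SUGAR_GROUP_II),
            score(SUGAR_GROUP_III))


@dataclass
class AxisConfig:
    """Tunable parameters of the geno-phenotype scoring."""

    pili_gene_tags: tuple[str, ...] = ()
    spacba_island_tags: tuple[str, ...] = ()     # defaults to pili_gene_tags
    gene_content_bounds: tuple[float, float] = (0.85, 1.0)
    bile_scores: dict[str, float] = field(default_factory=lambda: {
        "resistant": 1.0, "moderately_resistant": 0.67,
        "poorly_resistant": 0.33, "sensitive": 0.0})
    b_cutoff: float = 0.6
    a_cutoff: float = 0.4

    def __post_init__(self) -> None:
        if not self.spacba_island_tags:
            self.spacba_island_tags = tuple(self.pili_gene_tags)
        if not self.a_cutoff < self.b_cutoff:
            raise ValueError("a_cutoff must be below b_cutoff")


@dataclass(frozen=True)
class GenoPhenotype:
    strain_id: str
    axis_scores: dict[str, float]
    mean_score: float
    genophenotype_class: str


def score_genophenotype(presence_row: Mapping[str, int],
                        crispr_profile: CrisprProfile,
                        phenotype: PhenotypeRecord,
                        config: AxisConfig) -> GenoPhenotype:
    """Score the seven axes and assign the A / B / B_dspaCBA class."""
    if not presence_row:
        raise ValueError("missing presence row")
    if not config.pili_gene_tags:
        raise ValueError("AxisConfig.pili_gene_tags must be configured")
    shared_fraction = float(np.mean(list(presence_row.values())))
    lo, hi = config.gene_content_bounds
    gene_axis = float(np.clip((shared_fraction - lo) / (hi - lo), 0.0, 1.0))
    crispr_axis = (sum(1 for s in crispr_profile.spacer_status if s == CONSERVED)
                   / len(crispr_profile.spacer_status))
    bile_axis = config.bile_scores[phenotype.bile]
    pilosotype = pilosotype_call(presence_row, config.pili_gene_tags,
                                 phenotype.pilosotype)
    pili_axis = 1.0 if pilosotype == POSITIVE else 0.0
    s1, s2, s3 = sugar_group_scores(phenotype.api_calls)
    axes = {
        "gene_content": gene_axis,
        "crispr_oligotype": crispr_axis,
        "bile": bile_axis,
        "pilosotype": pili_axis,
        "sugar_I": s1,
        "sugar_II": 1.0 - s2,
        "sugar_III": 1.0 - s3,
    }
    mean_score = float(np.mean([axes[a] for a in AXES]))
    island_present = all(presence_row.get(t, 0) == 1
                         for t in config.spacba_island_tags)
    if mean_score >= config.b_cutoff:
        cls = CLASS_B if island_present else CLASS_B_DSPACBA
    elif mean_score <= config.a_cutoff:
        cls = CLASS_A
    else:
        cls = CLASS_UNASSIGNED
    return GenoPhenotype(strain_id=phenotype.strain_id, axis_scores=axes,
                         mean_score=mean_score, genophenotype_class=cls)


def write_phenotype_table(records: Sequence[PhenotypeRecord], path) -> None:
    """Phenotype TSV: one row per strain, one ``api:`` column per substrate."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "strain": rec.strain_id, "bile": rec.bile,
            "mucus_binding": round(rec.mucus_binding, 3),
            "pilosotype": rec.pilosotype,
            "tlr2_fold": round(rec.tlr2_fold, 3),
        }
        for sugar in API50CH_SUBSTRATES:
            row[f"api:{sugar}"] = rec.api_calls.get(sugar, NEGATIVE)
        for (pathogen, ph), value in sorted(rec.arp.items()):
            row[f"arp:{pathogen}:{ph}"] = round(value, 3)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_phenotype_table(path) -> list[PhenotypeRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"strain": str})
    records = []
    for _, row in df.iterrows():
        api = {col[len("api:"):]: row[col]
               for col in df.columns if col.startswith("api:")}
        arp = {}
        for col in df.columns:
            if col.startswith("arp:"):
                _, pathogen, ph = col.split(":", 2)
                arp[(pathogen, float(ph))] = float(row[col])
        records.append(PhenotypeRecord(
            strain_id=row["strain"], api_calls=api, bile=row["bile"],
            mucus_binding=float(row["mucus_binding"]),
            pilosotype=row["pilosotype"], tlr2_fold=float(row["tlr2_fold"]),
            arp=arp))
    return records


def cohort_genophenotype_report(results: Sequence[GenoPhenotype],
                                niche_labels: Mapping[str, str],
                                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-niche class counts plus per-niche axis means (radar-plot table)."""
    classes = (CLASS_A, CLASS_B, CLASS_B_DSPACBA, CLASS_UNASSIGNED)
    rows = {}
    axis_rows: dict[str, list[dict[str, float]]] = {}
    for res in results:
        niche = niche_labels.get(res.strain_id, "other")
        row = rows.setdefault(niche, {c: 0 for c in classes})
        row[res.genophenotype_class] += 1
        axis_rows.setdefault(niche, []).append(res.axis_scores)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=list(classes))
    counts.index.name = "niche"
    counts = counts.sort_index()
    means = pd.DataFrame.from_dict(
        {niche: {axis: float(np.mean([r[axis] for r in rs]))
                 for axis in AXES}
         for niche, rs in axis_rows.items()}, orient="index", columns=list(AXES))
    means.index.name = "niche"
    return counts, means.sort_index()
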