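"""Synthetic strain cohorts with the statistical structure the pipeline assumes.

The generator emulates a reference-centric view of a bacterial species
radiating into ecological niches:

* a reference chromosome with ORF-like genes, a configurable number of
  contiguous genomic islands, and an embedded Type II-A CRISPR-Cas locus;
* strains derived from the reference by **island-level gene loss**
  (all-or-none per island, with niche-dependent probabilities),
  independent background gene loss, point substitutions at a per-niche
  rate, and CRISPR spacer turnover (a niche keeps only the trailing,
  ancestral part of the reference spacer array);
* phenotypes coupled deterministically to the true genotype through
  per-trait rules (bile resistance from the taurine-transporter island,
  pilosotype from the pili island, sugar fermentation groups from the
  metabolic islands), then corrupted by a small flip probability.

Ground truth (lost genes, retained spacers, noise-free phenotypes and the
intended geno-phenotype class) is recorded on each strain so downstream
calls can be scored against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .align import revcomp
from .crispr_typing import ABSENT, CONSERVED, CrisprProfile, ReferenceCrispr
from .genophenotype import (API50CH_SUBSTRATES, AxisConfig, GrowthCurve,
                            NEGATIVE, POSITIVE, PhenotypeRecord,
                            SUGAR_GROUP_I, SUGAR_GROUP_II, SUGAR_GROUP_III,
                            compute_arp, score_genophenotype)
from .io_core import GeneModel, ReferenceAnnotation, StrainGenome

# island identities used by the default reference layout and profiles
BILE_ISLAND = "GI1"          # taurine ABC transporter region
PILI_ISLAND = "GI2"          # spaCBA pilin cluster + sortase
PROPHAGE_ISLAND = "GI3"
EPS_ISLAND = "GI4"
FUCOSE_ISLAND = "GI5"        # sugar group I utilisation
DAIRY_SUGAR_ISLAND = "GI6"   # lactose/maltose-type PTS, sugar groups II/III

ARP_PATHOGENS = ("E. coli", "Y. enterocolitica", "L. monocytogenes")
ARP_PH_LEVELS = (5.0, 6.2)

_ISLAND_ROLES = {
    BILE_ISLAND: (("taurine ABC transporter", "P"),
                  ("taurine transport ATP-binding protein", "P"),
                  ("transcriptional regulator", "K")),
    PILI_ISLAND: (("SpaC pilin", "N"), ("SpaB pilin", "N"),
                  ("SpaA pilin", "N"), ("pilin-specific sortase", "N"),
                  ("conserved protein", "S")),
    PROPHAGE_ISLAND: (("phage-related protein", "S"),
                      ("phage integrase", "L")),
    EPS_ISLAND: (("EPS biosynthesis glycosyltransferase", "M"),
                 ("polysaccharide export protein", "M")),
    FUCOSE_ISLAND: (("L-fucose isomerase", "G"), ("fucose transporter", "G"),
                    ("alpha-L-fucosidase", "G"),
                    ("fucose operon repressor", "K")),
    DAIRY_SUGAR_ISLAND: (("lactose PTS EIIA component", "G"),
                         ("phospho-beta-galactosidase", "G"),
                         ("maltose ABC transporter", "G"),
                         ("galactitol PTS EIIC component", "G")),
}

_BACKGROUND_PRODUCTS = ("conserved protein", "hypothetical protein",
                        "ABC transporter", "transcriptional regulator",
                        "ribosomal protein", "aminotransferase",
                        "cell wall hydrolase", "tRNA ligase")
_BACKGROUND_COGS = "JKLMNOPQRSTUVEFGHIC"

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = ["".join((a, b, c)) for a in "ACGT" for b in "ACGT" for c in "ACGT"]
_SENSE_CODONS = [c for c in _CODONS if c not in _STOP_CODONS]


@dataclass(frozen=True)
class TraitRule:
    """Deterministic genotype condition for one phenotypic trait.

    ``island_id`` ties the trait to island presence (positive when the
    island is present, or the reverse); ``constant`` makes the trait
    genotype-independent.
    """

    island_id: str | None = None
    positive_when_present: bool = True
    constant: bool | None = None

    def evaluate(self, island_present: Mapping[str, bool]) -> bool:
        if self.island_id is None:
            if self.constant is None:
                raise ValueError("rule needs an island_id or a constant")
            return self.constant
        present = island_present.get(self.island_id, True)
        return present if self.positive_when_present else not present


def _default_rules(antagonism: bool) -> dict[str, TraitRule]:
    rules: dict[str, TraitRule] = {
        "bile": TraitRule(island_id=BILE_ISLAND),
        "pilosotype": TraitRule(island_id=PILI_ISLAND),
        "antagonism": TraitRule(constant=antagonism),
    }
    for sugar in SUGAR_GROUP_I:
        rules[sugar] = TraitRule(island_id=FUCOSE_ISLAND)
    for sugar in SUGAR_GROUP_II + SUGAR_GROUP_III:
        rules[sugar] = TraitRule(island_id=DAIRY_SUGAR_ISLAND)
    return rules


#: genotype-independent baseline of the fermentation panel: substrates a
#: typical strain of this species ferments regardless of island content
_BASELINE_POSITIVE = {
    "D-galactose", "D-glucose", "D-fructose", "D-mannose", "D-mannitol",
    "D-sorbitol", "N-acetylglucosamine", "amygdalin", "arbutin", "salicin",
    "D-cellobiose", "D-trehalose", "D-melezitose", "gentiobiose",
    "D-tagatose", "L-arabinose",
}
_BASELINE_PARTIAL = {"esculin", "D-ribose"}


def baseline_api_calls() -> dict[str, str]:
    calls = {}
    for sugar in API50CH_SUBSTRATES:
        if sugar in _BASELINE_POSITIVE:
            calls[sugar] = POSITIVE
        elif sugar in _BASELINE_PARTIAL:
            calls[sugar] = "partial"
        else:
            calls[sugar] = NEGATIVE
    return calls


@dataclass
class NicheProfile:
    """Generator parameters of one ecological niche."""

    niche_name: str
    island_loss_probs: dict[str, float]
    background_loss_prob: float
    snp_rate: float
    spacer_retention: int
    phenotype_rules: dict[str, TraitRule] = field(default_factory=dict)
    phenotype_noise: float = 0.0

    def __post_init__(self) -> None:
        for island, p in self.island_loss_probs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{island}: loss probability {p} outside [0, 1]")
        if not 0 <= self.background_loss_prob <= 1:
            raise ValueError("background_loss_prob outside [0, 1]")
        if not 0 <= self.snp_rate <= 0.3:
            raise ValueError("snp_rate outside [0, 0.3]")
        if not 0 <= self.phenotype_noise <= 0.1:
            raise ValueError("phenotype_noise outside [0, 0.1]")
        if self.spacer_retention < 0:
            raise ValueError("spacer_retention must be >= 0")


def default_profiles() -> dict[str, NicheProfile]:
    """Niche profiles calibrated to the qualitative niche contrasts:

    dairy-adapted strains lose the pili, fucose and bile islands, keep the
    lactose/maltose island, diverge more at the nucleotide level and keep
    only the 6 ancestral reference spacers; intestinal strains are
    reference-like.  Vaginal and oral strains are dairy-like in gene
    content (geno-phenotype A) but bile resistant in the vaginal case;
    clinical isolates are an eclectic intermediate pool.
    """
    return {
        "dairy": NicheProfile(
            niche_name="dairy",
            island_loss_probs={BILE_ISLAND: 0.7, PILI_ISLAND: 0.85,
                               PROPHAGE_ISLAND: 0.5, EPS_ISLAND: 0.3,
                               FUCOSE_ISLAND: 0.8, DAIRY_SUGAR_ISLAND: 0.05},
            background_loss_prob=0.02, snp_rate=0.02, spacer_retention=6,
            phenotype_rules=_default_rules(antagonism=False),
            phenotype_noise=0.02),
        "intestinal": NicheProfile(
            niche_name="intestinal",
            island_loss_probs={BILE_ISLAND: 0.05, PILI_ISLAND: 0.2,
                               PROPHAGE_ISLAND: 0.2, EPS_ISLAND: 0.1,
                               FUCOSE_ISLAND: 0.05, DAIRY_SUGAR_ISLAND: 0.85},
            background_loss_prob=0.005, snp_rate=0.005, spacer_retention=24,
            phenotype_rules=_default_rules(antagonism=True),
            phenotype_noise=0.02),
        "vaginal": NicheProfile(
            niche_name="vaginal",
            island_loss_probs={BILE_ISLAND: 0.05, PILI_ISLAND: 0.9,
                               PROPHAGE_ISLAND: 0.4, EPS_ISLAND: 0.3,
                               FUCOSE_ISLAND: 0.7, DAIRY_SUGAR_ISLAND: 0.2},
            background_loss_prob=0.015, snp_rate=0.015, spacer_retention=8,
            phenotype_rules=_default_rules(antagonism=True),
            phenotype_noise=0.02),
        "oral": NicheProfile(
            niche_name="oral",
            island_loss_probs={BILE_ISLAND: 0.6, PILI_ISLAND: 0.9,
                               PROPHAGE_ISLAND: 0.4, EPS_ISLAND: 0.3,
                               FUCOSE_ISLAND: 0.7, DAIRY_SUGAR_ISLAND: 0.3},
            background_loss_prob=0.015, snp_rate=0.015, spacer_retention=8,
            phenotype_rules=_default_rules(antagonism=True),
            phenotype_noise=0.02),
        "clinical": NicheProfile(
            niche_name="clinical",
            island_loss_probs={BILE_ISLAND: 0.25, PILI_ISLAND: 0.5,
                               PROPHAGE_ISLAND: 0.3, EPS_ISLAND: 0.2,
                               FUCOSE_ISLAND: 0.3, DAIRY_SUGAR_ISLAND: 0.5},
            background_loss_prob=0.01, snp_rate=0.01, spacer_retention=12,
            phenotype_rules=_default_rules(antagonism=True),
            phenotype_noise=0.02),
        "other": NicheProfile(
            niche_name="other",
            island_loss_probs={BILE_ISLAND: 0.3, PILI_ISLAND: 0.5,
                               PROPHAGE_ISLAND: 0.3, EPS_ISLAND: 0.2,
                               FUCOSE_ISLAND: 0.4, DAIRY_SUGAR_ISLAND: 0.4},
            background_loss_prob=0.01, snp_rate=0.01, spacer_retention=12,
            phenotype_rules=_default_rules(antagonism=True),
            phenotype_noise=0.02),
    }


#: cohort composition mirroring a 100-strain multi-niche collection
DEFAULT_NICHE_MIX = {"dairy": 23, "intestinal": 16, "vaginal": 8, "oral": 3,
                     "clinical": 33, "other": 17}


def disjoint_contrast_profiles() -> dict[str, NicheProfile]:
    """Two-niche study condition for clustering-recovery experiments.

    The niches lose disjoint island sets, so gene content carries an
    unambiguous niche signature: the dairy-like niche loses the bile,
    pili and fucose islands, the intestinal-like niche the lactose/maltose
    island (and occasionally the prophage).
    """
    return {
        "dairy": NicheProfile(
            niche_name="dairy",
            island_loss_probs={BILE_ISLAND: 0.9, PILI_ISLAND: 0.9,
                               FUCOSE_ISLAND: 0.9},
            background_loss_prob=0.02, snp_rate=0.02, spacer_retention=6,
            phenotype_rules=_default_rules(antagonism=False),
            phenotype_noise=0.02),
        "intestinal": NicheProfile(
            niche_name="intestinal",
            island_loss_probs={PROPHAGE_ISLAND: 0.3, DAIRY_SUGAR_ISLAND: 0.9},
            background_loss_prob=0.005, snp_rate=0.005, spacer_retention=24,
            phenotype_rules=_default_rules(antagonism=True),
            phenotype_noise=0.02),
    }


@dataclass
class SimulationTruth:
    """Ground truth recorded for one simulated strain."""

    lost_gene_tags: set[str] = field(default_factory=set)
    retained_spacer_indices: set[int] = field(default_factory=set)
    true_phenotypes: dict[str, object] = field(default_factory=dict)


@dataclass
class SimulatedReference:
    """A simulated reference: annotation, chromosome and CRISPR geometry."""

    annotation: ReferenceAnnotation
    sequence: str
    crispr: ReferenceCrispr | None = None
    crispr_span: tuple[int, int] | None = None   # 0-based [start, end)
    array_span: tuple[int, int] | None = None

    def axis_config(self, **overrides) -> AxisConfig:
        """Geno-phenotype axis configuration bound to this reference."""
        pili_tags = tuple(g.locus_tag for g in self.annotation.genes
                          if g.island_id == PILI_ISLAND)
        return AxisConfig(pili_gene_tags=pili_tags, **overrides)


# ---------------------------------------------------------------------------
# reference simulation
# ---------------------------------------------------------------------------

def _random_orf(rng: np.random.Generator, length: int) -> str:
    n_codons = length // 3
    middle = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    return "ATG" + "".join(_SENSE_CODONS[i] for i in middle) + "TAA"


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def simulate_reference_crispr(seed: int, n_spacers: int = 24, n_cas: int = 4,
                              spacer_length: int = 30, repeat_length: int = 36,
                              ) -> ReferenceCrispr:
    """Random Type II-A-style locus descriptor: ordered spacers + cas genes."""
    rng = np.random.default_rng([seed, 2])
    spacers = []
    seen = set()
    while len(spacers) < n_spacers:
        seq = _random_dna(rng, spacer_length)
        if seq not in seen:
            seen.add(seq)
            spacers.append((len(spacers) + 1, seq))
    names = ["cas9", "cas1", "cas2", "csn2"]
    cas = []
    for i in range(n_cas):
        name = names[i] if i < len(names) else f"cas_{i + 1}"
        cas.append((name, _random_orf(rng, int(rng.integers(300, 500)) * 3)))
    return ReferenceCrispr(spacers=spacers, cas_genes=cas,
                           repeat=_random_dna(rng, repeat_length),
                           leader=_random_dna(rng, 100))


def _crispr_locus(crispr: ReferenceCrispr,
                  rng: np.random.Generator) -> tuple[str, int, int]:
    """Locus sequence plus the [start, end) of the spacer array within it."""
    parts = [crispr.leader or ""]
    for _, seq in crispr.cas_genes:
        parts.append(seq)
        parts.append(_random_dna(rng, 25))
    head = "".join(parts)
    array = crispr.repeat + "".join(seq + crispr.repeat
                                    for _, seq in crispr.spacers)
    return head + array, len(head), len(head) + len(array)


def simulate_reference(n_genes: int = 300, n_islands: int = 6,
                       island_sizes: Sequence[int] = (8, 8, 8, 8, 8, 8),
                       genome_length: int = 300_000, seed: int = 0,
                       crispr: ReferenceCrispr | None = None,
                       genome_id: str = "REF") -> SimulatedReference:
    """Simulate an annotated reference chromosome.

    Genes are random non-overlapping ORF-like segments; islands are
    contiguous runs of genes labelled GI1..GIn in chromosome order, with
    role-specific products for the default six-island layout.  When a
    CRISPR descriptor is supplied its locus is embedded downstream of the
    last gene.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([seed, 1])
    island_sizes = list(island_sizes)
    if len(island_sizes) != n_islands:
        raise ValueError("island_sizes length must equal n_islands")
    if any(s < 5 for s in island_sizes):
        raise ValueError("each island must span at least 5 genes")
    if sum(island_sizes) > n_genes:
        raise ValueError("island sizes exceed the gene count")

    lengths = (rng.integers(134, 267, size=n_genes) * 3).astype(int)
    locus_seq = ""
    array_lo = array_hi = 0
    if crispr is not None:
        locus_seq, array_lo, array_hi = _crispr_locus(crispr, rng)
    min_gap = 20
    needed = int(lengths.sum()) + (n_genes + 1) * min_gap + len(locus_seq) + 100
    if needed > genome_length:
        raise ValueError(
            f"infeasible packing: {needed} bp needed, genome_length {genome_length}")

    # place islands as disjoint runs with >= 2 background genes between them
    free = n_genes - sum(island_sizes)
    slots = n_islands + 1
    interior_min = 2
    base = np.zeros(slots, dtype=int)
    base[1:-1] = interior_min
    extra = free - int(base.sum())
    if extra < 0:
        raise ValueError("not enough background genes to separate islands")
    base += rng.multinomial(extra, np.full(slots, 1.0 / slots))
    island_of_gene: dict[int, str] = {}
    cursor = 0
    for isl in range(n_islands):
        cursor += int(base[isl])
        for g in range(cursor, cursor + island_sizes[isl]):
            island_of_gene[g] = f"GI{isl + 1}"
        cursor += island_sizes[isl]

    # distribute remaining intergenic length over the gaps
    spare = genome_length - int(lengths.sum()) - len(locus_seq) \
        - (n_genes + 1) * min_gap - 100
    gaps = np.full(n_genes + 1, min_gap, dtype=int)
    gaps += rng.multinomial(spare, np.full(n_genes + 1, 1.0 / (n_genes + 1)))

    genes: list[GeneModel] = []
    parts: list[str] = []
    pos = 0
    tag_width = max(5, len(str(n_genes * 10)))
    island_counters: dict[str, int] = {}
    for gi in range(n_genes):
        gap = _random_dna(rng, int(gaps[gi]))
        parts.append(gap)
        pos += len(gap)
        orf = _random_orf(rng, int(lengths[gi]))
        strand = "+" if rng.random() < 0.5 else "-"
        parts.append(orf if strand == "+" else revcomp(orf))
        island = island_of_gene.get(gi)
        if island is not None and island in _ISLAND_ROLES:
            k = island_counters.get(island, 0)
            island_counters[island] = k + 1
            roles = _ISLAND_ROLES[island]
            product, cog = roles[k % len(roles)]
            is_is = k >= len(roles) and (k - len(roles)) % 3 == 0
            if is_is:
                product, cog = "transposase", "L"
        else:
            product = _BACKGROUND_PRODUCTS[int(rng.integers(0, len(_BACKGROUND_PRODUCTS)))]
            cog = _BACKGROUND_COGS[int(rng.integers(0, len(_BACKGROUND_COGS)))]
            is_is = rng.random() < 0.01
            if is_is:
                product, cog = "transposase", "L"
        genes.append(GeneModel(
            locus_tag=f"SYN_{(gi + 1) * 10:0{tag_width}d}",
            start=pos + 1, end=pos + len(orf), strand=strand,
            product=product, cog_category=cog, island_id=island,
            is_IS_element=is_is))
        pos += len(orf)
    tail_gap = _random_dna(rng, int(gaps[n_genes]))
    parts.append(tail_gap)
    pos += len(tail_gap)
    crispr_span = array_span = None
    if crispr is not None:
        crispr_span = (pos, pos + len(locus_seq))
        array_span = (pos + array_lo, pos + array_hi)
        parts.append(locus_seq)
        pos += len(locus_seq)
    parts.append(_random_dna(rng, genome_length - pos))
    sequence = "".join(parts)
    annotation = ReferenceAnnotation(genome_id=genome_id,
                                     genome_length=len(sequence), genes=genes)
    return SimulatedReference(annotation=annotation, sequence=sequence,
                              crispr=crispr, crispr_span=crispr_span,
                              array_span=array_span)


def default_reference(seed: int = 0, n_genes: int = 300,
                      genome_length: int = 300_000) -> SimulatedReference:
    """The standard test reference: 300 genes, 6 islands, embedded CRISPR."""
    crispr = simulate_reference_crispr(seed=seed)
    return simulate_reference(n_genes=n_genes, n_islands=6,
                              island_sizes=(8, 8, 8, 8, 8, 8),
                              genome_length=genome_length, seed=seed,
                              crispr=crispr)


# ---------------------------------------------------------------------------
# strain simulation
# ---------------------------------------------------------------------------

def _mutate(seq: str, snp_rate: float, rng: np.random.Generator) -> str:
    if snp_rate <= 0:
        return seq
    from .align import encode

    enc = encode(seq).copy()
    n = rng.binomial(len(enc), snp_rate)
    if n == 0:
        return seq
    positions = rng.choice(len(enc), size=n, replace=False)
    keep = enc[positions] < 4
    positions = positions[keep]
    shift = rng.integers(1, 4, size=len(positions))
    enc[positions] = (enc[positions] + shift) % 4
    return "".join("ACGTN"[b] for b in enc)


def _true_phenotypes(profile: NicheProfile,
                     island_present: Mapping[str, bool]) -> dict[str, object]:
    truth: dict[str, object] = {}
    api = baseline_api_calls()
    for trait, rule in profile.phenotype_rules.items():
        value = rule.evaluate(island_present)
        if trait == "bile":
            truth["bile"] = "resistant" if value else "sensitive"
        elif trait == "pilosotype":
            truth["pilosotype"] = POSITIVE if value else NEGATIVE
        elif trait == "antagonism":
            truth["antagonism"] = bool(value)
        else:
            api[trait] = POSITIVE if value else NEGATIVE
    truth["api_calls"] = api
    return truth


def simulate_strain(reference: SimulatedReference, profile: NicheProfile,
                    seed: int, strain_id: str | None = None,
                    niche: str | None = None) -> StrainGenome:
    """Derive one strain from the reference under a niche profile.

    Island loss is all-or-none per island (regions are lost as blocks);
    background genes are lost independently; everything retained is
    mutated by substitutions at ``snp_rate``; the CRISPR array keeps the
    trailing (ancestral) ``spacer_retention`` reference spacers.
    """
    rng = np.random.default_rng([seed, 3])
    annotation = reference.annotation
    islands: dict[str, list[GeneModel]] = {}
    for gene in annotation.genes:
        if gene.island_id:
            islands.setdefault(gene.island_id, []).append(gene)
    island_present = {isl: True for isl in islands}
    lost: set[str] = set()
    for isl in sorted(islands):
        p = profile.island_loss_probs.get(isl, 0.0)
        if rng.random() < p:
            island_present[isl] = False
            lost.update(g.locus_tag for g in islands[isl])
    for gene in annotation.genes:
        if gene.island_id is None and rng.random() < profile.background_loss_prob:
            lost.add(gene.locus_tag)

    retained_spacers: set[int] = set()
    edits: list[tuple[int, int, str]] = []   # (start0, end0, replacement)
    for gene in annotation.genes:
        if gene.locus_tag in lost:
            edits.append((gene.start - 1, gene.end, ""))
    if reference.crispr is not None and reference.array_span is not None:
        n_sp = reference.crispr.n_spacers
        if profile.spacer_retention > n_sp:
            raise ValueError("spacer_retention exceeds the reference array size")
        retained_spacers = set(range(n_sp - profile.spacer_retention + 1,
                                     n_sp + 1)) if profile.spacer_retention else set()
        repeat = reference.crispr.repeat or ""
        array = repeat + "".join(seq + repeat
                                 for idx, seq in reference.crispr.spacers
                                 if idx in retained_spacers)
        edits.append((reference.array_span[0], reference.array_span[1], array))
    edits.sort()
    parts = []
    cursor = 0
    for start, end, replacement in edits:
        parts.append(reference.sequence[cursor:start])
        parts.append(replacement)
        cursor = end
    parts.append(reference.sequence[cursor:])
    sequence = _mutate("".join(parts), profile.snp_rate, rng)

    truth = SimulationTruth(lost_gene_tags=lost,
                            retained_spacer_indices=retained_spacers,
                            true_phenotypes=_true_phenotypes(profile,
                                                             island_present))
    truth.true_phenotypes["intended_class"] = _intended_class(
        reference, profile, truth)
    niche = niche or profile.niche_name
    strain_id = strain_id or f"{niche[:1].upper()}{seed % 100000:05d}"
    return StrainGenome(strain_id=strain_id, niche=niche,
                        sequences=[sequence], truth=truth)


def _truth_phenotype_record(strain_id: str, truth: SimulationTruth,
                            mucus: float = 0.0, tlr2: float = 1.5,
                            arp: dict | None = None) -> PhenotypeRecord:
    return PhenotypeRecord(
        strain_id=strain_id,
        api_calls=dict(truth.true_phenotypes["api_calls"]),
        bile=("resistant" if truth.true_phenotypes.get("bile") == "resistant"
              else "sensitive"),
        mucus_binding=mucus,
        pilosotype=truth.true_phenotypes.get("pilosotype", NEGATIVE),
        tlr2_fold=tlr2, arp=arp or {})


def _intended_class(reference: SimulatedReference, profile: NicheProfile,
                    truth: SimulationTruth) -> str:
    """Class the noise-free truth would receive from the scorer."""
    row = {g.locus_tag: 0 if g.locus_tag in truth.lost_gene_tags else 1
           for g in reference.annotation.genes}
    n_sp = reference.crispr.n_spacers if reference.crispr else 24
    n_cas = reference.crispr.n_cas if reference.crispr else 4
    crispr_profile = CrisprProfile(
        strain_id="truth",
        spacer_status=[CONSERVED if i in truth.retained_spacer_indices
                       else ABSENT for i in range(1, n_sp + 1)],
        cas_status=["present"] * n_cas)
    record = _truth_phenotype_record("truth", truth)
    result = score_genophenotype(row, crispr_profile, record,
                                 reference.axis_config())
    return result.genophenotype_class


# ---------------------------------------------------------------------------
# cohorts, phenotype noise and growth curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticGrowthParams:
    """Logistic growth model: OD(t) = max_od / (1 + exp(-rate (t - t_mid)))."""

    max_od: float = 1.2
    rate: float = 0.8
    t_mid: float = 6.0
    noise_sd: float = 0.0


def simulate_growth_curve(model_params: LogisticGrowthParams,
                          inhibition_factor: float,
                          timepoints: Sequence[float],
                          seed: int = 0) -> GrowthCurve:
    """Logistic growth scaled by an inhibition factor, with Gaussian noise."""
    rng = np.random.default_rng([seed, 4])
    t = np.asarray(timepoints, dtype=float)
    od = inhibition_factor * model_params.max_od / (
        1.0 + np.exp(-model_params.rate * (t - model_params.t_mid)))
    if model_params.noise_sd > 0:
        od = od + rng.normal(0.0, model_params.noise_sd, size=len(t))
    return GrowthCurve(timepoints=t, od=np.clip(od, 0.0, None))


#: the antagonism assay grid: readings every 30 min for 15 h
ARP_TIMEPOINTS = np.arange(0.0, 15.01, 0.5)


def _flip_api(call: str) -> str:
    return NEGATIVE if call in (POSITIVE, "partial") else POSITIVE


def _noisy_phenotype(strain: StrainGenome, profile: NicheProfile,
                     rng: np.random.Generator,
                     phenotype_noise: float | None = None) -> PhenotypeRecord:
    truth = strain.truth
    noise = (profile.phenotype_noise if phenotype_noise is None
             else phenotype_noise)
    api = dict(truth.true_phenotypes["api_calls"])
    for sugar in API50CH_SUBSTRATES:
        if rng.random() < noise:
            api[sugar] = _flip_api(api[sugar])
    bile = truth.true_phenotypes.get("bile", "sensitive")
    if rng.random() < noise:
        bile = "sensitive" if bile == "resistant" else "resistant"
    pilosotype = truth.true_phenotypes.get("pilosotype", NEGATIVE)
    if rng.random() < noise:
        pilosotype = NEGATIVE if pilosotype == POSITIVE else POSITIVE
    mucus = (float(rng.uniform(5.0, 29.9)) if pilosotype == POSITIVE
             else float(rng.uniform(0.05, 2.0)))
    tlr2 = float(rng.lognormal(np.log(1.5), 0.3))
    antagonistic = bool(truth.true_phenotypes.get("antagonism", True))
    control = simulate_growth_curve(
        LogisticGrowthParams(noise_sd=0.0), 1.0, ARP_TIMEPOINTS)
    arp: dict[tuple[str, float], float] = {}
    for pathogen in ARP_PATHOGENS:
        for ph in ARP_PH_LEVELS:
            factor = (float(rng.uniform(0.3, 0.6)) if antagonistic
                      else float(rng.uniform(0.85, 1.05)))
            sample = simulate_growth_curve(
                LogisticGrowthParams(noise_sd=0.0), factor, ARP_TIMEPOINTS)
            arp[(pathogen, ph)] = compute_arp(sample, control)
    return PhenotypeRecord(strain_id=strain.strain_id, api_calls=api,
                           bile=bile, mucus_binding=mucus,
                           pilosotype=pilosotype, tlr2_fold=tlr2, arp=arp)


def simulate_cohort(reference: SimulatedReference,
                    niche_mix: Mapping[str, int] | None = None,
                    seed: int = 0,
                    profiles: Mapping[str, NicheProfile] | None = None,
                    phenotype_noise: float | None = None,
                    ) -> tuple[list[StrainGenome], list[PhenotypeRecord]]:
    """Simulate a multi-niche cohort with coupled phenotypes.

    ``phenotype_noise`` overrides every profile's flip probability when
    given.  Strain ids are niche-prefixed and stable for a fixed seed.
    """
    niche_mix = dict(DEFAULT_NICHE_MIX if niche_mix is None else niche_mix)
    profiles = dict(default_profiles() if profiles is None else profiles)
    rng = np.random.default_rng(seed)
    strains: list[StrainGenome] = []
    phenotypes: list[PhenotypeRecord] = []
    for niche, count in niche_mix.items():
        if niche not in profiles:
            raise ValueError(f"no profile for niche {niche!r}")
        profile = profiles[niche]
        for i in range(count):
            strain_seed = int(rng.integers(0, 2 ** 31 - 1))
            strain = simulate_strain(reference, profile, strain_seed,
                                     strain_id=f"{niche[:3].upper()}{i + 1:03d}",
                                     niche=niche)
            strains.append(strain)
            phenotypes.append(_noisy_phenotype(strain, profile, rng,
                                               phenotype_noise))
    return strains, phenotypes


def write_cohort(strains: Sequence[StrainGenome],
                 phenotypes: Sequence[PhenotypeRecord],
                 outdir: str | Path) -> None:
    """Write strain FASTAs, a truth JSON and the phenotype TSV to a directory."""
    import json

    from .genophenotype import write_phenotype_table
    from .io_core import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    strain_dir = outdir / "strains"
    strain_dir.mkdir(exist_ok=True)
    truth: dict[str, dict] = {}
    niches: dict[str, str] = {}
    for strain in strains:
        write_fasta([(f"{strain.strain_id}_contig{c + 1}", seq)
                     for c, seq in enumerate(strain.sequences)],
                    strain_dir / f"{strain.strain_id}.fasta")
        niches[strain.strain_id] = strain.niche
        if strain.truth is not None:
            truth[strain.strain_id] = {
                "lost_gene_tags": sorted(strain.truth.lost_gene_tags),
                "retained_spacer_indices":
                    sorted(strain.truth.retained_spacer_indices),
                "intended_class":
                    strain.truth.true_phenotypes.get("intended_class"),
            }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "niches.tsv", "w") as fh:
        fh.write("strain\tniche\n")
        for sid in sorted(niches):
            fh.write(f"{sid}\t{niches[sid]}\n")
    write_phenotype_table(phenotypes, outdir / "phenotypes.tsv")
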