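"""CRISPR spacer oligotyping against a reference Type II-A locus.

Each strain is profiled against the reference CRISPR array (ordered
spacers) and cas genes: every spacer is scored ``conserved``, ``partial``
or ``absent`` and every cas gene ``present`` or ``absent``.  Spacers are
short (tens of bp), so their thresholds are stricter than gene-level
presence calls: conserved requires >= 90% identity over >= 95% of the
spacer, partial >= 80% identity over >= 50%.  A single point mutation in a
typical spacer therefore still scores conserved, while a half-deleted
spacer scores partial.  Cas genes reuse the gene-level presence rule.

Spacers can also be searched against a phage/plasmid FASTA database with
a word-size-7 seed-and-extend scan (protospacer search).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

from .align import (DEFAULT_SCORING, SequenceSearcher, revcomp,
                    semiglobal_identity)
from .io_core import StrainGenome, read_fasta
from .ortholog_calling import DEFAULT_THRESHOLDS, Thresholds

MIN_SPACER_LENGTH = 15

CONSERVED = "conserved"
PARTIAL = "partial"
ABSENT = "absent"


class SpacerThresholds(NamedTuple):
    conserved_identity: float = 0.90
    conserved_coverage: float = 0.95
    partial_identity: float = 0.80
    partial_coverage: float = 0.50


DEFAULT_SPACER_THRESHOLDS = SpacerThresholds()


@dataclass
class ReferenceCrispr:
    """Ordered reference spacers plus cas genes (and optional scaffold parts)."""

    spacers: list[tuple[int, str]]          # (1-based index, sequence)
    cas_genes: list[tuple[str, str]]        # (name, sequence)
    repeat: str | None = None
    leader: str | None = None

    def __post_init__(self) -> None:
        if not self.spacers:
            raise ValueError("reference CRISPR must have at least one spacer")
        seqs = [s for _, s in self.spacers]
        if len(set(seqs)) != len(seqs):
            raise ValueError("spacer sequences must be unique")

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    @property
    def n_cas(self) -> int:
        return len(self.cas_genes)

    @classmethod
    def from_fasta(cls, spacer_fasta, cas_fasta,
                   repeat: str | None = None,
                   leader: str | None = None) -> "ReferenceCrispr":
        spacers = [(i + 1, seq) for i, (_, seq) in
                   enumerate(read_fasta(spacer_fasta))]
        cas = list(read_fasta(cas_fasta))
        return cls(spacers=spacers, cas_genes=cas, repeat=repeat, leader=leader)


@dataclass
class CrisprProfile:
    strain_id: str
    spacer_status: list[str]                # conserved / partial / absent
    cas_status: list[str]                   # present / absent

    def __post_init__(self) -> None:
        bad = set(self.spacer_status) - {CONSERVED, PARTIAL, ABSENT}
        if bad:
            raise ValueError(f"invalid spacer statuses {bad}")
        bad = set(self.cas_status) - {"present", "absent"}
        if bad:
            raise ValueError(f"invalid cas statuses {bad}")

    @property
    def shared_spacer_count(self) -> int:
        return sum(1 for s in self.spacer_status if s == CONSERVED)


def type_spacer(spacer_seq: str, strain_seqs: Sequence[str],
                thresholds: SpacerThresholds = DEFAULT_SPACER_THRESHOLDS,
                searcher: SequenceSearcher | None = None) -> str:
    """Score one reference spacer in a strain (both strands searched).

    The conserved tier is judged on the best end-to-end placement of the
    spacer, so that point mutations near a spacer edge count against
    identity rather than being trimmed away as lost coverage; a spacer is
    also conserved if a trimmed local match still spans >= 95% of it.
    The partial tier uses the best local alignment, which lets a
    half-deleted spacer qualify through its intact half.
    """
    if len(spacer_seq) < MIN_SPACER_LENGTH:
        raise ValueError(f"spacer shorter than {MIN_SPACER_LENGTH} bp")
    if searcher is None:
        searcher = SequenceSearcher(strain_seqs)
    if semiglobal_identity(spacer_seq, searcher.contigs) >= thresholds.conserved_identity:
        return CONSERVED
    hit = searcher.best_local(spacer_seq)
    if (hit.identity >= thresholds.conserved_identity
            and hit.coverage >= thresholds.conserved_coverage):
        return CONSERVED
    # a partial remnant must carry at least as much alignment evidence as
    # an intact half-spacer, otherwise chance matches in a genome-sized
    # background would surface as partial conservation
    min_score = DEFAULT_SCORING.match * len(spacer_seq) / 2
    if (hit.identity >= thresholds.partial_identity
            and hit.coverage >= thresholds.partial_coverage
            and hit.score >= min_score):
        return PARTIAL
    return ABSENT


def type_cas(cas_seq: str, strain_seqs: Sequence[str],
             thresholds: Thresholds = DEFAULT_THRESHOLDS,
             searcher: SequenceSearcher | None = None) -> str:
    """Presence of one cas gene, using the gene-level identity/coverage rule."""
    if searcher is None:
        searcher = SequenceSearcher(strain_seqs)
    hit = searcher.best_local(cas_seq)
    present = (hit.identity >= thresholds.identity
               and hit.coverage >= thresholds.coverage)
    return "present" if present else "absent"


def oligotype_strain(reference: ReferenceCrispr,
                     strain: StrainGenome | Sequence[str],
                     strain_id: str | None = None,
                     spacer_thresholds: SpacerThresholds = DEFAULT_SPACER_THRESHOLDS,
                     cas_thresholds: Thresholds = DEFAULT_THRESHOLDS) -> CrisprProfile:
    if isinstance(strain, StrainGenome):
        seqs = strain.sequences
        strain_id = strain_id or strain.strain_id
    else:
        seqs = list(strain)
        strain_id = strain_id or "strain"
    searcher = SequenceSearcher(seqs)
    spacer_status = [type_spacer(seq, seqs, spacer_thresholds, searcher)
                     for _, seq in reference.spacers]
    cas_status = [type_cas(seq, seqs, cas_thresholds, searcher)
                  for _, seq in reference.cas_genes]
    return CrisprProfile(strain_id=strain_id, spacer_status=spacer_status,
                         cas_status=cas_status)


def oligotype_cohort(reference: ReferenceCrispr,
                     strains: Sequence[StrainGenome],
                     spacer_thresholds: SpacerThresholds = DEFAULT_SPACER_THRESHOLDS,
                     cas_thresholds: Thresholds = DEFAULT_THRESHOLDS,
                     ) -> tuple[list[CrisprProfile], dict[str, int]]:
    """Profile every strain; also return per-strain conserved-spacer counts."""
    profiles = [oligotype_strain(reference, s,
                                 spacer_thresholds=spacer_thresholds,
                                 cas_thresholds=cas_thresholds)
                for s in strains]
    shared = {p.strain_id: p.shared_spacer_count for p in profiles}
    return profiles, shared


def profiles_to_table(profiles: Sequence[CrisprProfile],
                      reference: ReferenceCrispr):
    """Profiles as a DataFrame: one C/P/A column per spacer, 1/0 per cas gene."""
    import pandas as pd

    code = {CONSERVED: "C", PARTIAL: "P", ABSENT: "A"}
    rows = {}
    for p in profiles:
        row = {f"spacer_{i}": code[s]
               for (i, _), s in zip(reference.spacers, p.spacer_status)}
        row.update({name: (1 if s == "present" else 0)
                    for (name, _), s in zip(reference.cas_genes, p.cas_status)})
        rows[p.strain_id] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def table_to_profiles(df) -> dict[str, CrisprProfile]:
    """Inverse of :func:`profiles_to_table` (extra columns are ignored)."""
    code = {"C": CONSERVED, "P": PARTIAL, "A": ABSENT}
    spacer_cols = sorted((c for c in df.columns if c.startswith("spacer_")),
                         key=lambda c: int(c.split("_", 1)[1]))
    cas_cols = [c for c in df.columns
                if not c.startswith("spacer_") and c != "shared_spacers"]
    out = {}
    for sid, row in df.iterrows():
        out[str(sid)] = CrisprProfile(
            strain_id=str(sid),
            spacer_status=[code[row[c]] for c in spacer_cols],
            cas_status=["present" if int(row[c]) == 1 else "absent"
                        for c in cas_cols])
    return out


# ---------------------------------------------------------------------------
# protospacer search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtospacerHit:
    spacer_index: int
    target_id: str
    identity: float
    coverage: float
    strand: str


PROTOSPACER_WORD_SIZE = 7
PROTOSPACER_MIN_IDENTITY = 0.85
PROTOSPACER_MIN_COVERAGE = 0.80


def _has_seed(query: str, target: str, word_size: int) -> bool:
    words = {query[i:i + word_size]
             for i in range(len(query) - word_size + 1)}
    return any(w in target for w in words)


def protospacer_search(spacers: Sequence[tuple[int, str]] | ReferenceCrispr,
                       database: Sequence[tuple[str, str]] | str,
                       word_size: int = PROTOSPACER_WORD_SIZE,
                       min_identity: float = PROTOSPACER_MIN_IDENTITY,
                       min_coverage: float = PROTOSPACER_MIN_COVERAGE,
                       ) -> dict[int, list[ProtospacerHit]]:
    """Search spacers against a phage/plasmid FASTA database.

    Seed-and-extend: a target is examined only if it shares at least one
    exact word of ``word_size`` bases with the spacer (either strand); the
    best local alignment against that target is then reported when it
    reaches ``min_identity`` over ``min_coverage`` of the spacer.  One hit
    is reported per (spacer, target) pair; a spacer may hit many targets.
    """
    if isinstance(spacers, ReferenceCrispr):
        spacers = spacers.spacers
    if isinstance(database, str):
        database = read_fasta(database)
    database = list(database)
    if not database:
        raise ValueError("empty protospacer database")
    hits: dict[int, list[ProtospacerHit]] = {idx: [] for idx, _ in spacers}
    searchers = {tid: SequenceSearcher([seq]) for tid, seq in database}
    for idx, spacer in spacers:
        for tid, seq in database:
            target = seq.upper()
            if not (_has_seed(spacer.upper(), target, word_size)
                    or _has_seed(revcomp(spacer.upper()), target, word_size)):
                continue
            hit = searchers[tid].best_local(spacer)
            if hit.identity >= min_identity and hit.coverage >= min_coverage:
                hits[idx].append(ProtospacerHit(
                    spacer_index=idx, target_id=tid,
                    identity=hit.identity, coverage=hit.coverage,
                    strand=hit.strand))
    return hits


def profile_distance(profile_a: CrisprProfile, profile_b: CrisprProfile) -> float:
    """Normalised mismatch between two profiles, partial as half-match.

    Spacer positions contribute 0 for equal statuses, 1 for conserved vs
    absent, and 0.5 when exactly one side is partial; cas positions
    contribute 0/1.  The sum is divided by the total position count.
    """
    if (len(profile_a.spacer_status) != len(profile_b.spacer_status)
            or len(profile_a.cas_status) != len(profile_b.cas_status)):
        raise ValueError("profiles must describe the same reference locus")
    total = 0.0
    for a, b in zip(profile_a.spacer_status, profile_b.spacer_status):
        if a == b:
            continue
        total += 0.5 if PARTIAL in (a, b) else 1.0
    for a, b in zip(profile_a.cas_status, profile_b.cas_status):
        if a != b:
            total += 1.0
    n = len(profile_a.spacer_status) + len(profile_a.cas_status)
    return total / n
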