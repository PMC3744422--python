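"""Reference-gene presence/absence calling from strain sequences.

Each reference gene is searched in every strain (all contigs, both
strands) and called ``present`` when its best local alignment reaches the
identity and coverage thresholds, ``absent`` otherwise.  Divergent and
missing genes are deliberately collapsed into ``absent``; the best
identity and coverage are kept on the per-gene call for diagnostics.

The identity threshold defaults to 0.40 (inclusive), the annotation-transfer
cutoff used for synteny-based ortholog sharing; the coverage threshold
defaults to 0.80 so that genes with only a fragment left (for example one
half after a partial deletion) score absent rather than present.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .align import DEFAULT_SCORING, Scoring, SequenceSearcher
from .io_core import ReferenceAnnotation, StrainGenome

MIN_GENE_LENGTH = 30


class Thresholds(NamedTuple):
    """Presence-call cutoffs; both comparisons are inclusive."""

    identity: float = 0.40
    coverage: float = 0.80


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class GeneCall:
    locus_tag: str
    status: str                 # "present" | "absent"
    best_identity: float
    best_coverage: float

    @property
    def present(self) -> bool:
        return self.status == "present"


@dataclass
class PresenceMatrix:
    """Binary strains x reference-genes matrix (1 present, 0 absent)."""

    strain_ids: list[str]
    locus_tags: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.strain_ids), len(self.locus_tags)):
            raise ValueError(
                f"matrix shape {self.calls.shape} does not match "
                f"{len(self.strain_ids)} strains x {len(self.locus_tags)} genes")
        if self.calls.size and not np.isin(self.calls, (0, 1)).all():
            raise ValueError("matrix cells must be 0 or 1")
        if len(set(self.strain_ids)) != len(self.strain_ids):
            raise ValueError("duplicate strain ids")
        if len(set(self.locus_tags)) != len(self.locus_tags):
            raise ValueError("duplicate locus tags")

    @property
    def n_strains(self) -> int:
        return len(self.strain_ids)

    @property
    def n_genes(self) -> int:
        return len(self.locus_tags)

    def row(self, strain_id: str) -> dict[str, int]:
        idx = self.strain_ids.index(strain_id)
        return dict(zip(self.locus_tags, (int(x) for x in self.calls[idx])))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.strain_ids,
                            columns=self.locus_tags)

    def __eq__(self, other) -> bool:
        return (isinstance(other, PresenceMatrix)
                and self.strain_ids == other.strain_ids
                and self.locus_tags == other.locus_tags
                and np.array_equal(self.calls, other.calls))


def align_gene(gene_seq: str, strain_seqs: Sequence[str],
               scoring: Scoring = DEFAULT_SCORING,
               searcher: SequenceSearcher | None = None) -> tuple[float, float]:
    """Best (identity, coverage) of a reference gene over strain contigs.

    ``searcher`` may be passed to reuse a prebuilt index for the same
    contigs across many genes.
    """
    if len(gene_seq) < MIN_GENE_LENGTH:
        raise ValueError(f"gene shorter than {MIN_GENE_LENGTH} bp")
    if searcher is None:
        if not strain_seqs:
            raise ValueError("empty strain sequence set")
        searcher = SequenceSearcher(strain_seqs, scoring=scoring)
    hit = searcher.best_local(gene_seq)
    return hit.identity, hit.coverage


def call_gene(gene_seq: str, strain: StrainGenome | Sequence[str],
              thresholds: Thresholds = DEFAULT_THRESHOLDS,
              locus_tag: str = "gene",
              searcher: SequenceSearcher | None = None) -> GeneCall:
    """Call one gene present/absent in one strain."""
    seqs = strain.sequences if isinstance(strain, StrainGenome) else strain
    identity, coverage = align_gene(gene_seq, seqs, searcher=searcher)
    present = identity >= thresholds.identity and coverage >= thresholds.coverage
    return GeneCall(locus_tag=locus_tag,
                    status="present" if present else "absent",
                    best_identity=identity, best_coverage=coverage)


def build_presence_matrix(annotation: ReferenceAnnotation, reference_seq: str,
                          strains: Sequence[StrainGenome],
                          thresholds: Thresholds = DEFAULT_THRESHOLDS,
                          ) -> PresenceMatrix:
    """Call every reference gene in every strain.

    Rows follow the supplied strain order; columns follow reference gene
    order.  The reference strain against itself yields an all-ones row.
    """
    if not strains:
        raise ValueError("at least one strain required")
    gene_seqs = [annotation.gene_sequence(g, reference_seq)
                 for g in annotation.genes]
    calls = np.zeros((len(strains), len(gene_seqs)), dtype=np.int8)
    for si, strain in enumerate(strains):
        searcher = SequenceSearcher(strain.sequences)
        for gi, gene_seq in enumerate(gene_seqs):
            call = call_gene(gene_seq, strain.sequences, thresholds,
                             locus_tag=annotation.genes[gi].locus_tag,
                             searcher=searcher)
            calls[si, gi] = 1 if call.present else 0
    return PresenceMatrix(strain_ids=[s.strain_id for s in strains],
                          locus_tags=annotation.locus_tags, calls=calls)
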