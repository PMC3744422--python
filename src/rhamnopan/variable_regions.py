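"""Gene-loss frequency profiles and hyper-variable region detection.

A variable region is a maximal run of reference genes, in gene-index
space, whose loss frequency across the cohort reaches a threshold, with a
small number of below-threshold genes tolerated inside the run.  Runs
always start and end on an above-threshold gene.  Regions are annotated
with the genomic island (GI) they overlap and their insertion-sequence
(IS) gene count, both taken from the reference annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ReferenceAnnotation
from .ortholog_calling import PresenceMatrix

DEFAULT_FREQ_THRESHOLD = 0.10
DEFAULT_MIN_GENES = 5
DEFAULT_MAX_GAP = 1


@dataclass(frozen=True)
class LossProfile:
    """Per-gene fraction of strains in which the gene is called absent."""

    locus_tags: list[str]
    frequencies: np.ndarray

    def __getitem__(self, locus_tag: str) -> float:
        return float(self.frequencies[self.locus_tags.index(locus_tag)])


def loss_profile(matrix: PresenceMatrix) -> LossProfile:
    """Loss frequency per reference gene: 1 - column mean of the calls."""
    if matrix.n_strains == 0:
        raise ValueError("empty matrix")
    freqs = 1.0 - matrix.calls.mean(axis=0)
    return LossProfile(locus_tags=list(matrix.locus_tags), frequencies=freqs)


@dataclass(frozen=True)
class VariableRegion:
    region_id: int
    first_tag: str
    last_tag: str
    first_index: int
    last_index: int
    gene_count: int
    mean_loss: float
    max_loss: float
    gi_overlap: str | None = None
    is_count: int = 0

    @property
    def locus_range(self) -> str:
        return f"{self.first_tag}–{self.last_tag}"


def detect_regions(profile: LossProfile,
                   annotation: ReferenceAnnotation | None = None,
                   freq_threshold: float = DEFAULT_FREQ_THRESHOLD,
                   min_genes: int = DEFAULT_MIN_GENES,
                   max_gap: int = DEFAULT_MAX_GAP) -> list[VariableRegion]:
    """Segment the loss profile into variable regions.

    A region is a maximal run of genes with loss frequency >=
    ``freq_threshold`` in which at most ``max_gap`` consecutive genes may
    fall below the threshold, trimmed to start and end on above-threshold
    genes, and spanning at least ``min_genes`` genes.
    """
    hot = profile.frequencies >= freq_threshold
    n = len(hot)
    regions: list[VariableRegion] = []
    i = 0
    while i < n:
        if not hot[i]:
            i += 1
            continue
        start = i
        end = i
        j = i + 1
        gap = 0
        while j < n:
            if hot[j]:
                end = j
                gap = 0
            else:
                gap += 1
                if gap > max_gap:
                    break
            j += 1
        if end - start + 1 >= min_genes:
            regions.append(_make_region(len(regions) + 1, start, end,
                                        profile, annotation))
        # everything in (end, j) is below threshold; resume the scan at j
        i = j
    return regions


def _make_region(region_id: int, start: int, end: int, profile: LossProfile,
                 annotation: ReferenceAnnotation | None) -> VariableRegion:
    freqs = profile.frequencies[start:end + 1]
    gi: str | None = None
    is_count = 0
    if annotation is not None:
        genes = annotation.genes[start:end + 1]
        gi_ids = [g.island_id for g in genes if g.island_id]
        if gi_ids:
            # the dominant island among member genes
            gi = max(sorted(set(gi_ids)), key=gi_ids.count)
        is_count = sum(1 for g in genes if g.is_IS_element)
    return VariableRegion(
        region_id=region_id,
        first_tag=profile.locus_tags[start],
        last_tag=profile.locus_tags[end],
        first_index=start, last_index=end,
        gene_count=end - start + 1,
        mean_loss=float(freqs.mean()),
        max_loss=float(freqs.max()),
        gi_overlap=gi, is_count=is_count)


def region_report(regions: list[VariableRegion],
                  annotation: ReferenceAnnotation | None = None,
                  max_keywords: int = 4) -> pd.DataFrame:
    """Tabulate detected regions: locus range, GI, IS count, product keywords."""
    rows = []
    for region in regions:
        keywords = ""
        if annotation is not None:
            genes = annotation.genes[region.first_index:region.last_index + 1]
            seen: list[str] = []
            for g in genes:
                if g.product and g.product not in seen:
                    seen.append(g.product)
            keywords = ", ".join(seen[:max_keywords])
        rows.append({
            "region": region.region_id,
            "genes": region.locus_range,
            "gene_count": region.gene_count,
            "GI": region.gi_overlap or "",
            "IS": region.is_count or "",
            "mean_loss": round(region.mean_loss, 4),
            "max_loss": round(region.max_loss, 4),
            "main_features": keywords,
        })
    return pd.DataFrame(rows, columns=["region", "genes", "gene_count", "GI",
                                       "IS", "mean_loss", "max_loss",
                                       "main_features"])


def write_regions_gff(regions: list[VariableRegion],
                      annotation: ReferenceAnnotation, path) -> None:
    """Write detected regions as GFF3 features on the reference chromosome."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for region in regions:
            first = annotation.genes[region.first_index]
            last = annotation.genes[region.last_index]
            attrs = [f"ID=region_{region.region_id}",
                     f"locus_range={region.first_tag}-{region.last_tag}",
                     f"gene_count={region.gene_count}",
                     f"mean_loss={region.mean_loss:.4f}"]
            if region.gi_overlap:
                attrs.append(f"gi_overlap={region.gi_overlap}")
            if region.is_count:
                attrs.append(f"is_count={region.is_count}")
            fh.write("\t".join([
                annotation.genome_id, "rhamnopan", "variable_region",
                str(first.start), str(last.end), ".", ".", ".",
                ";".join(attrs)]) + "\n")
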