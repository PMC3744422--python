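"""Readers, writers and run plumbing for the pipeline's on-disk formats.

In-memory coordinates are 1-based and inclusive throughout the package;
GFF3 already uses that convention, so no conversion is needed there.  The
native presence/absence matrix format is a plain TSV (strains as rows,
locus tags as columns, cells 0/1); a read-only XLSX import shim exists to
ingest externally published matrices of the same shape.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

if TYPE_CHECKING:  # pragma: no cover
    from .ortholog_calling import PresenceMatrix
    from .synthetic_data import SimulationTruth

logger = logging.getLogger("rhamnopan")

NICHES = ("dairy", "intestinal", "oral", "vaginal", "clinical", "other")

_VALID_BASES = set("ACGTN")


def configure_logging(level: int = logging.INFO) -> None:
    """Attach a plain stderr handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GeneModel:
    """One reference gene: 1-based inclusive coordinates on the chromosome."""

    locus_tag: str
    start: int
    end: int
    strand: str
    product: str = ""
    cog_category: str | None = None
    island_id: str | None = None
    is_IS_element: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"{self.locus_tag}: end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReferenceAnnotation:
    """Ordered gene models of the reference chromosome."""

    genome_id: str
    genome_length: int
    genes: list[GeneModel]

    def __post_init__(self) -> None:
        tags = [g.locus_tag for g in self.genes]
        if len(set(tags)) != len(tags):
            dup = sorted({t for t in tags if tags.count(t) > 1})
            raise ValueError(f"duplicate locus tags: {dup}")
        for g in self.genes:
            if g.start < 1 or g.end > self.genome_length:
                raise ValueError(
                    f"{g.locus_tag}: interval [{g.start}, {g.end}] outside "
                    f"[1, {self.genome_length}]")
        # equal starts are broken by locus tag, which encodes chromosomal order
        self.genes.sort(key=lambda g: (g.start, g.locus_tag))

    @property
    def locus_tags(self) -> list[str]:
        return [g.locus_tag for g in self.genes]

    def gene_sequence(self, gene: GeneModel, genome_seq: str) -> str:
        seq = genome_seq[gene.start - 1:gene.end]
        if gene.strand == "-":
            from .align import revcomp
            seq = revcomp(seq)
        return seq

    def index_of(self, locus_tag: str) -> int:
        try:
            return self.locus_tags.index(locus_tag)
        except ValueError:
            raise KeyError(locus_tag) from None


@dataclass
class StrainGenome:
    """A strain's consensus sequence(s) plus its niche label."""

    strain_id: str
    niche: str
    sequences: list[str]
    truth: "SimulationTruth | None" = None

    def __post_init__(self) -> None:
        if self.niche not in NICHES:
            raise ValueError(f"unknown niche {self.niche!r}; expected one of {NICHES}")
        if not self.sequences or any(len(s) == 0 for s in self.sequences):
            raise ValueError(f"{self.strain_id}: sequences must be non-empty")
        for seq in self.sequences:
            extra = set(seq.upper()) - _VALID_BASES
            if extra:
                raise ValueError(
                    f"{self.strain_id}: invalid characters {sorted(extra)}")


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Ordered (id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


_GFF_COLS = ("seqid", "source", "type", "start", "end",
             "score", "strand", "phase", "attributes")


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def read_reference(fasta_path: str | Path, gff_path: str | Path) -> tuple[ReferenceAnnotation, str]:
    """Load a reference genome (FASTA) and its gene annotation (GFF3).

    Returns the annotation plus the chromosome sequence.  The FASTA and the
    GFF must refer to the same sequence identifier.
    """
    fasta = read_fasta(fasta_path)
    if len(fasta) != 1:
        raise ValueError(f"reference FASTA must hold exactly one sequence, got {len(fasta)}")
    genome_id, genome_seq = fasta[0]
    genes: list[GeneModel] = []
    with open(gff_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{gff_path}:{line_no}: expected 9 columns")
            row = dict(zip(_GFF_COLS, fields))
            if row["type"] != "gene":
                continue
            if row["seqid"] != genome_id:
                raise ValueError(
                    f"{gff_path}:{line_no}: sequence id {row['seqid']!r} does not "
                    f"match FASTA id {genome_id!r}")
            try:
                start, end = int(row["start"]), int(row["end"])
            except ValueError:
                raise ValueError(f"{gff_path}:{line_no}: malformed coordinates") from None
            attrs = _parse_gff_attributes(row["attributes"])
            tag = attrs.get("locus_tag") or attrs.get("ID")
            if not tag:
                raise ValueError(f"{gff_path}:{line_no}: gene without locus_tag/ID")
            genes.append(GeneModel(
                locus_tag=tag, start=start, end=end, strand=row["strand"],
                product=attrs.get("product", ""),
                cog_category=attrs.get("cog_category") or None,
                island_id=attrs.get("island_id") or None,
                is_IS_element=attrs.get("is_IS_element", "").lower() == "true",
            ))
    return ReferenceAnnotation(genome_id=genome_id,
                               genome_length=len(genome_seq),
                               genes=genes), genome_seq


def write_reference_gff(annotation: ReferenceAnnotation, path: str | Path,
                        source: str = "rhamnopan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {annotation.genome_id} 1 {annotation.genome_length}\n")
        for g in annotation.genes:
            attrs = [f"ID={g.locus_tag}", f"locus_tag={g.locus_tag}"]
            if g.product:
                attrs.append(f"product={g.product}")
            if g.cog_category:
                attrs.append(f"cog_category={g.cog_category}")
            if g.island_id:
                attrs.append(f"island_id={g.island_id}")
            if g.is_IS_element:
                attrs.append("is_IS_element=true")
            fh.write("\t".join([
                annotation.genome_id, source, "gene", str(g.start), str(g.end),
                ".", g.strand, ".", ";".join(attrs)]) + "\n")


# ---------------------------------------------------------------------------
# presence/absence matrix TSV (+ XLSX import shim)
# ---------------------------------------------------------------------------

def write_matrix(matrix: "PresenceMatrix", path: str | Path) -> None:
    """Serialise a presence matrix as TSV: strain rows, locus-tag columns."""
    df = matrix.to_dataframe()
    df.to_csv(path, sep="\t", index_label="strain")


def read_matrix(path: str | Path) -> "PresenceMatrix":
    from .ortholog_calling import PresenceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.columns.duplicated().any() or df.index.duplicated().any():
        raise ValueError("duplicate strain ids or locus tags in matrix")
    values = df.to_numpy()
    if values.size:
        flat = pd.unique(values.ravel())
        bad = sorted(set(flat) - {"0", "1"})
        if bad:
            raise ValueError(f"matrix cells must be 0 or 1, found {bad}")
        calls = values.astype(np.int8)
    else:
        calls = np.zeros((df.shape[0], df.shape[1]), dtype=np.int8)
    return PresenceMatrix(strain_ids=list(df.index.astype(str)),
                          locus_tags=list(df.columns.astype(str)),
                          calls=calls)


_TAG_RE = re.compile(r"^[A-Za-z][A-Za-z0-9]*_\d+$")


def import_presence_xlsx(path: str | Path,
                         reference_tags: Sequence[str] | None = None) -> "PresenceMatrix":
    """Import a published presence/absence matrix from XLSX.

    Orientation (strains-as-rows vs genes-as-rows) is auto-detected: the
    axis whose labels look like locus tags (or match ``reference_tags``)
    becomes the column axis.
    """
    from .ortholog_calling import PresenceMatrix

    df = pd.read_excel(path, index_col=0)
    df = df.dropna(how="all").dropna(axis=1, how="all")

    def tag_fraction(labels: Iterable) -> float:
        labels = [str(x) for x in labels]
        if not labels:
            return 0.0
        if reference_tags is not None:
            ref = set(reference_tags)
            return sum(1 for x in labels if x in ref) / len(labels)
        return sum(1 for x in labels if _TAG_RE.match(x)) / len(labels)

    if tag_fraction(df.index) > tag_fraction(df.columns):
        df = df.T
    values = df.to_numpy()
    numeric = pd.to_numeric(pd.Series(values.ravel()), errors="coerce")
    if numeric.isna().any() or not set(numeric.unique()) <= {0, 1}:
        raise ValueError("XLSX matrix cells must all be 0 or 1")
    calls = numeric.to_numpy().reshape(values.shape).astype(np.int8)
    return PresenceMatrix(strain_ids=[str(x) for x in df.index],
                          locus_tags=[str(x) for x in df.columns],
                          calls=calls)


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------
# dendropy handles the newick grammar (quoting of labels with spaces,
# malformed-string detection); in-memory trees are scikit-bio TreeNodes.

def _dendropy_to_skbio(node: dendropy.Node) -> TreeNode:
    label = None
    if node.taxon is not None:
        label = node.taxon.label
    elif node.label is not None:
        label = node.label
    out = TreeNode(name=label, length=node.edge.length)
    for child in node.child_nodes():
        out.append(_dendropy_to_skbio(child))
    return out


def _skbio_to_dendropy(tree: TreeNode) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=taxa)

    def build(src: TreeNode, dst: dendropy.Node) -> None:
        for child in src.children:
            node = dendropy.Node()
            node.edge.length = child.length
            dst.add_child(node)
            if child.is_tip():
                node.taxon = taxa.new_taxon(child.name or "")
            else:
                if child.name:
                    node.label = child.name
                build(child, node)

    if tree.name:
        dtree.seed_node.label = tree.name
    build(tree, dtree.seed_node)
    return dtree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write a tree as newick; leaf names with spaces are quoted."""
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise ValueError("tree leaves must be uniquely labelled")
    dtree = _skbio_to_dendropy(tree)
    dtree.write(path=str(path), schema="newick", suppress_rooting=True,
                unquoted_underscores=True, preserve_spaces=True)


def read_newick(path: str | Path) -> TreeNode:
    try:
        dtree = dendropy.Tree.get(path=str(path), schema="newick",
                                  preserve_underscores=True)
    except Exception as exc:
        raise ValueError(f"malformed newick in {path}: {exc}") from exc
    return _dendropy_to_skbio(dtree.seed_node)


# ---------------------------------------------------------------------------
# configuration and run manifest
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a YAML configuration file as a plain dict."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


@dataclass
class RunManifest:
    """Record of one pipeline run: the seed and parameters that produced it.

    Deliberately carries no timestamps or host information so that repeated
    runs with the same seed produce byte-identical manifests.
    """

    command: str
    seed: int | None = None
    parameters: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        payload = {
            "command": self.command,
            "seed": self.seed,
            "parameters": self.parameters,
            "outputs": sorted(self.outputs),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")
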