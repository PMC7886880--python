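"""Readers and writers for every external representation the pipeline touches.

All format dialects live here; the computational modules exchange only the
domain types.  Coordinates are 1-based with the VCF anchor-base convention.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence, Union

import pandas as pd
import pysam
from Bio import SeqIO
from skbio import TreeNode

from .genotypes import GenotypeMatrix
from .types import IndelCall, MarkerCandidate, ReferenceGenome

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA / chromosome lengths
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> ReferenceGenome:
    """Load a reference genome from FASTA.

    Record names are the first whitespace-delimited header token; sequences
    are uppercased.  Duplicate names and empty records are hard errors.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in sequences:
            raise ValueError(f"duplicate chromosome name {name!r} in {path}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty record {name!r} in {path}")
        sequences[name] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    return ReferenceGenome(sequences=sequences)


def write_fasta(genome: ReferenceGenome, path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_lengths(path: PathLike) -> ReferenceGenome:
    """Two-column TSV (chrom, length in bp) -> genome with lengths only."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    lengths = {}
    for _, row in df.iterrows():
        chrom = str(row["chrom"])
        if chrom in lengths:
            raise ValueError(f"duplicate chromosome {chrom!r} in {path}")
        length = int(row["length"])
        if length <= 0:
            raise ValueError(f"non-positive length for {chrom!r}")
        lengths[chrom] = length
    return ReferenceGenome(lengths=lengths)


def write_chrom_lengths(genome: ReferenceGenome, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.lengths.items():
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# InDel call sets
# ---------------------------------------------------------------------------

def _pure_indel(chrom: str, pos: int, ref: str, alt: str) -> IndelCall | None:
    """Build an IndelCall, or None when (ref, alt) is not a pure InDel."""
    if len(ref) == len(alt):
        return None
    short, long = (ref, alt) if len(ref) < len(alt) else (alt, ref)
    if not long.startswith(short):
        return None
    try:
        return IndelCall(chrom, pos, ref.upper(), alt.upper())
    except ValueError:
        return None


def read_indel_calls(path: PathLike, dialect: str = "vcf") -> list[IndelCall]:
    """Read a parent-versus-reference call set.

    ``dialect`` is "vcf" (CHROM/POS/REF/ALT of a VCF 4.x file; INFO and
    FORMAT are ignored) or "tsv" (columns chrom, pos, ref, alt).  SNVs and
    alleles that are not pure InDels are skipped with a logged count; pure
    InDel alleles of multi-allelic records are expanded into separate calls.
    """
    if dialect == "vcf":
        calls, skipped = _read_vcf(path)
    elif dialect == "tsv":
        calls, skipped = _read_call_tsv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if skipped:
        logger.info("%s: skipped %d non-InDel allele(s)", path, skipped)
    return calls


def _read_vcf(path: PathLike) -> tuple[list[IndelCall], int]:
    calls: list[IndelCall] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None:
                skipped += 1
                continue
            for alt in rec.alts:
                call = _pure_indel(rec.chrom, rec.pos, rec.ref, alt)
                if call is None:
                    skipped += 1
                else:
                    calls.append(call)
    return calls, skipped


def _read_call_tsv(path: PathLike) -> tuple[list[IndelCall], int]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: call table needs columns {sorted(required)}")
    calls: list[IndelCall] = []
    skipped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pos = int(row.pos)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path} line {i}: malformed coordinate {row.pos!r}") from exc
        for alt in str(row.alt).split(","):
            call = _pure_indel(str(row.chrom), pos, str(row.ref), alt)
            if call is None:
                skipped += 1
            else:
                calls.append(call)
    return calls, skipped


def write_indel_calls(
    calls: Iterable[IndelCall],
    path: PathLike,
    dialect: str = "vcf",
    genome: ReferenceGenome | None = None,
) -> None:
    """Write a call set as a minimal VCF (with contig headers) or a TSV."""
    calls = sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt_allele))
    if dialect == "tsv":
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\n")
            for c in calls:
                fh.write(f"{c.chrom}\t{c.pos}\t{c.ref_allele}\t{c.alt_allele}\n")
        return
    if dialect != "vcf":
        raise ValueError(f"unknown dialect {dialect!r}")
    contigs: dict[str, int | None] = {}
    if genome is not None:
        contigs.update(genome.lengths)
    for c in calls:
        contigs.setdefault(c.chrom, None)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contigs.items():
            if length is None:
                fh.write(f"##contig=<ID={name}>\n")
            else:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref_allele}\t{c.alt_allele}\t.\t.\t.\n"
            )


# ---------------------------------------------------------------------------
# Cross-parent InDel tables
# ---------------------------------------------------------------------------

def write_cross_parent_table(indels, path: PathLike) -> None:
    """TSV of cross-parent polymorphic InDels (both alleles for both_distinct)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tcarrier\tallele_size_diff"
                 "\tref_other\talt_other\n")
        for x in indels:
            other = x.call_other
            fh.write(
                f"{x.chrom}\t{x.pos}\t{x.call.ref_allele}\t{x.call.alt_allele}"
                f"\t{x.carrier}\t{x.allele_size_diff}"
                f"\t{other.ref_allele if other else ''}"
                f"\t{other.alt_allele if other else ''}\n"
            )


def read_cross_parent_table(path: PathLike):
    from .types import CrossParentIndel

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        call = IndelCall(row.chrom, int(row.pos), row.ref, row.alt)
        other = (
            IndelCall(row.chrom, int(row.pos), row.ref_other, row.alt_other)
            if row.ref_other
            else None
        )
        out.append(
            CrossParentIndel(call, row.carrier, int(row.allele_size_diff), other)
        )
    return out


# ---------------------------------------------------------------------------
# Marker tables
# ---------------------------------------------------------------------------

MARKER_TABLE_COLUMNS = [
    "marker_id",
    "chrom",
    "pos",
    "indel_length",
    "size_class",
    "gel_class",
    "forward_primer",
    "reverse_primer",
    "tm_forward",
    "tm_reverse",
    "product_size_A",
    "product_size_B",
]


def write_marker_table(markers: Sequence[MarkerCandidate], path: PathLike) -> None:
    """Write designed markers as TSV, sorted by (chrom, pos).

    Markers without a designed primer pair get empty primer/product fields
    and a logged warning.
    """
    from .discovery import classify_size

    if not markers:
        raise ValueError("no markers to write")
    rows = []
    for m in sorted(markers, key=lambda m: (m.source.chrom, m.source.pos)):
        if m.primers is None:
            logger.warning("marker %s has no designed primers", m.id)
            primer_fields = [""] * 6
        else:
            p = m.primers
            primer_fields = [
                p.forward_seq,
                p.reverse_seq,
                f"{p.tm_forward:.2f}",
                f"{p.tm_reverse:.2f}",
                "" if m.product_size_a is None else str(m.product_size_a),
                "" if m.product_size_b is None else str(m.product_size_b),
            ]
        rows.append(
            [
                m.id,
                m.source.chrom,
                m.source.pos,
                m.source.call.length,
                classify_size(m.source.call),
                m.gel_class,
                *primer_fields,
            ]
        )
    pd.DataFrame(rows, columns=MARKER_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_marker_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})


# ---------------------------------------------------------------------------
# Genotype matrices
# ---------------------------------------------------------------------------

def read_genotype_matrix(path: PathLike, sep: str | None = None) -> GenotypeMatrix:
    """Read a lines x markers matrix of co-dominant calls (CSV or TSV).

    First column = line id; header row = marker ids; cells are slash-joined
    allele sizes ("191/218"), a single size, or "NA".
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    return GenotypeMatrix.from_dataframe(df)


def write_genotype_matrix(
    matrix: GenotypeMatrix, path: PathLike, sep: str | None = None
) -> None:
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    matrix.to_dataframe().to_csv(path, sep=sep)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def write_newick(tree: TreeNode, path: PathLike) -> None:
    """Serialize a dendrogram as Newick with branch lengths."""
    tree.write(str(path), format="newick")


def read_newick(path: PathLike) -> TreeNode:
    return TreeNode.read(str(path), format="newick")
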