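"""Cross-parent InDel discovery and accounting.

Two parents re-sequenced against a common reference each yield a
parent-versus-reference InDel call set.  An InDel present in exactly one
parent is polymorphic between the parents — at its position the other parent
matches the reference — and is the raw material for a co-dominant PCR
marker.  InDels shared identically by both parents are invisible between
them and are dropped.

Identity is decided on the canonical (left-aligned, parsimonious)
chrom+pos+ref+alt key, so the comparison is insensitive to how a caller
anchored an event inside a repeat tract.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

from .types import (
    CARRIER_A,
    CARRIER_B,
    CARRIER_BOTH_DISTINCT,
    SIZE_CLASS_BINS,
    CrossParentIndel,
    DiscoverySummary,
    IndelCall,
    ReferenceGenome,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_indel(call: IndelCall, genome: ReferenceGenome) -> IndelCall:
    """Return the canonical left-aligned, parsimonious form of an InDel.

    The event is shifted left through any repeat context until no further
    shift is possible, and trimmed to the minimal representation with a
    single anchor base.  Idempotent; all anchorings of one physical event
    collapse to the same key.
    """
    chrom = call.chrom
    if chrom not in genome.sequences:
        raise KeyError(f"chromosome {chrom!r} not in genome")
    seq = genome.sequences[chrom]
    pos = call.pos
    ref = call.ref_allele
    alt = call.alt_allele
    observed = seq[pos - 1 : pos - 1 + len(ref)]
    if observed != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: call has {ref!r}, "
            f"genome has {observed!r}"
        )
    # Left-align: while the alleles end with the same base, drop it; when
    # the shorter allele would empty, pull in the preceding reference base.
    while ref[-1] == alt[-1]:
        if min(len(ref), len(alt)) > 1:
            ref, alt = ref[:-1], alt[:-1]
        elif pos > 1:
            prev = seq[pos - 2]
            pos -= 1
            ref, alt = prev + ref[:-1], prev + alt[:-1]
        else:
            break
    # Trim the shared prefix down to one anchor base.
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return IndelCall(chrom, pos, ref, alt)


# ---------------------------------------------------------------------------
# Cross-parent derivation
# ---------------------------------------------------------------------------

def derive_cross_parent(
    calls_a: Iterable[IndelCall],
    calls_b: Iterable[IndelCall],
    genome: ReferenceGenome,
) -> list[CrossParentIndel]:
    """Derive the InDels polymorphic between parent A and parent B.

    Both call sets are normalized internally.  A canonical key present in
    exactly one parent yields a :class:`CrossParentIndel` with that carrier;
    keys present in both are shared (non-polymorphic) and excluded.  Two
    different alleles at the same canonical anchor are kept as
    ``both_distinct`` when their lengths differ (distinguishable bands);
    equal-length allele pairs are logged and dropped.
    """
    norm_a = {normalize_indel(c, genome) for c in calls_a}
    norm_b = {normalize_indel(c, genome) for c in calls_b}
    keys_a = {c.key for c in norm_a}
    keys_b = {c.key for c in norm_b}
    unique_a = sorted(c for c in norm_a if c.key not in keys_b)
    unique_b = sorted(c for c in norm_b if c.key not in keys_a)

    by_anchor: dict[tuple[str, int], tuple[list[IndelCall], list[IndelCall]]] = {}
    for c in unique_a:
        by_anchor.setdefault((c.chrom, c.pos), ([], []))[0].append(c)
    for c in unique_b:
        by_anchor.setdefault((c.chrom, c.pos), ([], []))[1].append(c)

    out: list[CrossParentIndel] = []
    for anchor in sorted(by_anchor):
        at_a, at_b = by_anchor[anchor]
        if at_a and at_b:
            if len(at_a) == 1 and len(at_b) == 1:
                a, b = at_a[0], at_b[0]
                diff = abs(a.length - b.length)
                if diff == 0:
                    logger.info(
                        "dropping length-identical allele pair at %s:%d "
                        "(not length-polymorphic)",
                        *anchor,
                    )
                    continue
                out.append(
                    CrossParentIndel(
                        call=a,
                        carrier=CARRIER_BOTH_DISTINCT,
                        allele_size_diff=diff,
                        call_other=b,
                    )
                )
                continue
            logger.info(
                "multi-allelic anchor %s:%d in both parents; keeping alleles "
                "as separate carrier records",
                *anchor,
            )
        for c in at_a:
            out.append(CrossParentIndel(c, CARRIER_A, c.size))
        for c in at_b:
            out.append(CrossParentIndel(c, CARRIER_B, c.size))
    out.sort(key=lambda x: (x.chrom, x.pos, x.carrier, x.call.alt_allele))
    return out


# ---------------------------------------------------------------------------
# Size classes and accounting
# ---------------------------------------------------------------------------

def classify_size(call: IndelCall) -> str:
    """Bin an InDel by |length|: 1-10 small, 11-20 and 21-30 medium, >30 large."""
    size = call.size
    if size < 1:
        raise ValueError("zero-length event")
    for label, low, high in SIZE_CLASS_BINS:
        if size >= low and (high is None or size <= high):
            return label
    raise AssertionError("size-class bins do not partition positive lengths")


def density(count: int, length_mb: float) -> float:
    """InDel density in events/Mb, reported to one decimal."""
    if length_mb <= 0:
        raise ValueError(f"non-positive length {length_mb} Mb")
    if count < 0:
        raise ValueError("negative count")
    return round(count / length_mb, 1)


def summarize(
    indels: Sequence[CrossParentIndel],
    lengths_mb: Mapping[str, float],
) -> DiscoverySummary:
    """Per-chromosome counts/densities and size-class accounting.

    ``lengths_mb`` maps chromosome name to physical length in Mb.  Every
    chromosome carrying a counted event must have a length.  Size-class
    percentages (of the grand total) are reported to one decimal; counts are
    split by insertion/deletion using the carrier allele's sign.
    """
    if not indels:
        raise ValueError("empty InDel set")
    summary = DiscoverySummary()
    for chrom in sorted({x.chrom for x in indels}):
        if chrom not in lengths_mb:
            raise ValueError(f"no length for chromosome {chrom!r}")
    for x in indels:
        summary.chrom_counts[x.chrom] = summary.chrom_counts.get(x.chrom, 0) + 1
    for chrom, count in summary.chrom_counts.items():
        summary.chrom_density[chrom] = density(count, lengths_mb[chrom])
    summary.total = len(indels)
    total_mb = sum(lengths_mb.values())
    summary.total_density = density(summary.total, total_mb)

    for label, _, _ in SIZE_CLASS_BINS:
        summary.class_counts[label] = {"insertion": 0, "deletion": 0}
    for x in indels:
        label = classify_size(x.call)
        kind = "insertion" if x.call.is_insertion else "deletion"
        summary.class_counts[label][kind] += 1
    for label, kinds in summary.class_counts.items():
        summary.class_percent[label] = round(
            100.0 * sum(kinds.values()) / summary.total, 1
        )
    return summary


def size_class_percentages(class_counts: Mapping[str, int]) -> dict[str, float]:
    """Percentages (1 decimal) of total for already-tallied size-class counts."""
    total = sum(class_counts.values())
    if total == 0:
        raise ValueError("no events")
    return {k: round(100.0 * v / total, 1) for k, v in class_counts.items()}


def summary_table(summary: DiscoverySummary) -> str:
    """Render a DiscoverySummary as a TSV (chromosome rows, then class rows)."""
    lines = ["section\tname\tcount\tdensity_or_percent"]
    for chrom in sorted(summary.chrom_counts):
        lines.append(
            f"chromosome\t{chrom}\t{summary.chrom_counts[chrom]}"
            f"\t{summary.chrom_density[chrom]}"
        )
    lines.append(f"chromosome\ttotal\t{summary.total}\t{summary.total_density}")
    for label, kinds in summary.class_counts.items():
        lines.append(
            f"size_class\t{label}\t{sum(kinds.values())}"
            f"\t{summary.class_percent[label]}"
        )
    return "\n".join(lines) + "\n"
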