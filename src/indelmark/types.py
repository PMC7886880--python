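"""Core domain types shared across the pipeline.

The unit of work is an insertion/deletion polymorphism (InDel) between two
re-sequenced breeding parents, called against a common reference genome.
Coordinates are 1-based throughout and follow the VCF anchor convention:
``pos`` addresses the reference base immediately preceding the event, and
that anchor base is the first character of both allele strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SIZE_CLASS_SMALL = "small"
SIZE_CLASS_MEDIUM_11_20 = "medium_11_20"
SIZE_CLASS_MEDIUM_21_30 = "medium_21_30"
SIZE_CLASS_LARGE = "large"

#: Size-class bins in bp of |indel length|; (label, low, high). ``None`` = unbounded.
SIZE_CLASS_BINS = (
    (SIZE_CLASS_SMALL, 1, 10),
    (SIZE_CLASS_MEDIUM_11_20, 11, 20),
    (SIZE_CLASS_MEDIUM_21_30, 21, 30),
    (SIZE_CLASS_LARGE, 31, None),
)

#: Allele size difference (bp) above which the two PCR products of a
#: co-dominant marker separate on a standard agarose gel.
AGAROSE_MIN_DIFF = 30

GEL_AGAROSE = "agarose"
GEL_POLYACRYLAMIDE = "polyacrylamide"


@dataclass(frozen=True, order=True)
class IndelCall:
    """One insertion or deletion versus the reference.

    Exactly one of ``ref_allele``/``alt_allele`` must be a strict prefix of
    the other (a pure InDel; complex substitutions are rejected upstream).
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        r, a = self.ref_allele, self.alt_allele
        if not (r and a):
            raise ValueError("empty allele string")
        if len(r) == len(a):
            raise ValueError(f"not an InDel: {r}>{a} at {self.chrom}:{self.pos}")
        short, long = (r, a) if len(r) < len(a) else (a, r)
        if not long.startswith(short):
            raise ValueError(
                f"complex substitution, not a pure InDel: {r}>{a} "
                f"at {self.chrom}:{self.pos}"
            )

    @property
    def length(self) -> int:
        """Signed event length: positive insertion, negative deletion."""
        return len(self.alt_allele) - len(self.ref_allele)

    @property
    def size(self) -> int:
        """Unsigned event length in bp."""
        return abs(self.length)

    @property
    def is_insertion(self) -> bool:
        return self.length > 0

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity key (chrom, pos, ref, alt); compare normalized calls only."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


_DNA_ALPHABET = frozenset("ACGTN")


@dataclass
class ReferenceGenome:
    """Reference chromosome sequences and/or their lengths.

    ``lengths`` may be populated without ``sequences`` (from a two-column
    chromosome-length table) so that density accounting can run without a
    genome in memory.  When both are present they must agree.
    """

    sequences: dict[str, str] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - _DNA_ALPHABET
            if bad:
                raise ValueError(f"{name}: non-ACGTN characters {sorted(bad)}")
            if name in self.lengths and self.lengths[name] != len(seq):
                raise ValueError(
                    f"{name}: sequence length {len(seq)} != declared "
                    f"length {self.lengths[name]}"
                )
        for name, seq in self.sequences.items():
            self.lengths.setdefault(name, len(seq))

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice of a chromosome sequence."""
        if chrom not in self.sequences:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        return self.sequences[chrom][start - 1 : end]

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())


CARRIER_A = "A"
CARRIER_B = "B"
CARRIER_BOTH_DISTINCT = "both_distinct"


@dataclass(frozen=True, order=True)
class CrossParentIndel:
    """An InDel polymorphic between parent A and parent B.

    ``carrier`` names the parent holding the non-reference allele, or
    ``both_distinct`` when the parents carry two different InDel alleles at
    the same canonical anchor.  ``allele_size_diff`` is the bp difference
    between the two parents' local allele lengths — the quantity a gel
    resolves.
    """

    call: IndelCall
    carrier: str
    allele_size_diff: int
    call_other: Optional[IndelCall] = None

    def __post_init__(self) -> None:
        if self.carrier not in (CARRIER_A, CARRIER_B, CARRIER_BOTH_DISTINCT):
            raise ValueError(f"bad carrier {self.carrier!r}")
        if self.allele_size_diff < 1:
            raise ValueError("allele_size_diff must be >= 1")

    @property
    def chrom(self) -> str:
        return self.call.chrom

    @property
    def pos(self) -> int:
        return self.call.pos


@dataclass(frozen=True)
class PrimerPair:
    """A designed PCR primer pair (both sequences written 5'->3')."""

    forward_seq: str
    reverse_seq: str
    tm_forward: float
    tm_reverse: float
    product_size_ref: int


@dataclass
class MarkerCandidate:
    """A candidate co-dominant PCR marker built around one cross-parent InDel."""

    id: str
    source: CrossParentIndel
    template: str
    primers: Optional[PrimerPair] = None
    product_size_a: Optional[int] = None
    product_size_b: Optional[int] = None

    @property
    def gel_class(self) -> str:
        return gel_class_for_diff(self.source.allele_size_diff)


def gel_class_for_diff(allele_size_diff: int) -> str:
    """Gel on which two products differing by ``allele_size_diff`` bp resolve.

    Differences above 30 bp separate on a standard 2% agarose gel; smaller
    differences need polyacrylamide.
    """
    return GEL_AGAROSE if allele_size_diff > AGAROSE_MIN_DIFF else GEL_POLYACRYLAMIDE


@dataclass(frozen=True)
class MarkerSummary:
    """Per-marker panel statistics (PowerMarker-style)."""

    marker_id: str
    allele_count: int
    major_allele_freq: float
    gene_diversity: float
    observed_heterozygosity: float
    pic: float


@dataclass
class DiscoverySummary:
    """Density and size-class accounting of a cross-parent InDel set."""

    chrom_counts: dict[str, int] = field(default_factory=dict)
    chrom_density: dict[str, float] = field(default_factory=dict)
    class_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    class_percent: dict[str, float] = field(default_factory=dict)
    total: int = 0
    total_density: float = 0.0
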