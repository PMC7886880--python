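"""PCR marker design around cross-parent InDels.

For each polymorphic InDel the reference-strand template is the event's
allele plus fixed-length flanks (default 150 bp each side).  Primers are
chosen by exhaustive scan of both flanks under the marker-development
constraints: primer length 18-28 bp, melting temperature 57-63 degC and a
reference-allele product of 80-300 bp.  Both primers lie strictly outside
the InDel allele, so both parental alleles amplify and the two products
differ by exactly the allele length difference — the property that makes the
marker co-dominant and, for differences above 30 bp, agarose-resolvable.

Melting temperatures use the unified nearest-neighbor thermodynamic
parameters (SantaLucia 1998) at 50 mM monovalent salt and 500 nM total
primer, with the entropic salt correction 0.368*N*ln[Na+].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .types import (
    CARRIER_A,
    CARRIER_B,
    CrossParentIndel,
    IndelCall,
    MarkerCandidate,
    PrimerPair,
    ReferenceGenome,
    gel_class_for_diff,
)

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------

# Unified nearest-neighbor parameters: dH in kcal/mol, dS in cal/(mol*K),
# keyed by the 5'->3' dinucleotide; a stack and its reverse complement share
# one entry.
_NN_DH_DS = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)
_R_GAS = 1.98717  # cal/(mol*K)

MONOVALENT_M = 0.05  # 50 mM Na+
PRIMER_CONC_M = 500e-9  # 500 nM total strand concentration


def melting_temperature(primer: str) -> float:
    """Nearest-neighbor duplex melting temperature in degC.

    Assumes the primer meets its exact complement and is in excess
    (CT/4 term); conditions fixed at 50 mM Na+, 500 nM primer, no divalent
    correction.  Requires length >= 8 and an unambiguous ACGT sequence.
    """
    seq = primer.upper()
    if len(seq) < 8:
        raise ValueError(f"primer too short for NN model: {len(seq)} < 8")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguous base in primer {primer!r}")
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        init = _INIT_GC if end in "GC" else _INIT_AT
        dh += init[0]
        ds += init[1]
    for i in range(len(seq) - 1):
        pair_dh, pair_ds = _NN_DH_DS[seq[i : i + 2]]
        dh += pair_dh
        ds += pair_ds
    ds_salt = ds + 0.368 * (len(seq) - 1) * math.log(MONOVALENT_M)
    tm_kelvin = dh * 1000.0 / (ds_salt + _R_GAS * math.log(PRIMER_CONC_M / 4.0))
    return tm_kelvin - 273.15


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _homopolymer_runs(seq: str, min_run: int = 5) -> int:
    """Number of maximal single-base runs of length >= min_run."""
    runs = 0
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            runs += 1
        i = j
    return runs


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Template:
    """Reference-strand design template: upstream flank + InDel allele + downstream."""

    seq: str
    up_len: int
    ref_span: int  # length of the reference-allele segment between the flanks

    @property
    def down_start(self) -> int:
        return self.up_len + self.ref_span


def extract_flanks(
    genome: ReferenceGenome, indel: IndelCall, flank_len: int = 150
) -> Template:
    """Extract the design template around a (normalized) InDel.

    Returns ``flank_len`` reference bases upstream of the anchor, the
    reference allele, and ``flank_len`` bases downstream.  Flanks truncated
    by a chromosome end are shortened with a logged warning.
    """
    if indel.chrom not in genome.sequences:
        raise KeyError(f"chromosome {indel.chrom!r} not in genome")
    seq = genome.sequences[indel.chrom]
    ref_len = len(indel.ref_allele)
    up_start = indel.pos - 1 - flank_len  # 0-based
    if up_start < 0:
        logger.warning(
            "upstream flank of %s:%d truncated to %d bases",
            indel.chrom, indel.pos, indel.pos - 1,
        )
        up_start = 0
    up = seq[up_start : indel.pos - 1]
    ref_end = indel.pos - 1 + ref_len
    down = seq[ref_end : ref_end + flank_len]
    if len(down) < flank_len:
        logger.warning(
            "downstream flank of %s:%d truncated to %d bases",
            indel.chrom, indel.pos, len(down),
        )
    return Template(seq=up + indel.ref_allele + down, up_len=len(up), ref_span=ref_len)


def extract_locus_template(
    genome: ReferenceGenome, indel: CrossParentIndel, flank_len: int = 150
) -> Template:
    """Template around a cross-parent locus.

    For ``both_distinct`` loci the central segment spans the longer of the
    two reference alleles so primers clear both events.
    """
    span = len(indel.call.ref_allele)
    if indel.call_other is not None:
        span = max(span, len(indel.call_other.ref_allele))
    if indel.chrom not in genome.sequences:
        raise KeyError(f"chromosome {indel.chrom!r} not in genome")
    seq = genome.sequences[indel.chrom]
    up_start = max(indel.pos - 1 - flank_len, 0)
    up = seq[up_start : indel.pos - 1]
    centre = seq[indel.pos - 1 : indel.pos - 1 + span]
    down = seq[indel.pos - 1 + span : indel.pos - 1 + span + flank_len]
    return Template(seq=up + centre + down, up_len=len(up), ref_span=span)


def allele_sequence(template: Template, call: IndelCall | None) -> str:
    """Apply one parent's allele to the reference template (None = reference)."""
    if call is None:
        return template.seq
    lr = len(call.ref_allele)
    if lr > template.ref_span:
        raise ValueError("reference allele exceeds template centre span")
    centre = template.seq[template.up_len : template.down_start]
    return (
        template.seq[: template.up_len]
        + call.alt_allele
        + centre[lr:]
        + template.seq[template.down_start :]
    )


# ---------------------------------------------------------------------------
# Primer design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignConstraints:
    """Primer-design windows; defaults are the marker-development settings."""

    primer_len_min: int = 18
    primer_len_max: int = 28
    tm_min: float = 57.0
    tm_max: float = 63.0
    product_min: int = 80
    product_max: int = 300
    tm_opt: float = 60.0
    gc_min: float = 0.40
    gc_max: float = 0.60


def _candidate_sites(
    seq: str, lo: int, hi: int, constraints: DesignConstraints
) -> list[tuple[int, int, str, float, int]]:
    """All template sites [start, end) within [lo, hi) passing length+Tm.

    Returns (start, end, site_seq, tm, penalty) with penalty = GC-window
    violation (1) plus homopolymer runs >= 5.
    """
    out = []
    c = constraints
    for start in range(lo, hi):
        for length in range(c.primer_len_min, c.primer_len_max + 1):
            end = start + length
            if end > hi:
                break
            site = seq[start:end]
            if "N" in site:
                continue
            tm = melting_temperature(site)
            if not c.tm_min <= tm <= c.tm_max:
                continue
            penalty = 0 if c.gc_min <= gc_fraction(site) <= c.gc_max else 1
            penalty += _homopolymer_runs(site)
            out.append((start, end, site, tm, penalty))
    return out


def design_primers(
    template: Template, constraints: DesignConstraints | None = None
) -> Optional[PrimerPair]:
    """Exhaustively scan both flanks for the best constraint-satisfying pair.

    Forward candidates are substrings of the upstream flank; reverse
    candidates are reverse complements of downstream-flank substrings, so
    both primers lie strictly outside the InDel allele.  Among pairs meeting
    every window the score
    ``|Tm_f - 60| + |Tm_r - 60| + |Tm_f - Tm_r| + GC-penalty + homopolymer-penalty``
    is minimized, with deterministic tie-breaks (smaller product, leftmost
    forward start, lexicographic sequences).  Returns None when no pair
    qualifies.
    """
    c = constraints or DesignConstraints()
    fwd = _candidate_sites(template.seq, 0, template.up_len, c)
    rev = _candidate_sites(template.seq, template.down_start, len(template.seq), c)
    if not fwd or not rev:
        logger.info("no primer candidates pass the Tm window")
        return None
    best = None
    best_key = None
    for f_start, f_end, f_seq, f_tm, f_pen in fwd:
        for r_start, r_end, r_site, r_tm, r_pen in rev:
            product = r_end - f_start
            if not c.product_min <= product <= c.product_max:
                continue
            score = (
                abs(f_tm - c.tm_opt)
                + abs(r_tm - c.tm_opt)
                + abs(f_tm - r_tm)
                + f_pen
                + r_pen
            )
            r_seq = revcomp(r_site)
            key = (score, product, f_start, f_seq, r_seq)
            if best_key is None or key < best_key:
                best_key = key
                best = PrimerPair(
                    forward_seq=f_seq,
                    reverse_seq=r_seq,
                    tm_forward=f_tm,
                    tm_reverse=r_tm,
                    product_size_ref=product,
                )
    if best is None:
        logger.info("no primer pair satisfies the product-size window")
    return best


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------

def _count_sites(haystack: str, needle: str) -> list[int]:
    """Start indices of (possibly overlapping) exact matches."""
    sites = []
    start = haystack.find(needle)
    while start != -1:
        sites.append(start)
        start = haystack.find(needle, start + 1)
    return sites


def predict_product(primers: PrimerPair, sequence: str) -> Optional[int]:
    """Exact-match amplicon size on one template, or None.

    The forward primer must match the plus strand exactly once and the
    reverse primer's reverse complement likewise; the product spans both
    primers inclusively.  Zero or multiple binding sites for either primer
    yield None (no single clean band).
    """
    fwd_sites = _count_sites(sequence, primers.forward_seq)
    rev_sites = _count_sites(sequence, revcomp(primers.reverse_seq))
    if len(fwd_sites) != 1 or len(rev_sites) != 1:
        return None
    f_start = fwd_sites[0]
    r_end = rev_sites[0] + len(primers.reverse_seq)
    if r_end <= f_start + len(primers.forward_seq):
        return None
    return r_end - f_start


def assign_gel_class(marker: MarkerCandidate) -> str:
    """Agarose iff the parental product sizes differ by more than 30 bp."""
    return gel_class_for_diff(marker.source.allele_size_diff)


# ---------------------------------------------------------------------------
# Marker pipeline
# ---------------------------------------------------------------------------

def _parent_calls(indel: CrossParentIndel) -> tuple[IndelCall | None, IndelCall | None]:
    if indel.carrier == CARRIER_A:
        return indel.call, None
    if indel.carrier == CARRIER_B:
        return None, indel.call
    return indel.call, indel.call_other


def design_marker(
    genome: ReferenceGenome,
    indel: CrossParentIndel,
    marker_id: str,
    constraints: DesignConstraints | None = None,
    flank_len: int = 150,
) -> MarkerCandidate:
    """Design one marker: template, primers, per-parent in-silico products."""
    template = extract_locus_template(genome, indel, flank_len)
    primers = design_primers(template, constraints)
    marker = MarkerCandidate(id=marker_id, source=indel, template=template.seq,
                             primers=primers)
    if primers is not None:
        call_a, call_b = _parent_calls(indel)
        marker.product_size_a = predict_product(
            primers, allele_sequence(template, call_a))
        marker.product_size_b = predict_product(
            primers, allele_sequence(template, call_b))
    return marker


def design_markers(
    genome: ReferenceGenome,
    indels: Sequence[CrossParentIndel],
    constraints: DesignConstraints | None = None,
    flank_len: int = 150,
    id_prefix: str = "InDel",
) -> list[MarkerCandidate]:
    """Design markers for a sorted cross-parent InDel list (ids are 1-based)."""
    width = max(3, len(str(len(indels))))
    return [
        design_marker(genome, x, f"{id_prefix}{i:0{width}d}", constraints, flank_len)
        for i, x in enumerate(indels, start=1)
    ]


def subsample_markers(
    markers: Sequence[MarkerCandidate], n: int, seed: int
) -> list[MarkerCandidate]:
    """Seeded random subsample without replacement (cost-driven selection step)."""
    if n >= len(markers):
        return list(markers)
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(markers), size=n, replace=False))
    return [markers[i] for i in idx]
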