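"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: a reference
genome, two re-sequenced inbred parents carrying planted InDels (some
parent-unique, some shared), the parent-versus-reference call sets a variant
caller would emit, genotype matrices for a panel of inbred breeding lines
with optional group structure, and F1 seedling batches with contaminants.

Default event mixtures follow the empirical genome-wide accounting of
cucumber parent-versus-reference InDels: size classes 53.9% (1-10 bp),
26.1% (11-20), 8.9% (21-30), 11.1% (>30) with ~49.4% insertions.  Events
are spaced (default >= 200 bp) so flank extraction and primer design never
straddle two events; a configurable fraction (default 10%) is planted
inside generated homopolymer tracts and exported with a randomized anchor
to exercise call normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .discovery import normalize_indel
from .genotypes import GenotypeMatrix
from .purity import (
    CLASS_HYBRID,
    CLASS_MISSING,
    CLASS_OFF_TYPE,
    CLASS_SELFED_FEMALE,
    CLASS_SELFED_MALE,
)
from .types import IndelCall, ReferenceGenome

SIZE_CLASS_MIXTURE = {
    "small": 0.539,
    "medium_11_20": 0.261,
    "medium_21_30": 0.089,
    "large": 0.111,
}
_SIZE_RANGES = {
    "small": (1, 10),
    "medium_11_20": (11, 20),
    "medium_21_30": (21, 30),
    "large": (31, 60),
}
INSERTION_FRACTION = 5208 / 10552

CATEGORY_A_ONLY = "A_only"
CATEGORY_B_ONLY = "B_only"
CATEGORY_SHARED = "shared"


@dataclass
class SimulationConfig:
    """Knobs of the genome/parent simulator; defaults mirror the study design."""

    seed: int = 0
    n_chrom: int = 7
    chrom_length: int = 100_000
    gc: float = 0.35
    n_a_only: int = 100
    n_b_only: int = 50
    n_shared: int = 25
    size_class_probs: dict = field(default_factory=lambda: dict(SIZE_CLASS_MIXTURE))
    insertion_prob: float = INSERTION_FRACTION
    min_spacing: int = 200
    repeat_fraction: float = 0.10
    edge_margin: int = 300

    def __post_init__(self) -> None:
        total = sum(self.size_class_probs.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"size-class proportions sum to {total}, not 1")
        if self.min_spacing < 1:
            raise ValueError("min_spacing must be >= 1")
        if min(self.n_a_only, self.n_b_only, self.n_shared) < 0:
            raise ValueError("event counts must be >= 0")


def simulate_reference(config: SimulationConfig) -> ReferenceGenome:
    """I.i.d. reference genome at the configured GC fraction."""
    rng = np.random.default_rng(config.seed)
    p_gc = config.gc / 2.0
    p_at = (1.0 - config.gc) / 2.0
    bases = np.array(list("ACGT"))
    sequences = {}
    for i in range(1, config.n_chrom + 1):
        draws = rng.choice(4, size=config.chrom_length, p=[p_at, p_gc, p_gc, p_at])
        sequences[f"Chr{i}"] = "".join(bases[draws])
    return ReferenceGenome(sequences=sequences)


@dataclass(frozen=True)
class PlantedEvent:
    """One planted InDel: canonical truth plus its exported representation."""

    category: str
    canonical: IndelCall
    exported: IndelCall
    in_repeat: bool


@dataclass
class PlantedData:
    """Simulated parents with full ground truth.

    ``reference`` is the generator's own copy of the input genome (repeat
    tracts are written into it); downstream modules must use this copy.
    """

    reference: ReferenceGenome
    parent_a: ReferenceGenome
    parent_b: ReferenceGenome
    truth: list[PlantedEvent]
    calls_a: list[IndelCall]
    calls_b: list[IndelCall]


def _apply_calls(sequences: dict[str, str], calls: Sequence[IndelCall]) -> dict[str, str]:
    """Apply non-overlapping calls to chromosome strings (descending position)."""
    out = dict(sequences)
    by_chrom: dict[str, list[IndelCall]] = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, chrom_calls in by_chrom.items():
        seq = out[chrom]
        for c in sorted(chrom_calls, key=lambda c: -c.pos):
            seq = seq[: c.pos - 1] + c.alt_allele + seq[c.pos - 1 + len(c.ref_allele) :]
        out[chrom] = seq
    return out


def plant_indels(genome: ReferenceGenome, config: SimulationConfig) -> PlantedData:
    """Plant parent-unique and shared InDels; export per-parent call sets.

    A-only events mutate only parent A, B-only only parent B, shared events
    mutate both identically.  Sizes are drawn from the configured class
    mixture (uniform within class; large uniform on 31-60 bp).  Repeat-tract
    events are exported anchored at a random offset inside the tract; their
    canonical (left-aligned) form is recorded in the truth table.
    """
    rng = np.random.default_rng(config.seed + 1)
    sequences = dict(genome.sequences)
    chroms = sorted(sequences)
    chrom_lens = np.array([len(sequences[c]) for c in chroms], dtype=float)
    chrom_p = chrom_lens / chrom_lens.sum()

    labels = list(config.size_class_probs)
    probs = np.array([config.size_class_probs[k] for k in labels])

    categories = (
        [CATEGORY_A_ONLY] * config.n_a_only
        + [CATEGORY_B_ONLY] * config.n_b_only
        + [CATEGORY_SHARED] * config.n_shared
    )
    n_events = len(categories)

    # Reserve loci first (footprint-aware spacing), then write repeat tracts
    # and build the calls against the finished reference copy.
    placements = []  # (chrom, pos, footprint, category, size, is_ins, in_repeat)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    max_tries = 200 * max(n_events, 1)
    tries = 0
    for category in categories:
        label = labels[int(rng.choice(len(labels), p=probs))]
        lo, hi = _SIZE_RANGES[label]
        size = int(rng.integers(lo, hi + 1))
        is_ins = bool(rng.random() < config.insertion_prob)
        in_repeat = bool(rng.random() < config.repeat_fraction)
        tract_len = size + int(rng.integers(2, 8)) if in_repeat else 0
        footprint = max(size + 1, tract_len + 1)
        while True:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    "infeasible packing: cannot place "
                    f"{n_events} events at spacing {config.min_spacing}"
                )
            ci = int(rng.choice(len(chroms), p=chrom_p))
            chrom = chroms[ci]
            length = len(sequences[chrom])
            lo_pos = config.edge_margin
            hi_pos = length - config.edge_margin - footprint
            if hi_pos <= lo_pos:
                continue
            pos = int(rng.integers(lo_pos, hi_pos))
            clash = any(
                pos - config.min_spacing < end and start < pos + footprint + config.min_spacing
                for start, end in occupied[chrom]
            )
            if not clash:
                occupied[chrom].append((pos, pos + footprint))
                placements.append(
                    (chrom, pos, footprint, category, size, is_ins, in_repeat, tract_len)
                )
                break

    # Write homopolymer tracts for repeat-context events.
    for chrom, pos, _fp, _cat, size, _ins, in_repeat, tract_len in placements:
        if not in_repeat:
            continue
        seq = sequences[chrom]
        base = "ACGT"[int(rng.integers(0, 4))]
        anchor = "A" if base != "A" else "C"
        sequences[chrom] = (
            seq[: pos - 1] + anchor + base * tract_len + seq[pos + tract_len :]
        )
    reference = ReferenceGenome(sequences=dict(sequences))

    truth: list[PlantedEvent] = []
    calls_a: list[IndelCall] = []
    calls_b: list[IndelCall] = []
    for chrom, pos, _fp, category, size, is_ins, in_repeat, tract_len in placements:
        seq = sequences[chrom]
        anchor_base = seq[pos - 1]
        if in_repeat:
            base = seq[pos]  # tract base
            if is_ins:
                canonical = IndelCall(chrom, pos, anchor_base, anchor_base + base * size)
                max_shift = tract_len
            else:
                canonical = IndelCall(
                    chrom, pos, anchor_base + base * size, anchor_base
                )
                max_shift = tract_len - size
            shift = int(rng.integers(0, max(max_shift, 0) + 1))
            if shift == 0:
                exported = canonical
            elif is_ins:
                exported = IndelCall(chrom, pos + shift, base, base + base * size)
            else:
                exported = IndelCall(
                    chrom,
                    pos + shift,
                    seq[pos + shift - 1 : pos + shift + size],
                    seq[pos + shift - 1],
                )
        else:
            if is_ins:
                ins = "".join(
                    "ACGT"[int(b)] for b in rng.integers(0, 4, size=size)
                )
                raw = IndelCall(chrom, pos, anchor_base, anchor_base + ins)
            else:
                raw = IndelCall(
                    chrom, pos, seq[pos - 1 : pos + size], anchor_base
                )
            canonical = normalize_indel(raw, reference)
            exported = raw
        truth.append(PlantedEvent(category, canonical, exported, in_repeat))
        if category in (CATEGORY_A_ONLY, CATEGORY_SHARED):
            calls_a.append(exported)
        if category in (CATEGORY_B_ONLY, CATEGORY_SHARED):
            calls_b.append(exported)

    parent_a = ReferenceGenome(
        sequences=_apply_calls(sequences, [e.canonical for e in truth
                                           if e.category != CATEGORY_B_ONLY])
    )
    parent_b = ReferenceGenome(
        sequences=_apply_calls(sequences, [e.canonical for e in truth
                                           if e.category != CATEGORY_A_ONLY])
    )
    calls_a.sort()
    calls_b.sort()
    truth.sort(key=lambda e: (e.canonical.chrom, e.canonical.pos))
    return PlantedData(reference, parent_a, parent_b, truth, calls_a, calls_b)


# ---------------------------------------------------------------------------
# Genotype panels
# ---------------------------------------------------------------------------

def simulate_genotype_matrix(
    n_lines: int,
    marker_freqs: dict[str, dict[int, float]],
    seed: int,
    het_rate: float = 0.0,
    n_group_markers: int = 0,
    line_prefix: str = "L",
) -> tuple[GenotypeMatrix, dict]:
    """Draw a panel of (by default fully inbred) lines.

    ``marker_freqs`` maps marker id to {allele size: frequency}.  With
    ``n_group_markers`` > 0 the panel is split into two equal groups and the
    first that many markers are fixed for alternate alleles between the
    groups (group-diagnostic markers); remaining markers draw alleles
    independently per line.  ``het_rate`` is the per-call probability of a
    heterozygous draw (two distinct alleles) at non-diagnostic markers.

    Returns the matrix plus a truth dict with group labels and the input
    frequencies.
    """
    rng = np.random.default_rng(seed)
    line_ids = [f"{line_prefix}{i + 1:03d}" for i in range(n_lines)]
    half = n_lines // 2
    groups = {line: (1 if i < half else 2) for i, line in enumerate(line_ids)}
    marker_ids = list(marker_freqs)
    calls = {}
    for mi, marker in enumerate(marker_ids):
        freqs = marker_freqs[marker]
        alleles = sorted(freqs)
        p = np.array([freqs[a] for a in alleles], dtype=float)
        if not np.isclose(p.sum(), 1.0, atol=1e-8):
            raise ValueError(f"frequencies for {marker!r} do not sum to 1")
        diagnostic = mi < n_group_markers
        if diagnostic and len(alleles) < 2:
            raise ValueError(f"group marker {marker!r} needs >= 2 alleles")
        for line in line_ids:
            if diagnostic:
                allele = alleles[0] if groups[line] == 1 else alleles[1]
                calls[(line, marker)] = frozenset({allele})
            elif len(alleles) >= 2 and rng.random() < het_rate:
                pair = rng.choice(len(alleles), size=2, replace=False, p=p)
                calls[(line, marker)] = frozenset(
                    {alleles[int(pair[0])], alleles[int(pair[1])]}
                )
            else:
                allele = alleles[int(rng.choice(len(alleles), p=p))]
                calls[(line, marker)] = frozenset({allele})
    matrix = GenotypeMatrix(line_ids, marker_ids, calls)
    return matrix, {"groups": groups, "marker_freqs": marker_freqs}


# ---------------------------------------------------------------------------
# F1 seedling batches
# ---------------------------------------------------------------------------

def simulate_f1_batch(
    female_allele: int,
    male_allele: int,
    n: int,
    hybrid_fraction: float,
    contaminants: Optional[dict[str, float]] = None,
    seed: int = 0,
    off_type_allele: Optional[int] = None,
) -> tuple[list[Optional[frozenset]], list[str]]:
    """Simulate a seed lot of n individuals with known class labels.

    ``contaminants`` maps class name (selfed_female, selfed_male, off_type,
    missing) to its fraction; fractions plus ``hybrid_fraction`` must sum to
    1.  Class counts are allocated exactly (largest-remainder rounding) and
    the individuals shuffled, so the batch composition is the configured one.
    """
    contaminants = dict(contaminants or {})
    fractions = {CLASS_HYBRID: hybrid_fraction, **contaminants}
    bad = set(fractions) - {
        CLASS_HYBRID, CLASS_SELFED_FEMALE, CLASS_SELFED_MALE,
        CLASS_OFF_TYPE, CLASS_MISSING,
    }
    if bad:
        raise ValueError(f"unknown classes {sorted(bad)}")
    total = sum(fractions.values())
    if not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"class fractions sum to {total}, not 1")
    if off_type_allele is None:
        off_type_allele = max(female_allele, male_allele) + 22

    # largest-remainder allocation of exact counts
    raw = {k: v * n for k, v in fractions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    for k in sorted(raw, key=lambda k: (raw[k] - counts[k]), reverse=True)[:short]:
        counts[k] += 1

    bands = {
        CLASS_HYBRID: frozenset({female_allele, male_allele}),
        CLASS_SELFED_FEMALE: frozenset({female_allele}),
        CLASS_SELFED_MALE: frozenset({male_allele}),
        CLASS_OFF_TYPE: frozenset({off_type_allele}),
        CLASS_MISSING: None,
    }
    labels = [k for k, c in counts.items() for _ in range(c)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    calls = [bands[label] for label in labels]
    return calls, labels
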