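"""Hybrid-seed purity scoring from co-dominant marker calls.

A co-dominant InDel marker amplifies a different-sized product from each
parent of an F1 hybrid.  A true hybrid seedling shows both parental bands
simultaneously; a selfed seedling shows only its seed parent's band; a band
matching neither parent marks an off-type contaminant.  Batch purity is the
fraction of classified (non-missing) individuals scored as true hybrids.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

CLASS_HYBRID = "true_hybrid"
CLASS_SELFED_FEMALE = "selfed_female"
CLASS_SELFED_MALE = "selfed_male"
CLASS_OFF_TYPE = "off_type"
CLASS_MISSING = "missing"

CLASSES = (
    CLASS_HYBRID,
    CLASS_SELFED_FEMALE,
    CLASS_SELFED_MALE,
    CLASS_OFF_TYPE,
    CLASS_MISSING,
)


@dataclass
class PurityResult:
    """Per-individual classes and the batch purity percentage."""

    classes: list[str]
    counts: Counter = field(default_factory=Counter)
    purity_percent: float = 0.0

    @property
    def n_classified(self) -> int:
        return len(self.classes) - self.counts[CLASS_MISSING]


def classify_individual(
    call: Optional[frozenset],
    female_allele: int,
    male_allele: int,
    tolerance: int = 0,
) -> str:
    """Classify one seedling's call against the two parental band sizes.

    Band-size matching uses ``tolerance`` bp (0 for in-silico sizes; widen
    for gel-estimated sizes).  The marker is unusable when the parental
    bands are indistinguishable under the tolerance.
    """
    if abs(female_allele - male_allele) <= 2 * tolerance:
        raise ValueError(
            f"parental alleles {female_allele} and {male_allele} are not "
            f"distinguishable at tolerance {tolerance} bp"
        )
    if call is None or not call:
        return CLASS_MISSING
    has_female = any(abs(b - female_allele) <= tolerance for b in call)
    has_male = any(abs(b - male_allele) <= tolerance for b in call)
    stray = any(
        abs(b - female_allele) > tolerance and abs(b - male_allele) > tolerance
        for b in call
    )
    if stray:
        return CLASS_OFF_TYPE
    if has_female and has_male:
        return CLASS_HYBRID
    if has_female:
        return CLASS_SELFED_FEMALE
    return CLASS_SELFED_MALE


def batch_purity(
    calls: Sequence[Optional[frozenset]],
    female_allele: int,
    male_allele: int,
    tolerance: int = 0,
) -> PurityResult:
    """Score a seedling batch at one marker.

    Purity = true hybrids / classified individuals * 100; missing calls are
    reported separately and excluded from the denominator.
    """
    if not calls:
        raise ValueError("empty batch")
    classes = [
        classify_individual(c, female_allele, male_allele, tolerance) for c in calls
    ]
    counts = Counter(classes)
    classified = len(calls) - counts[CLASS_MISSING]
    if classified == 0:
        raise ValueError("every individual in the batch is missing")
    purity = 100.0 * counts[CLASS_HYBRID] / classified
    return PurityResult(classes=classes, counts=counts, purity_percent=purity)


def combine_classes(per_marker: Sequence[str]) -> str:
    """Combine one individual's per-marker classes (conservative AND rule).

    True hybrid only if hybrid at every informative marker; conflicting
    selfed calls (female at one marker, male at another) or any off-type
    band mark the individual as off-type.
    """
    informative = [c for c in per_marker if c != CLASS_MISSING]
    if not informative:
        return CLASS_MISSING
    if all(c == CLASS_HYBRID for c in informative):
        return CLASS_HYBRID
    if CLASS_OFF_TYPE in informative:
        return CLASS_OFF_TYPE
    selfed = {c for c in informative if c in (CLASS_SELFED_FEMALE, CLASS_SELFED_MALE)}
    if len(selfed) > 1:
        return CLASS_OFF_TYPE
    return selfed.pop()


def batch_purity_multi(
    calls_by_marker: Mapping[str, Sequence[Optional[frozenset]]],
    parental_alleles: Mapping[str, tuple[int, int]],
    tolerance: int = 0,
) -> tuple[PurityResult, dict[str, PurityResult]]:
    """Score a batch at several markers and combine per individual.

    ``parental_alleles`` maps marker id to (female band, male band).
    Returns the combined result plus each marker's own result.
    """
    per_marker: dict[str, PurityResult] = {}
    n = None
    for marker, calls in calls_by_marker.items():
        if n is None:
            n = len(calls)
        elif len(calls) != n:
            raise ValueError("marker call lists differ in length")
        female, male = parental_alleles[marker]
        per_marker[marker] = batch_purity(calls, female, male, tolerance)
    if not per_marker:
        raise ValueError("no markers supplied")
    combined_classes = [
        combine_classes([per_marker[m].classes[i] for m in per_marker])
        for i in range(n)
    ]
    counts = Counter(combined_classes)
    classified = n - counts[CLASS_MISSING]
    if classified == 0:
        raise ValueError("every individual in the batch is missing")
    combined = PurityResult(
        classes=combined_classes,
        counts=counts,
        purity_percent=100.0 * counts[CLASS_HYBRID] / classified,
    )
    return combined, per_marker
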