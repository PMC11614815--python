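"""Read classification and apportioned counting.

A mapped read is classified by length and feature overlap: any overlap
with a contamination class (miRNA, rRNA, snRNA, simple repeat, low
complexity) excludes it from the piRNA/siRNA pools; otherwise a
TE-overlapping read of 24-32 nt is a piRNA and one of 18-23 nt an siRNA
candidate.  Overlap for exclusion is strand-blind: the exclusion lists
act as contamination filters, not expression calls.

Counting is apportioned twice over: each genomic mapping carries weight
``1/mapping_count``, and that weight is further split evenly across the
features the mapping overlaps, so the total counted mass always equals
the number of distinct sequenced reads.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping

from .model import AlignedRead, FeatureIndex

#: precedence when a read overlaps several excluded classes
EXCLUSION_PRECEDENCE = ("miRNA", "rRNA", "snRNA", "simple_repeat", "low_complexity")

LABELS = ("miRNA", "rRNA_like", "piRNA", "siRNA_candidate", "unassigned")


@dataclass(frozen=True)
class ClassRanges:
    """Inclusive length windows for the small-RNA classes (nt)."""

    pirna: tuple[int, int] = (24, 32)
    sirna: tuple[int, int] = (18, 23)


def filter_by_length(
    reads: Iterable[AlignedRead], min_nt: int, max_nt: int
) -> list[AlignedRead]:
    """Reads with ``min_nt <= length <= max_nt``, order preserved."""
    if min_nt > max_nt:
        raise ValueError(f"min_nt {min_nt} > max_nt {max_nt}")
    return [r for r in reads if min_nt <= r.length <= max_nt]


def matched_exclusion(read: AlignedRead, index: FeatureIndex) -> str | None:
    """First excluded class the read overlaps, in precedence order."""
    hits = {f.feature_class for f in index.overlapping(read.interval)}
    for cls in EXCLUSION_PRECEDENCE:
        if cls in hits:
            return cls
    return None


def classify_read(
    read: AlignedRead,
    index: FeatureIndex,
    ranges: ClassRanges = ClassRanges(),
) -> str:
    """Assign one of the five small-RNA class labels to a read.

    Exclusion wins over everything: a miRNA overlap yields "miRNA", any
    other structural/repeat contamination yields "rRNA_like".  Among the
    remaining reads, TE overlap plus the piRNA length window yields
    "piRNA", the siRNA window "siRNA_candidate"; everything else is
    "unassigned".
    """
    excluded = matched_exclusion(read, index)
    if excluded == "miRNA":
        return "miRNA"
    if excluded is not None:
        return "rRNA_like"
    if index.overlapping(read.interval, feature_class="TE"):
        if ranges.pirna[0] <= read.length <= ranges.pirna[1]:
            return "piRNA"
        if ranges.sirna[0] <= read.length <= ranges.sirna[1]:
            return "siRNA_candidate"
    return "unassigned"


_GROUPERS = {
    "name": lambda f: f.name,
    "family": lambda f: f.family,
    "feature_class": lambda f: f.feature_class,
}


def apportioned_counts(
    reads: Iterable[AlignedRead],
    index: FeatureIndex,
    by: str = "name",
) -> dict[str, float]:
    """Fractional counts per feature group.

    Each mapping contributes ``weight / n_overlapping_features`` to every
    feature it overlaps; mappings overlapping nothing accumulate under
    "unassigned".  Summed over all groups the result equals the number of
    distinct read ids (conservation).
    """
    if by not in _GROUPERS:
        raise ValueError(f"unknown grouping {by!r}; use one of {sorted(_GROUPERS)}")
    key = _GROUPERS[by]
    counts: dict[str, float] = defaultdict(float)
    for read in reads:
        hits = index.overlapping(read.interval)
        if not hits:
            counts["unassigned"] += read.weight
        else:
            share = read.weight / len(hits)
            for feat in hits:
                counts[key(feat)] += share
    return dict(counts)


def rpm(count: float, mapped_total: int) -> float:
    """Reads per million mapped: count * 1e6 / mapped_total."""
    if mapped_total <= 0:
        raise ValueError(f"mapped_total must be positive, got {mapped_total}")
    return count * 1e6 / mapped_total


def length_histogram(
    reads: Iterable[AlignedRead],
    mapped_total: int,
    index: FeatureIndex | None = None,
    te_only: bool = False,
) -> dict[int, float]:
    """Apportioned RPM per integer read length.

    With ``te_only`` the histogram is restricted to mappings overlapping
    a TE annotation (the repeat-associated length profile).
    """
    if te_only and index is None:
        raise ValueError("te_only requires an annotation index")
    mass: dict[int, float] = defaultdict(float)
    for read in reads:
        if te_only and not index.overlapping(read.interval, feature_class="TE"):
            continue
        mass[read.length] += read.weight
    return {length: rpm(m, mapped_total) for length, m in sorted(mass.items())}


def class_summary(
    reads: list[AlignedRead],
    index: FeatureIndex,
    ranges: ClassRanges = ClassRanges(),
) -> "Mapping[str, dict[str, float]]":
    """Per-class apportioned read mass and percentage (library profile).

    A multi-mapping read contributes ``1/mapping_count`` per mapping under
    the label of each mapping, so classes partition the distinct-read mass.
    """
    mass: dict[str, float] = defaultdict(float)
    for read in reads:
        mass[classify_read(read, index, ranges)] += read.weight
    total = sum(mass.values())
    return {
        label: {
            "count": mass.get(label, 0.0),
            "percent": 100.0 * mass.get(label, 0.0) / total if total else 0.0,
        }
        for label in LABELS
    }
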