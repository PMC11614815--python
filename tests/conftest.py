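"""Shared fixtures, read factories and independent brute-force oracles.

The oracles deliberately re-derive each statistic from its definition
(window-by-window scans, all-pairs enumerations) without touching the
optimised implementation paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from pirnakit.model import AlignedRead, ClusterCallParams, GenomicInterval

_counter = itertools.count()


def make_read(
    scaffold: str = "s1",
    start: int = 100,
    length: int = 28,
    strand: str = "+",
    read_id: str | None = None,
    mapping_count: int = 1,
    sequence: str | None = None,
) -> AlignedRead:
    if read_id is None:
        read_id = f"t{next(_counter):06d}"
    if sequence is None:
        sequence = "A" * length
    return AlignedRead(
        read_id=read_id,
        sequence=sequence,
        interval=GenomicInterval(scaffold, start, start + length, strand),
        mapping_count=mapping_count,
    )


# ---------------------------------------------------------------------------
# brute-force oracles


def oracle_call_clusters(reads, scaffold_sizes, params: ClusterCallParams):
    """Naive all-windows cluster enumeration straight from the definition.

    Returns {scaffold: [(start, end), ...]} of final cluster intervals.
    """
    if params.unique_only:
        reads = [r for r in reads if r.mapping_count == 1]
    out = {}
    for scaffold, size in scaffold_sizes.items():
        sreads = [r for r in reads if r.interval.scaffold == scaffold]
        retained = []
        start = 0
        while start < size:
            end = min(start + params.window_size, size)
            width = end - start
            n5 = sum(1 for r in sreads if start <= r.five_prime < end)
            covered = set()
            for r in sreads:
                lo, hi = max(r.interval.start, start), min(r.interval.end, end)
                if lo < hi:
                    covered.update(range(lo, hi))
            density_ok = n5 / (width / 1000.0) > params.min_density
            coverage_ok = len(covered) / width >= params.min_cov_frac
            if density_ok and coverage_ok:
                retained.append((start, end))
            start += params.step
        merged = []
        for s, e in sorted(retained):
            if merged and s < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        combined = []
        for s, e in merged:
            if combined and s - combined[-1][1] < params.merge_gap:
                combined[-1][1] = max(combined[-1][1], e)
            else:
                combined.append([s, e])
        out[scaffold] = [(s, e) for s, e in combined]
    return out


def clusters_as_dict(clusters):
    out = {}
    for c in clusters:
        out.setdefault(c.interval.scaffold, []).append(
            (c.interval.start, c.interval.end)
        )
    for v in out.values():
        v.sort()
    return out


def oracle_pingpong_counts(sense_reads, antisense_reads, max_overlap=30):
    """O(n^2) all-pairs 5'-5' overlap enumeration."""
    counts = np.zeros(max_overlap + 1)
    for a in sense_reads:
        for b in antisense_reads:
            if a.interval.scaffold != b.interval.scaffold:
                continue
            if a.strand == b.strand:
                continue
            plus, minus = (a, b) if a.strand == "+" else (b, a)
            k = minus.five_prime - plus.five_prime + 1
            if 1 <= k <= max_overlap and k <= plus.length and k <= minus.length:
                counts[k] += a.weight * b.weight
    return counts[1:]


def oracle_phasing_counts(reads, max_distance=50):
    """O(n^2) all-pairs 3'->5' distance enumeration on each strand."""
    counts = np.zeros(max_distance + 1)
    for up in reads:
        for down in reads:
            if up is down:
                continue
            if up.interval.scaffold != down.interval.scaffold:
                continue
            if up.strand != down.strand:
                continue
            if up.strand == "+":
                d = down.five_prime - (up.three_prime + 1)
            else:
                d = (up.three_prime - 1) - down.five_prime
            if 0 <= d <= max_distance:
                counts[d] += up.weight * down.weight
    return counts


def oracle_paired_ids(reads, max_overlap=30):
    paired = set()
    for a in reads:
        for b in reads:
            if a.interval.scaffold != b.interval.scaffold or a.strand == b.strand:
                continue
            plus, minus = (a, b) if a.strand == "+" else (b, a)
            k = minus.five_prime - plus.five_prime + 1
            if 1 <= k <= max_overlap and k <= plus.length and k <= minus.length:
                paired.add(a.read_id)
                paired.add(b.read_id)
    return paired


# ---------------------------------------------------------------------------
# shared simulated sample (moderate size, reused across test modules)


@pytest.fixture(scope="session")
def default_sample():
    from pirnakit.simulate import SimulationConfig, simulate_sample

    cfg = SimulationConfig(seed=7, n_reads=3000)
    return simulate_sample(cfg)
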