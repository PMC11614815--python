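"""piRNA cluster calling by sliding-window density, and cluster descriptors.

The caller slides a 5 kb window in 1 kb steps along each scaffold
(windows are clipped at scaffold ends and a terminal partial window uses
its actual size in both criteria).  A window is retained when the number
of uniquely-mapping piRNA 5' ends inside it exceeds 5 per kb (strict >)
AND the fraction of window bases covered by read intervals is at least
12% (>=).  Overlapping retained windows are unioned, and unions separated
by less than 20 kb (strict <) are combined into one cluster.  Clusters
are ranked by descending read support and named cluster_1, cluster_2, ...

A read belongs to a window by its 5'-end position; coverage counts the
bases of full read intervals.  Density and coverage are therefore two
distinct criteria, which is why a handful of stacked reads can satisfy
the density threshold yet fail coverage.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AlignedRead,
    ClusterCallParams,
    GenomicInterval,
    PiRNACluster,
    distinct_read_count,
)


def _merge_overlapping(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of overlapping (not merely touching) half-open intervals."""
    if not windows:
        return []
    windows = sorted(windows)
    merged = [list(windows[0])]
    for start, end in windows[1:]:
        if start < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(w) for w in merged]


def _combine_by_gap(intervals: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    """Combine intervals whose separation is strictly below ``gap``."""
    if not intervals:
        return []
    combined = [list(intervals[0])]
    for start, end in intervals[1:]:
        if start - combined[-1][1] < gap:
            combined[-1][1] = max(combined[-1][1], end)
        else:
            combined.append([start, end])
    return [tuple(iv) for iv in combined]


def strand_fraction_label(
    fraction_plus: float, threshold: float = 0.75
) -> str:
    """75%-rule strandness: biased when either strand reaches the threshold.

    The boundary counts as biased — a cluster is unbiased only when *less*
    than the threshold fraction of its reads sits on a single strand.
    """
    if fraction_plus >= threshold:
        return "plus"
    if (1.0 - fraction_plus) >= threshold:
        return "minus"
    return "unbiased"


def classify_cluster_strand(
    cluster: PiRNACluster | GenomicInterval,
    reads: Iterable[AlignedRead],
    threshold: float = 0.75,
) -> tuple[str, float]:
    """Strandness label and plus-strand fraction for one cluster.

    Supporting reads are those whose 5' end lies inside the cluster
    interval; a zero-support cluster is an error.
    """
    interval = cluster.interval if isinstance(cluster, PiRNACluster) else cluster
    plus = minus = 0.0
    for r in reads:
        if r.interval.scaffold != interval.scaffold:
            continue
        if interval.start <= r.five_prime < interval.end:
            if r.strand == "+":
                plus += r.weight
            else:
                minus += r.weight
    total = plus + minus
    if total == 0:
        raise ValueError("cluster has no supporting reads")
    frac_plus = plus / total
    return strand_fraction_label(frac_plus, threshold), frac_plus


def call_clusters(
    reads: Iterable[AlignedRead],
    scaffold_sizes: Mapping[str, int],
    params: ClusterCallParams = ClusterCallParams(),
    mapped_total: int | None = None,
) -> list[PiRNACluster]:
    """Call piRNA clusters from uniquely-mapping piRNA-class reads.

    ``mapped_total`` sets the RPM denominator; it defaults to the number
    of distinct read ids in the input (per-library calling would normally
    pass the library's full mapped total instead).
    """
    if not scaffold_sizes:
        raise ValueError("scaffold_sizes is empty")
    reads = list(reads)
    if params.unique_only:
        reads = [r for r in reads if r.mapping_count == 1]
    for r in reads:
        size = scaffold_sizes.get(r.interval.scaffold)
        if size is None:
            raise ValueError(f"read {r.read_id} on unknown scaffold "
                             f"{r.interval.scaffold!r}")
        if r.interval.end > size:
            raise ValueError(
                f"read {r.read_id} extends past the end of "
                f"{r.interval.scaffold} ({r.interval.end} > {size})"
            )
    if mapped_total is None:
        mapped_total = distinct_read_count(reads)

    by_scaffold: dict[str, list[AlignedRead]] = {}
    for r in reads:
        by_scaffold.setdefault(r.interval.scaffold, []).append(r)

    raw: list[tuple[str, int, int]] = []
    for scaffold in sorted(by_scaffold):
        size = scaffold_sizes[scaffold]
        sreads = by_scaffold[scaffold]
        five = np.sort(np.array([r.five_prime for r in sreads], dtype=np.int64))
        # base-resolution coverage via difference array
        diff = np.zeros(size + 1, dtype=np.int32)
        for r in sreads:
            diff[r.interval.start] += 1
            diff[r.interval.end] -= 1
        covered = (np.cumsum(diff[:-1]) > 0).astype(np.int64)
        cov_prefix = np.concatenate([[0], np.cumsum(covered)])

        retained: list[tuple[int, int]] = []
        for wstart in range(0, size, params.step):
            wend = min(wstart + params.window_size, size)
            width = wend - wstart
            if width <= 0:
                break
            n5 = np.searchsorted(five, wend, side="left") - np.searchsorted(
                five, wstart, side="left"
            )
            density = n5 / (width / 1000.0)
            if density <= params.min_density:
                continue
            cov_frac = (cov_prefix[wend] - cov_prefix[wstart]) / width
            if cov_frac < params.min_cov_frac:
                continue
            retained.append((wstart, wend))

        merged = _merge_overlapping(retained)
        for start, end in _combine_by_gap(merged, params.merge_gap):
            raw.append((scaffold, start, end))

    # support, strandness and ranking
    described: list[tuple[float, str, int, int, float]] = []
    for scaffold, start, end in raw:
        plus = minus = 0.0
        for r in by_scaffold[scaffold]:
            if start <= r.five_prime < end:
                if r.strand == "+":
                    plus += r.weight
                else:
                    minus += r.weight
        support = plus + minus
        frac_plus = plus / support if support > 0 else 0.5
        described.append((support, scaffold, start, end, frac_plus))

    described.sort(key=lambda t: (-t[0], t[1], t[2]))
    clusters = []
    for rank, (support, scaffold, start, end, frac_plus) in enumerate(described, 1):
        clusters.append(
            PiRNACluster(
                cluster_id=f"cluster_{rank}",
                interval=GenomicInterval(scaffold, start, end),
                read_count=support,
                rpm=support * 1e6 / mapped_total if mapped_total else 0.0,
                fraction_plus=frac_plus,
                strandness=strand_fraction_label(
                    frac_plus, params.strand_bias_threshold
                ),
            )
        )
    return clusters


def cumulative_share(clusters: Sequence[PiRNACluster]) -> np.ndarray:
    """Cumulative fraction of cluster read support by descending rank."""
    if not clusters:
        raise ValueError("no clusters")
    support = np.sort(np.array([c.read_count for c in clusters]))[::-1]
    total = support.sum()
    if total == 0:
        raise ValueError("clusters carry no read support")
    return np.cumsum(support) / total


def in_cluster_fraction(
    groups: Mapping[str, Sequence[AlignedRead]],
    clusters: Sequence[PiRNACluster],
) -> dict[str, float | None]:
    """Per-group fraction of reads whose 5' end lies inside any cluster.

    Empty groups are reported as ``None`` (undefined).
    """
    by_scaffold: dict[str, list[tuple[int, int]]] = {}
    for c in clusters:
        by_scaffold.setdefault(c.interval.scaffold, []).append(
            (c.interval.start, c.interval.end)
        )

    def inside(read: AlignedRead) -> bool:
        p = read.five_prime
        return any(
            s <= p < e for s, e in by_scaffold.get(read.interval.scaffold, ())
        )

    out: dict[str, float | None] = {}
    for group, reads in groups.items():
        reads = list(reads)
        if not reads:
            out[group] = None
            continue
        out[group] = sum(1 for r in reads if inside(r)) / len(reads)
    return out


def count_htt_copies_in_clusters(
    htt_annotations: Iterable,
    clusters: Sequence[PiRNACluster],
) -> dict[str, int]:
    """Per-HTT-family number of copies intersecting any cluster interval."""
    counts: dict[str, int] = {}
    for feat in htt_annotations:
        if not feat.is_htt:
            continue
        counts.setdefault(feat.family, 0)
        if any(feat.interval.overlaps(c.interval) for c in clusters):
            counts[feat.family] += 1
    return counts


def te_orientation_in_clusters(
    te_annotations: Iterable,
    clusters: Sequence[PiRNACluster],
    threshold: float = 0.75,
) -> pd.DataFrame:
    """Per-cluster TE-fragment strand tallies and 75%-rule bias label."""
    rows = []
    for c in clusters:
        n_plus = n_minus = 0
        for feat in te_annotations:
            if feat.feature_class != "TE":
                continue
            if feat.interval.overlaps(c.interval):
                if feat.interval.strand == "+":
                    n_plus += 1
                elif feat.interval.strand == "-":
                    n_minus += 1
        total = n_plus + n_minus
        label = (
            "unbiased"
            if total == 0
            else strand_fraction_label(n_plus / total, threshold)
        )
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "n_plus": n_plus,
                "n_minus": n_minus,
                "bias": label,
            }
        )
    return pd.DataFrame(rows, columns=["cluster_id", "n_plus", "n_minus", "bias"])
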