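"""Ping-pong, phasing and nucleotide-bias signature statistics.

Ping-pong: for every opposite-strand read pair on one scaffold, the
5'-5' overlap is ``k = minus_five_prime - plus_five_prime + 1`` and is
counted when both reads cover the shared register (k no longer than
either read).  A 10-nt register is the hallmark of reciprocal
PIWI-protein cleavage.

Phasing: for same-strand reads, the 3'->5' distance between an upstream
read and a downstream read is counted with half-open ends, so two
head-to-tail reads give distance 0; enrichment at 0 (Z0) indicates
processive, phased primary piRNA production.

Pair counts are apportioned — every pair contributes the product of the
two mappings' weights — so duplicating every mapping while halving its
weight leaves the statistics unchanged.

z-scores use a leave-one-out background: z(k) compares counts[k] with
the mean and (sample) standard deviation of the counts at all other
offsets.  A zero-variance background is flagged and reported as z = 0.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (
    AlignedRead,
    BaseFrequencyMatrix,
    GenomicInterval,
    SignatureResult,
)

PINGPONG_REGISTER = 10


def _loo_zscores(counts: np.ndarray) -> tuple[np.ndarray, bool]:
    """Leave-one-out z-score of each offset against all the others."""
    n = len(counts)
    z = np.zeros(n)
    degenerate = False
    if n < 3:
        return z, True
    for i in range(n):
        others = np.delete(counts, i)
        sd = others.std(ddof=1)
        if sd == 0:
            degenerate = True
            continue
        z[i] = (counts[i] - others.mean()) / sd
    return z, degenerate


def _position_weights(
    reads: Iterable[AlignedRead],
) -> dict[tuple[str, str], dict[int, list[tuple[float, int]]]]:
    """(scaffold, strand) -> 5' position -> [(weight, length), ...]."""
    table: dict[tuple[str, str], dict[int, list[tuple[float, int]]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for r in reads:
        table[(r.interval.scaffold, r.strand)][r.five_prime].append(
            (r.weight, r.length)
        )
    return table


def pingpong_histogram(
    sense_reads: Iterable[AlignedRead],
    antisense_reads: Iterable[AlignedRead],
    max_overlap: int = 30,
) -> SignatureResult:
    """5'-5' overlap-length histogram between two opposite read sets.

    Counts[k] accumulates ``w_sense * w_antisense`` over all pairs with
    overlap exactly k in [1, max_overlap].  The focal statistic is the
    z-score at the 10-nt ping-pong register.
    """
    if max_overlap < 1:
        raise ValueError("max_overlap must be >= 1")
    sense_reads = list(sense_reads)
    partner = _position_weights(antisense_reads)
    counts = np.zeros(max_overlap + 1)  # index k
    for r in sense_reads:
        opp = "-" if r.strand == "+" else "+"
        sign = 1 if r.strand == "+" else -1
        table = partner.get((r.interval.scaffold, opp))
        if not table:
            continue
        p5 = r.five_prime
        for k in range(1, min(max_overlap, r.length) + 1):
            # the partner's 5' end sits k - 1 nt downstream of ours
            hits = table.get(p5 + sign * (k - 1))
            if not hits:
                continue
            counts[k] += r.weight * sum(w for w, length in hits if length >= k)
    offsets = np.arange(1, max_overlap + 1)
    z, degenerate = _loo_zscores(counts[1:])
    focal = float(z[PINGPONG_REGISTER - 1]) if max_overlap >= PINGPONG_REGISTER else 0.0
    return SignatureResult(
        offsets=offsets,
        counts=counts[1:],
        zscores=z,
        focal=focal,
        focal_offset=PINGPONG_REGISTER,
        degenerate=degenerate,
    )


def paired_fraction(
    reads: Iterable[AlignedRead],
    max_overlap: int = 30,
) -> float | None:
    """Fraction of distinct reads with >=1 opposite-strand 5' overlap.

    A read is "paired" when some opposite-strand read 5'-overlaps it by
    any k in [1, max_overlap] (both reads covering the register).
    Returns None for empty input (undefined).
    """
    reads = list(reads)
    if not reads:
        return None
    table = _position_weights(reads)
    paired_ids: set[str] = set()
    all_ids: set[str] = set()
    for r in reads:
        all_ids.add(r.read_id)
        if r.read_id in paired_ids:
            continue
        opp = "-" if r.strand == "+" else "+"
        sign = 1 if r.strand == "+" else -1
        partner = table.get((r.interval.scaffold, opp))
        if not partner:
            continue
        p5 = r.five_prime
        for k in range(1, min(max_overlap, r.length) + 1):
            hits = partner.get(p5 + sign * (k - 1))
            if hits and any(length >= k for _, length in hits):
                paired_ids.add(r.read_id)
                break
    return len(paired_ids) / len(all_ids)


def phasing_signature(
    reads: Iterable[AlignedRead],
    max_distance: int = 50,
) -> SignatureResult:
    """3'->5' distance histogram between same-strand reads.

    For an upstream read u and a downstream read d on one strand the
    distance is ``d.five_prime - (u.three_prime + 1)`` in transcription
    direction, so immediate adjacency scores 0.  All pairs with distance
    in [0, max_distance] are counted with apportioned weight products.
    The focal statistic Z0 is the z-score at distance 0.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    reads = list(reads)
    five_index: dict[tuple[str, str], dict[int, float]] = defaultdict(
        lambda: defaultdict(float)
    )
    for r in reads:
        five_index[(r.interval.scaffold, r.strand)][r.five_prime] += r.weight
    counts = np.zeros(max_distance + 1)
    for r in reads:
        table = five_index[(r.interval.scaffold, r.strand)]
        sign = 1 if r.strand == "+" else -1
        # position a gap-0 downstream 5' end would occupy
        origin = r.three_prime + sign
        for d in range(0, max_distance + 1):
            w = table.get(origin + sign * d)
            if w:
                counts[d] += r.weight * w
    offsets = np.arange(0, max_distance + 1)
    z, degenerate = _loo_zscores(counts)
    return SignatureResult(
        offsets=offsets,
        counts=counts,
        zscores=z,
        focal=float(z[0]),
        focal_offset=0,
        degenerate=degenerate,
    )


def base_frequency_matrix(
    reads: Iterable[AlignedRead],
    length: int = 30,
) -> tuple[BaseFrequencyMatrix, float, float]:
    """Per-position base frequencies plus the 1U and 10A fractions.

    T is read as U.  Position p is computed over the distinct reads of
    length >= p (multi-mapping reads counted once).  Returns the matrix
    together with ``freq(U, 1)`` and ``freq(A, 10)``.
    """
    seqs: dict[str, str] = {}
    for r in reads:
        seqs.setdefault(r.read_id, r.sequence.upper().replace("T", "U"))
    if not seqs:
        raise ValueError("base_frequency_matrix requires at least one read")
    bases = "ACGU"
    counts = np.zeros((length, 4))
    for seq in seqs.values():
        for pos, base in enumerate(seq[:length]):
            col = bases.find(base)
            if col >= 0:
                counts[pos, col] += 1
    totals = counts.sum(axis=1, keepdims=True)
    freqs = np.divide(counts, totals, out=np.zeros_like(counts), where=totals > 0)
    df = pd.DataFrame(
        freqs, index=pd.RangeIndex(1, length + 1, name="position"), columns=list(bases)
    )
    matrix = BaseFrequencyMatrix(freqs=df, n_reads=len(seqs))
    u1 = float(df.loc[1, "U"]) if length >= 1 else 0.0
    a10 = float(df.loc[10, "A"]) if length >= 10 else 0.0
    return matrix, u1, a10


def split_by_te_strand(
    reads: Iterable[AlignedRead],
    te_index,
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Split reads into TE-sense and TE-antisense sets.

    A read joins the sense set when it overlaps >=1 TE copy on its own
    strand and the antisense set when it overlaps >=1 opposite-strand
    copy; a read straddling both orientations appears in both sets.
    """
    sense: list[AlignedRead] = []
    anti: list[AlignedRead] = []
    for r in reads:
        hits = te_index.overlapping(r.interval, feature_class="TE")
        if any(f.interval.strand == r.strand for f in hits):
            sense.append(r)
        if any(f.interval.strand != r.strand for f in hits):
            anti.append(r)
    return sense, anti


def shuffle_read_positions(
    reads: Sequence[AlignedRead],
    scaffold_sizes: Mapping[str, int],
    rng: np.random.Generator,
) -> list[AlignedRead]:
    """Positional null model: uniform re-placement on the same scaffold.

    Lengths, strands, scaffolds, ids and weights are preserved; only the
    start coordinates are redrawn, destroying any 5'-5' or 3'->5'
    register between reads.
    """
    shuffled = []
    for r in reads:
        size = scaffold_sizes[r.interval.scaffold]
        start = int(rng.integers(0, size - r.length + 1))
        shuffled.append(
            AlignedRead(
                read_id=r.read_id,
                sequence=r.sequence,
                interval=GenomicInterval(
                    r.interval.scaffold, start, start + r.length, r.strand
                ),
                mapping_count=r.mapping_count,
            )
        )
    return shuffled
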