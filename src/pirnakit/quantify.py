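"""Strand-aware sense/antisense quantification and normalisation.

Sense and antisense are defined read-strand versus feature-strand at the
genomic locus.  For per-position profiles along a TE family consensus,
genomic reads are first projected through each insertion's orientation
(a read antisense to a minus-strand copy is sense in consensus space).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import rpm
from .model import (
    AlignedRead,
    ExpressionMatrix,
    FeatureAnnotation,
    FeatureIndex,
    GenomicInterval,
    distinct_read_count,
    opposite,
)


def _te_index(te_annotations: Sequence[FeatureAnnotation]) -> FeatureIndex:
    tes = [f for f in te_annotations if f.feature_class == "TE"]
    for f in tes:
        if f.interval.strand not in ("+", "-"):
            raise ValueError(
                f"TE record {f.name or f.family!r} is unstranded; "
                "sense/antisense split requires strand-bearing annotations"
            )
    return FeatureIndex(tes)


def sense_antisense_counts(
    reads: Iterable[AlignedRead],
    te_annotations: Sequence[FeatureAnnotation],
    by: str = "family",
    unit: str = "count",
    mapped_total: int | None = None,
    sample: str = "sample",
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Apportioned sense and antisense counts per TE group.

    A mapping overlapping several TE copies splits its weight evenly among
    them; each share lands in the sense matrix when read strand equals the
    copy's strand, else in the antisense matrix.  ``unit`` may be
    ``count``, ``RPM`` or ``log10RPM1`` (the latter two need
    ``mapped_total``).
    """
    reads = list(reads)
    index = _te_index(te_annotations)
    keyfn = {"family": lambda f: f.family, "name": lambda f: f.name}[by]
    sense: dict[str, float] = defaultdict(float)
    anti: dict[str, float] = defaultdict(float)
    for read in reads:
        hits = index.overlapping(read.interval)
        if not hits:
            continue
        share = read.weight / len(hits)
        for feat in hits:
            bucket = sense if feat.interval.strand == read.strand else anti
            bucket[keyfn(feat)] += share

    groups = sorted(set(sense) | set(anti))
    sense_df = pd.DataFrame(
        {sample: [sense.get(g, 0.0) for g in groups]}, index=pd.Index(groups, name="feature")
    )
    anti_df = pd.DataFrame(
        {sample: [anti.get(g, 0.0) for g in groups]}, index=pd.Index(groups, name="feature")
    )

    def finish(df: pd.DataFrame) -> ExpressionMatrix:
        if unit == "count":
            return ExpressionMatrix(df, "count")
        if mapped_total is None:
            raise ValueError(f"unit {unit!r} requires mapped_total")
        as_rpm = ExpressionMatrix(df * 1e6 / mapped_total, "RPM")
        if unit == "RPM":
            return as_rpm
        if unit == "log10RPM1":
            return as_rpm.to_log10_rpm1()
        raise ValueError(f"unsupported unit {unit!r}")

    return finish(sense_df), finish(anti_df)


def project_reads_to_consensus(
    reads: Iterable[AlignedRead],
    copies: Sequence[FeatureAnnotation],
    consensus_name: str,
    consensus_length: int,
) -> list[AlignedRead]:
    """Project genomic mappings into a TE family's consensus coordinates.

    Only mappings fully contained in a copy whose consensus span covers
    them are projected.  The projected strand is the read strand for a
    plus-orientation copy and flipped for a minus-orientation insertion.
    """
    index = FeatureIndex([c for c in copies if c.feature_class == "TE"])
    projected: list[AlignedRead] = []
    for read in reads:
        iv = read.interval
        for copy in index.overlapping(iv):
            civ = copy.interval
            if not (civ.start <= iv.start and iv.end <= civ.end):
                continue
            if civ.strand == "+":
                c_start = copy.consensus_start + (iv.start - civ.start)
                strand = read.strand
            else:
                c_start = copy.consensus_start + (civ.end - iv.end)
                strand = opposite(read.strand)
            if c_start < 0 or c_start + read.length > consensus_length:
                continue
            projected.append(
                AlignedRead(
                    read_id=read.read_id,
                    sequence=read.sequence,
                    interval=GenomicInterval(
                        consensus_name, c_start, c_start + read.length, strand
                    ),
                    mapping_count=read.mapping_count,
                )
            )
            break
    return projected


def consensus_profile(
    reads: Iterable[AlignedRead],
    consensus_length: int,
    mapped_total: int,
) -> pd.DataFrame:
    """Signed per-position RPM track along a consensus.

    Every position covered by a sense (plus-strand, in consensus space)
    mapping gains its apportioned RPM; antisense coverage is accumulated
    as negative values.  Columns: position, sense_rpm, antisense_rpm.
    """
    sense = np.zeros(consensus_length)
    anti = np.zeros(consensus_length)
    for read in reads:
        iv = read.interval
        if iv.start < 0 or iv.end > consensus_length:
            raise ValueError(
                f"read {read.read_id} at [{iv.start}, {iv.end}) lies outside "
                f"the consensus [0, {consensus_length})"
            )
        w = rpm(read.weight, mapped_total)
        if read.strand == "+":
            sense[iv.start : iv.end] += w
        else:
            anti[iv.start : iv.end] -= w
    return pd.DataFrame(
        {
            "position": np.arange(consensus_length),
            "sense_rpm": sense,
            "antisense_rpm": anti,
        }
    )


def rpkm(count: float, feature_length_nt: int, mapped_total: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_length_nt <= 0:
        raise ValueError("feature length must be positive")
    if mapped_total <= 0:
        raise ValueError("mapped_total must be positive")
    return count / ((feature_length_nt / 1e3) * (mapped_total / 1e6))


def rpkm_matrix(
    counts: dict[str, float],
    lengths: dict[str, int],
    mapped_total: int,
    sample: str = "sample",
) -> ExpressionMatrix:
    """RPKM matrix from per-feature counts and feature lengths (nt)."""
    features = sorted(counts)
    missing = [f for f in features if f not in lengths]
    if missing:
        raise ValueError(f"no length for features: {missing}")
    values = [rpkm(counts[f], lengths[f], mapped_total) for f in features]
    return ExpressionMatrix(
        pd.DataFrame({sample: values}, index=pd.Index(features, name="feature")),
        "RPKM",
    )


def fold_change_ddct(delta_ct: float) -> float:
    """qPCR fold change, 2 ** (-delta_ct)."""
    return 2.0 ** (-delta_ct)
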