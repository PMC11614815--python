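"""Readers and writers for the plain-text formats the pipeline touches.

Formats
-------
* FASTA — genome and TE consensus sequences (via Bio.SeqIO).
* Alignment table — a BED6+2 dialect with columns
  ``scaffold, start, end, read_id, mapping_count, strand, sequence``
  (tab-separated, 0-based half-open).  One row per genomic mapping.
* BED6 — feature annotations and called clusters.  For annotations the
  name column encodes ``feature_class|family|name`` with an ``|HTT``
  suffix for horizontally transferred transposon copies; for clusters the
  score column carries RPM rounded to three decimals.
* TSV — expression matrices (features in rows, samples in columns) with a
  ``#unit=`` header comment line.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .model import (
    AlignedRead,
    ExpressionMatrix,
    FeatureAnnotation,
    GenomicInterval,
    PiRNACluster,
    SignatureResult,
)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse a FASTA file into ``{id: uppercase sequence}``.

    Record ids are the first whitespace token of the header.  Duplicate
    ids, empty files, or text before the first header are parse errors.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}: line {lineno}: expected FASTA header")
            break
        else:
            raise ValueError(f"{path}: empty FASTA file")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"{path}: record with empty header")
        if rec.id in records:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: empty FASTA file")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as out:
        for name, seq in sequences.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_alignment_table(path: str | Path) -> list[AlignedRead]:
    """Read aligned small-RNA reads from the BED6+2 alignment dialect.

    Raises a row-level ``ValueError`` naming the offending line for empty
    intervals, mapping_count < 1 or strands outside {+, -}.
    """
    path = Path(path)
    reads: list[AlignedRead] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(
                    f"{path}: line {lineno}: expected 7 tab-separated fields, "
                    f"got {len(fields)}"
                )
            scaffold, start_s, end_s, read_id, count_s, strand, seq = fields
            try:
                start, end, count = int(start_s), int(end_s), int(count_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: empty interval [{start}, {end})"
                )
            if count < 1:
                raise ValueError(
                    f"{path}: line {lineno}: mapping_count {count} < 1"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: invalid strand {strand!r}")
            try:
                reads.append(
                    AlignedRead(
                        read_id=read_id,
                        sequence=seq.upper(),
                        interval=GenomicInterval(scaffold, start, end, strand),
                        mapping_count=count,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return reads


def write_alignment_table(reads: Iterable[AlignedRead], path: str | Path) -> None:
    with open(path, "w") as out:
        for r in reads:
            iv = r.interval
            out.write(
                f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{r.read_id}\t"
                f"{r.mapping_count}\t{iv.strand}\t{r.sequence}\n"
            )


def _annotation_name(feat: FeatureAnnotation) -> str:
    name = f"{feat.feature_class}|{feat.family}|{feat.name}"
    if feat.is_htt:
        name += "|HTT"
    return name


def write_bed(
    items: Sequence[FeatureAnnotation] | Sequence[PiRNACluster],
    path: str | Path,
) -> None:
    """Write annotations or called clusters as BED6.

    Cluster lines carry RPM (3 decimals) in the score column and an
    unstranded '.' strand; annotation lines carry ``consensus_start`` in
    the score column so TE copies round-trip through ``read_annotation_bed``.
    """
    with open(path, "w") as out:
        for item in items:
            if isinstance(item, PiRNACluster):
                iv = item.interval
                out.write(
                    f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{item.cluster_id}\t"
                    f"{item.rpm:.3f}\t.\n"
                )
            elif isinstance(item, FeatureAnnotation):
                iv = item.interval
                out.write(
                    f"{iv.scaffold}\t{iv.start}\t{iv.end}\t"
                    f"{_annotation_name(item)}\t{item.consensus_start}\t{iv.strand}\n"
                )
            else:
                raise TypeError(f"cannot write {type(item).__name__} as BED")


def read_annotation_bed(path: str | Path) -> list[FeatureAnnotation]:
    feats: list[FeatureAnnotation] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected BED6")
            scaffold, start, end, name, score, strand = fields[:6]
            parts = name.split("|")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: annotation name must encode "
                    "'feature_class|family|name'"
                )
            feats.append(
                FeatureAnnotation(
                    interval=GenomicInterval(scaffold, int(start), int(end), strand),
                    feature_class=parts[0],
                    family=parts[1],
                    name=parts[2],
                    is_htt=len(parts) > 3 and parts[3] == "HTT",
                    consensus_start=int(score),
                )
            )
    return feats


def read_cluster_bed(path: str | Path) -> list[PiRNACluster]:
    """Read cluster BED6; descriptors absent from BED default to neutral."""
    clusters: list[PiRNACluster] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            scaffold, start, end, name, score, _strand = line.split("\t")[:6]
            clusters.append(
                PiRNACluster(
                    cluster_id=name,
                    interval=GenomicInterval(scaffold, int(start), int(end)),
                    read_count=0.0,
                    rpm=float(score),
                    fraction_plus=0.5,
                    strandness="unbiased",
                )
            )
    return clusters


def write_cluster_table(clusters: Sequence[PiRNACluster], path: str | Path) -> None:
    """TSV sidecar with the full cluster descriptors."""
    rows = [
        {
            "cluster_id": c.cluster_id,
            "scaffold": c.interval.scaffold,
            "start": c.interval.start,
            "end": c.interval.end,
            "read_count": c.read_count,
            "rpm": c.rpm,
            "fraction_plus": c.fraction_plus,
            "strandness": c.strandness,
        }
        for c in clusters
    ]
    pd.DataFrame(
        rows,
        columns=[
            "cluster_id",
            "scaffold",
            "start",
            "end",
            "read_count",
            "rpm",
            "fraction_plus",
            "strandness",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_matrix_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write(f"#unit={matrix.unit}\n")
        matrix.values.to_csv(out, sep="\t", index_label="feature")


def read_matrix_tsv(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    with open(path) as handle:
        header = handle.readline().strip()
        if not header.startswith("#unit="):
            raise ValueError(f"{path}: missing '#unit=' header line")
        unit = header.split("=", 1)[1]
        df = pd.read_csv(handle, sep="\t", index_col="feature")
    return ExpressionMatrix(df, unit)


def write_signature_tsv(sig: SignatureResult, path: str | Path) -> None:
    sig.to_frame().to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as out:
        json.dump(obj, out, indent=2, sort_keys=True)
        out.write("\n")
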