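"""Core data model shared by every stage of the small-RNA pipeline.

Conventions
-----------
All genomic coordinates are 0-based half-open ``[start, end)``, the BED
convention, and BED is the only interchange dialect the package speaks.
Read sequences are stored as aligned-strand cDNA, so the 5' end of a
plus-strand read is ``interval.start`` and the 5' end of a minus-strand
read is ``interval.end - 1``.  Every downstream statistic — ping-pong
5'-5' overlaps, phasing 3'->5' gaps, window membership in the cluster
caller — leans on this single convention.

A read aligned to ``k`` genomic loci appears as ``k`` records sharing one
``read_id`` with ``mapping_count = k``; each record carries the fractional
weight ``1/k`` so that apportioned tallies conserve the number of distinct
sequenced reads.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

PLUS = "+"
MINUS = "-"
UNSTRANDED = "."
STRANDS = (PLUS, MINUS, UNSTRANDED)

#: upstream aligner cap on mappings per read
MAX_MAPPINGS = 50
#: sanity bounds for small-RNA read lengths (nt)
MIN_READ_LENGTH = 15
MAX_READ_LENGTH = 35

FEATURE_CLASSES = (
    "TE",
    "miRNA",
    "rRNA",
    "snRNA",
    "tRNA",
    "simple_repeat",
    "low_complexity",
    "gene",
    "cluster",
)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def opposite(strand: str) -> str:
    if strand == PLUS:
        return MINUS
    if strand == MINUS:
        return PLUS
    raise ValueError(f"strand {strand!r} has no opposite")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open, optionally stranded genomic interval."""

    scaffold: str
    start: int
    end: int
    strand: str = UNSTRANDED

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.end}) "
                f"on {self.scaffold}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Position of the 5' end (plus strand: start; minus: end - 1)."""
        if self.strand == PLUS:
            return self.start
        if self.strand == MINUS:
            return self.end - 1
        raise ValueError("unstranded interval has no 5' end")

    @property
    def three_prime(self) -> int:
        if self.strand == PLUS:
            return self.end - 1
        if self.strand == MINUS:
            return self.start
        raise ValueError("unstranded interval has no 3' end")

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Strand-blind overlap: >=1 shared base on the same scaffold."""
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AlignedRead:
    """One genomic mapping of a sequenced small-RNA read.

    ``sequence`` is the cDNA of the read in its own 5'->3' orientation;
    for a minus-strand mapping it equals the reverse complement of the
    genome slice under ``interval``.
    """

    read_id: str
    sequence: str
    interval: GenomicInterval
    mapping_count: int = 1

    def __post_init__(self) -> None:
        if self.interval.strand not in (PLUS, MINUS):
            raise ValueError("aligned reads must be stranded")
        if len(self.sequence) != self.interval.length:
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} "
                f"!= interval length {self.interval.length}"
            )
        n = len(self.sequence)
        if not (MIN_READ_LENGTH <= n <= MAX_READ_LENGTH):
            raise ValueError(
                f"read {self.read_id}: length {n} outside "
                f"[{MIN_READ_LENGTH}, {MAX_READ_LENGTH}]"
            )
        if not (1 <= self.mapping_count <= MAX_MAPPINGS):
            raise ValueError(
                f"read {self.read_id}: mapping_count {self.mapping_count} "
                f"outside [1, {MAX_MAPPINGS}]"
            )
        bad = set(self.sequence.upper()) - set("ACGTN")
        if bad:
            raise ValueError(f"read {self.read_id}: invalid bases {bad}")

    @property
    def weight(self) -> float:
        """Apportioned weight: one distinct read spread over its mappings."""
        return 1.0 / self.mapping_count

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def five_prime(self) -> int:
        return self.interval.five_prime

    @property
    def three_prime(self) -> int:
        return self.interval.three_prime


@dataclass
class FeatureAnnotation:
    """A strand-bearing annotated interval (TE copy, miRNA locus, ...).

    ``consensus_start`` records, for TE copies planted from a family
    consensus, which consensus position the copy's first genomic base
    corresponds to; it allows projecting genomic reads into consensus
    coordinates.
    """

    interval: GenomicInterval
    feature_class: str
    family: str = ""
    name: str = ""
    is_htt: bool = False
    consensus_start: int = 0

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.is_htt and self.feature_class != "TE":
            raise ValueError("is_htt implies feature_class == 'TE'")
        if self.feature_class == "TE" and not self.family:
            raise ValueError("TE records must carry a family")


@dataclass
class SampleLibrary:
    """A mapped small-RNA library.

    ``mapped_total`` is the number of distinct genome-mapped reads and is
    the denominator for RPM normalisation.
    """

    sample: str
    replicate: int
    reads: list[AlignedRead]
    mapped_total: int

    def __post_init__(self) -> None:
        n_ids = len({r.read_id for r in self.reads})
        if self.mapped_total < n_ids:
            raise ValueError(
                f"mapped_total {self.mapped_total} < {n_ids} distinct read ids"
            )


@dataclass
class ClusterCallParams:
    """Sliding-window cluster-caller thresholds.

    Defaults are the standard settings of this pipeline: 5 kb windows
    sliding by 1 kb, a strict density threshold of 5 uniquely-mapping
    piRNAs per kb, at least 12% of window bases covered, merged windows
    combined when separated by less than 20 kb, and a 75% strand-fraction
    rule for calling a cluster strand-biased.
    """

    window_size: int = 5_000
    step: int = 1_000
    min_density: float = 5.0
    min_cov_frac: float = 0.12
    merge_gap: int = 20_000
    strand_bias_threshold: float = 0.75
    unique_only: bool = True

    def __post_init__(self) -> None:
        if self.window_size <= 0 or self.step <= 0:
            raise ValueError("window_size and step must be positive")
        if self.step > self.window_size:
            raise ValueError("step must not exceed window_size")
        if not (0 < self.min_cov_frac <= 1):
            raise ValueError("min_cov_frac must lie in (0, 1]")
        if not (0.5 < self.strand_bias_threshold <= 1):
            raise ValueError("strand_bias_threshold must lie in (0.5, 1]")
        if self.min_density < 0 or self.merge_gap < 0:
            raise ValueError("min_density and merge_gap must be >= 0")


@dataclass
class PiRNACluster:
    """A called piRNA cluster, rank-named so cluster 1 is most productive."""

    cluster_id: str
    interval: GenomicInterval
    read_count: float
    rpm: float
    fraction_plus: float
    strandness: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_plus <= 1.0):
            raise ValueError("fraction_plus must lie in [0, 1]")
        if self.strandness not in ("plus", "minus", "unbiased"):
            raise ValueError(f"invalid strandness {self.strandness!r}")


@dataclass
class SignatureResult:
    """Offset histogram plus leave-one-out z-scores.

    For ping-pong, offsets are 5'-5' overlap lengths (1..K) and ``focal``
    is z at overlap 10; for phasing, offsets are 3'->5' distances (0..D)
    and ``focal`` is Z0 = z at distance 0.  ``degenerate`` flags a
    zero-variance background where z-scores are reported as 0.
    """

    offsets: np.ndarray
    counts: np.ndarray
    zscores: np.ndarray
    focal: float
    focal_offset: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (len(self.offsets) == len(self.counts) == len(self.zscores)):
            raise ValueError("offsets, counts and zscores must align")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"offset": self.offsets, "count": self.counts, "zscore": self.zscores}
        )

    def argmax_offset(self) -> int:
        """Offset with the highest z-score (ties: smallest offset)."""
        return int(self.offsets[int(np.argmax(self.zscores))])


@dataclass
class BaseFrequencyMatrix:
    """Per-position base frequencies over {A, C, G, U} for a read set.

    Row ``p`` (1-based position) is computed over the reads of length
    >= p; rows with no contributing read are all-zero.
    """

    freqs: pd.DataFrame
    n_reads: int

    def __post_init__(self) -> None:
        if list(self.freqs.columns) != ["A", "C", "G", "U"]:
            raise ValueError("columns must be A, C, G, U")
        if self.n_reads > 0:
            sums = self.freqs.sum(axis=1).to_numpy()
            ok = np.isclose(sums, 1.0, atol=1e-9) | np.isclose(sums, 0.0)
            if not ok.all():
                raise ValueError("each populated position must sum to 1")


EXPRESSION_UNITS = ("count", "RPM", "RPKM", "log10RPM1")


@dataclass
class ExpressionMatrix:
    """Features x samples matrix with an explicit unit tag."""

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in EXPRESSION_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.unit in ("count", "RPM", "RPKM") and (
            self.values.to_numpy(dtype=float) < 0
        ).any():
            raise ValueError(f"{self.unit} values must be non-negative")

    def to_log10_rpm1(self) -> "ExpressionMatrix":
        """log10(RPM + 1) transform; requires RPM input."""
        if self.unit != "RPM":
            raise ValueError("log10RPM1 transform requires an RPM matrix")
        return ExpressionMatrix(np.log10(self.values + 1.0), "log10RPM1")


class FeatureIndex:
    """Interval index over annotations for fast strand-blind overlap lookup.

    If ``scaffolds`` is given it declares the annotated universe and
    queries for other scaffolds raise; otherwise unknown scaffolds simply
    yield no overlaps.
    """

    def __init__(
        self,
        features: Iterable[FeatureAnnotation],
        scaffolds: Sequence[str] | None = None,
    ) -> None:
        self.features = list(features)
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for feat in self.features:
            iv = feat.interval
            self._trees[iv.scaffold].addi(iv.start, iv.end, feat)
        self.declared_scaffolds = set(scaffolds) if scaffolds is not None else None

    def overlapping(
        self,
        interval: GenomicInterval,
        feature_class: str | None = None,
        same_strand: bool | None = None,
    ) -> list[FeatureAnnotation]:
        """Features sharing >=1 base with ``interval``.

        ``same_strand=True`` keeps only features on the interval's strand,
        ``False`` only the opposite strand, ``None`` is strand-blind.
        """
        if (
            self.declared_scaffolds is not None
            and interval.scaffold not in self.declared_scaffolds
        ):
            raise KeyError(f"scaffold {interval.scaffold!r} not in annotation index")
        hits = [
            h.data for h in self._trees[interval.scaffold].overlap(interval.start, interval.end)
        ]
        if feature_class is not None:
            hits = [f for f in hits if f.feature_class == feature_class]
        if same_strand is not None:
            hits = [
                f
                for f in hits
                if (f.interval.strand == interval.strand) == same_strand
            ]
        # deterministic order regardless of tree internals
        hits.sort(key=lambda f: (f.interval.start, f.interval.end, f.name))
        return hits


def distinct_read_count(reads: Iterable[AlignedRead]) -> int:
    return len({r.read_id for r in reads})


def total_weight(reads: Iterable[AlignedRead]) -> float:
    return float(sum(r.weight for r in reads))
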