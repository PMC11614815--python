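"""Synthetic genome, annotation and small-RNA library generator.

The generator produces a toy genome with planted TE copies and piRNA
clusters, then samples a read library carrying the statistical structure
the analysis stages assume:

* a bimodal read-length distribution (~22 nt siRNA-like and ~28 nt
  piRNA-like modes);
* a configurable fraction of 28-nt-mode reads emitted as sense/antisense
  ping-pong pairs with an exact 5'-5' overlap (10 nt by default);
* phased head-to-tail read trails (3'->5' gap 0);
* 1U and 10A base biases written into the genome so that bias can be
  measured from read sequences or genome slices interchangeably;
* uni-strand clusters with a configurable per-locus strand purity and
  TE fragments interspersed on both strands;
* low-copy HTT (horizontally transferred transposon) insertions placed
  exactly where the configuration lists them;
* multi-mapping reads realised by replicating a read at other copies of
  its TE family (same consensus offset), mirroring how multimappers
  arise from dispersed TE copies.

Identical configuration + seed yields bit-identical output.  Every
simulated read appears exactly once in the truth manifest, which also
records the realized (measured) bias fractions.

For exact 10-nt ping-pong pairs, the antisense mate's first base and the
sense mate's tenth base occupy the same genomic position — the 1U/10A
coupling inherent to the ping-pong register.  The sense-side 10A is
written first and the antisense-side 1U last, so the primary antisense
bias wins at that shared base; recover the two biases independently
with ``pingpong_fraction = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    AlignedRead,
    FeatureAnnotation,
    GenomicInterval,
    SampleLibrary,
    opposite,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {65: 84, 67: 71, 71: 67, 84: 65}  # A<->T, C<->G (byte codes)

#: consensus lengths for the four HTT families when not configured
HTT_DEFAULT_LENGTHS = {"SPIN": 700, "hAT": 650, "OC1": 600, "ET": 550}

MIN_SIM_READ_LEN = 16
MAX_SIM_READ_LEN = 34


class SimulationError(ValueError):
    pass


@dataclass
class PlantedCluster:
    """A uni-strand piRNA cluster to plant, with its TE fragment mix.

    ``te_mix`` maps TE family -> fraction of that family's fragments
    inserted in plus orientation; ``strand_fraction`` is the fraction of
    the cluster's reads transcribed from the cluster strand (strand
    purity); ``weight`` sets the cluster's share of the simulated reads.
    """

    scaffold: str
    start: int
    end: int
    strand: str = "+"
    te_mix: dict[str, float] = field(default_factory=lambda: {"Mariner": 0.5})
    strand_fraction: float = 0.9
    weight: float = 1.0


@dataclass
class DecoyRegion:
    """A region seeded with sub-threshold read density (reads per kb)."""

    scaffold: str
    start: int
    end: int
    density: float = 2.0


@dataclass
class LengthMixture:
    """Two-mode Gaussian read-length mixture, discretised to integers."""

    means: tuple[float, float] = (22.0, 28.0)
    weights: tuple[float, float] = (0.3, 0.7)
    sd: float = 1.0


@dataclass
class HTTInsertion:
    family: str
    scaffold: str
    start: int
    strand: str = "+"


@dataclass
class SimulationConfig:
    """Full description of one simulated sample.

    Defaults describe an embryo-like library: the 28-nt piRNA mode
    dominates (70%), roughly 30% of piRNA-mode reads engage in ping-pong
    pairs with an exact 10-nt register, a strong 1U bias (0.8) and a
    moderate 10A bias (0.6), antisense reads predominating over dispersed
    TE copies (0.6), and a modest multimapper fraction (0.1) under the
    50-mapping cap.
    """

    seed: int = 0
    genome: list[tuple[str, int]] = field(
        default_factory=lambda: [("scaffold_1", 300_000)]
    )
    clusters: list[PlantedCluster] = field(
        default_factory=lambda: [
            PlantedCluster(
                "scaffold_1", 50_000, 80_000, "+",
                te_mix={"Mariner": 0.5, "Ty3": 0.5},
            ),
            PlantedCluster(
                "scaffold_1", 150_000, 170_000, "-",
                te_mix={"Jockey": 0.5, "RTE-X": 0.5},
            ),
        ]
    )
    decoy_regions: list[DecoyRegion] = field(default_factory=list)
    n_reads: int = 10_000
    length_modes: LengthMixture = field(default_factory=LengthMixture)
    pingpong_fraction: float = 0.3
    pingpong_overlap: int = 10
    phasing_fraction: float = 0.2
    u1_bias: float = 0.8
    a10_bias: float = 0.6
    antisense_fraction: float = 0.6
    multimap_fraction: float = 0.1
    max_multimap: int = 5
    dispersed_fraction: float = 0.15
    htt_insertions: list[HTTInsertion] = field(default_factory=list)
    te_families: dict[str, int] = field(
        default_factory=lambda: {
            "Mariner": 1300,
            "Ty3": 900,
            "Jockey": 1100,
            "RTE-X": 800,
            "Helitron": 1000,
        }
    )
    dispersed_copies_per_family: int = 3
    fragments_per_kb: float = 0.4
    n_mirna: int = 4
    n_rrna: int = 2
    sample: str = "Emb"
    replicate: int = 1

    def __post_init__(self) -> None:
        for name in (
            "pingpong_fraction",
            "phasing_fraction",
            "u1_bias",
            "a10_bias",
            "antisense_fraction",
            "multimap_fraction",
            "dispersed_fraction",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise SimulationError(f"{name} must lie in [0, 1], got {value}")
        if self.pingpong_overlap < 1:
            raise SimulationError("pingpong_overlap must be >= 1")
        if abs(sum(self.length_modes.weights) - 1.0) > 1e-9:
            raise SimulationError("length mode weights must sum to 1")

    # -- config (de)serialisation -----------------------------------------

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        data = dict(data)
        if "genome" in data:
            data["genome"] = [tuple(g) for g in data["genome"]]
        if "clusters" in data:
            data["clusters"] = [
                c if isinstance(c, PlantedCluster) else PlantedCluster(**c)
                for c in data["clusters"]
            ]
        if "decoy_regions" in data:
            data["decoy_regions"] = [
                d if isinstance(d, DecoyRegion) else DecoyRegion(**d)
                for d in data["decoy_regions"]
            ]
        if "length_modes" in data and not isinstance(data["length_modes"], LengthMixture):
            lm = dict(data["length_modes"])
            lm["means"] = tuple(lm.get("means", (22.0, 28.0)))
            lm["weights"] = tuple(lm.get("weights", (0.3, 0.7)))
            data["length_modes"] = LengthMixture(**lm)
        if "htt_insertions" in data:
            data["htt_insertions"] = [
                h if isinstance(h, HTTInsertion) else HTTInsertion(**h)
                for h in data["htt_insertions"]
            ]
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as out:
            yaml.safe_dump(asdict(self), out, sort_keys=False)


@dataclass
class TruthManifest:
    """Ground truth for parameter-recovery tests.

    ``reads`` holds one row per distinct read id (origin, family, primary
    mapping, mode, antisense flag, pair/trail labels, mapping count);
    ``clusters`` are the planted cluster specs; ``stats`` the realized
    (measured) bias and pairing fractions.
    """

    reads: pd.DataFrame
    clusters: list[PlantedCluster]
    stats: dict[str, float]

    def to_tsv(self, path: str | Path) -> None:
        self.reads.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome simulation


def _random_seq_array(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _revcomp_bytes(arr: np.ndarray) -> np.ndarray:
    return np.array([_COMP.get(b, 78) for b in arr[::-1]], dtype=np.uint8)


def _consensus_sequences(
    config: SimulationConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    families = dict(config.te_families)
    for ins in config.htt_insertions:
        families.setdefault(ins.family, HTT_DEFAULT_LENGTHS.get(ins.family, 600))
    return {
        fam: _random_seq_array(rng, length)
        for fam, length in sorted(families.items())
    }


def simulate_genome(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[FeatureAnnotation]]:
    """Build the toy genome and its feature annotations.

    TE fragments are planted inside each configured cluster with the
    configured per-family orientation mix; full-length dispersed copies
    go outside the clusters; HTT insertions land exactly where listed.
    Deterministic under the configuration seed.
    """
    rng = np.random.default_rng(config.seed)
    sizes = dict(config.genome)
    for cluster in config.clusters:
        if cluster.scaffold not in sizes:
            raise SimulationError(f"cluster on unknown scaffold {cluster.scaffold!r}")
        if not (0 <= cluster.start < cluster.end <= sizes[cluster.scaffold]):
            raise SimulationError(
                f"cluster [{cluster.start}, {cluster.end}) outside "
                f"{cluster.scaffold}"
            )
    by_scaffold: dict[str, list[PlantedCluster]] = {}
    for cluster in config.clusters:
        for other in by_scaffold.get(cluster.scaffold, []):
            if cluster.start < other.end and other.start < cluster.end:
                raise SimulationError("planted clusters overlap")
        by_scaffold.setdefault(cluster.scaffold, []).append(cluster)

    consensi = _consensus_sequences(config, rng)
    genome = {name: _random_seq_array(rng, size) for name, size in config.genome}
    annotations: list[FeatureAnnotation] = []

    def write_copy(
        scaffold: str,
        pos: int,
        family: str,
        cons_start: int,
        length: int,
        strand: str,
        name: str,
        is_htt: bool = False,
    ) -> None:
        slice_ = consensi[family][cons_start : cons_start + length]
        if strand == "-":
            slice_ = _revcomp_bytes(slice_)
        genome[scaffold][pos : pos + length] = slice_
        annotations.append(
            FeatureAnnotation(
                interval=GenomicInterval(scaffold, pos, pos + length, strand),
                feature_class="TE",
                family=family,
                name=name,
                is_htt=is_htt,
                consensus_start=cons_start,
            )
        )

    # TE fragments inside clusters, orientations per te_mix
    for ci, cluster in enumerate(config.clusters):
        span = cluster.end - cluster.start
        n_frag = max(1, round(span / 1000 * config.fragments_per_kb))
        families = sorted(cluster.te_mix)
        for fi in range(n_frag):
            family = families[int(rng.integers(0, len(families)))]
            cons_len = len(consensi[family])
            frag_len = int(rng.integers(150, min(800, cons_len) + 1))
            frag_len = min(frag_len, span)
            cons_start = int(rng.integers(0, cons_len - frag_len + 1))
            pos = int(rng.integers(cluster.start, cluster.end - frag_len + 1))
            strand = "+" if rng.random() < cluster.te_mix[family] else "-"
            write_copy(
                cluster.scaffold, pos, family, cons_start, frag_len, strand,
                name=f"{family}.c{ci}.{fi}",
            )

    occupied: dict[str, list[tuple[int, int]]] = {}

    def outside_clusters(scaffold: str, start: int, end: int) -> bool:
        """Free of planted clusters and previously placed dispersed features."""
        if any(
            start < c.end and c.start < end
            for c in by_scaffold.get(scaffold, [])
        ):
            return False
        return not any(
            start < e and s < end for s, e in occupied.get(scaffold, [])
        )

    # dispersed full-length copies outside clusters, non-overlapping
    scaffold_names = [name for name, _ in config.genome]
    scaffold_probs = np.array([size for _, size in config.genome], dtype=float)
    scaffold_probs /= scaffold_probs.sum()
    for family in sorted(config.te_families):
        cons_len = len(consensi[family])
        for j in range(config.dispersed_copies_per_family):
            for _attempt in range(200):
                scaffold = scaffold_names[
                    int(rng.choice(len(scaffold_names), p=scaffold_probs))
                ]
                size = sizes[scaffold]
                if size <= cons_len:
                    continue
                pos = int(rng.integers(0, size - cons_len + 1))
                if outside_clusters(scaffold, pos, pos + cons_len):
                    break
            else:
                raise SimulationError(
                    f"could not place dispersed {family} copy outside clusters"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            write_copy(scaffold, pos, family, 0, cons_len, strand,
                       name=f"{family}.d{j}")
            occupied.setdefault(scaffold, []).append((pos, pos + cons_len))

    # HTT insertions, exactly as listed
    for hi, ins in enumerate(config.htt_insertions):
        cons_len = len(consensi[ins.family])
        if ins.scaffold not in sizes or ins.start + cons_len > sizes[ins.scaffold]:
            raise SimulationError(f"HTT insertion {hi} does not fit the genome")
        write_copy(
            ins.scaffold, ins.start, ins.family, 0, cons_len, ins.strand,
            name=f"{ins.family}.htt{hi}", is_htt=True,
        )

    # contamination features (annotation-only; no sequence planting needed)
    for cls, count, length in (
        ("miRNA", config.n_mirna, 80),
        ("rRNA", config.n_rrna, 120),
    ):
        for j in range(count):
            for _attempt in range(200):
                scaffold = scaffold_names[
                    int(rng.choice(len(scaffold_names), p=scaffold_probs))
                ]
                size = sizes[scaffold]
                if size <= length:
                    continue
                pos = int(rng.integers(0, size - length + 1))
                if outside_clusters(scaffold, pos, pos + length):
                    break
            else:
                raise SimulationError(f"could not place {cls} feature")
            strand = "+" if rng.random() < 0.5 else "-"
            annotations.append(
                FeatureAnnotation(
                    interval=GenomicInterval(scaffold, pos, pos + length, strand),
                    feature_class=cls,
                    name=f"{cls}{j}",
                )
            )
            occupied.setdefault(scaffold, []).append((pos, pos + length))

    return (
        {name: arr.tobytes().decode("ascii") for name, arr in genome.items()},
        annotations,
    )


# ---------------------------------------------------------------------------
# library simulation


@dataclass
class _ReadRecord:
    scaffold: str
    start: int
    length: int
    strand: str
    origin: str
    family: str = ""
    is_antisense: bool = False
    pair_id: str = ""
    trail_id: str = ""
    mode: int = 1
    mapping_count: int = 1
    source_copy: FeatureAnnotation | None = None

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def _draw_length(config: SimulationConfig, rng: np.random.Generator) -> tuple[int, int]:
    lm = config.length_modes
    mode = int(rng.random() >= lm.weights[0])
    length = int(round(rng.normal(lm.means[mode], lm.sd)))
    return max(MIN_SIM_READ_LEN, min(MAX_SIM_READ_LEN, length)), mode


def _allocate(total: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder allocation of ``total`` among weights."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() == 0:
        return [0] * len(weights)
    quota = total * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: total - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def simulate_library(
    config: SimulationConfig,
    genome: dict[str, str],
    annotations: Sequence[FeatureAnnotation],
    seed: int | None = None,
    sample: str | None = None,
    replicate: int | None = None,
) -> tuple[SampleLibrary, TruthManifest]:
    """Sample a read library from a simulated genome.

    ``seed`` overrides the configuration seed so replicate libraries can
    be drawn from one genome.  Read sequences equal the (final) genome
    slice under each mapping, reverse-complemented for minus-strand
    mappings.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    garr = {name: bytearray(seq, "ascii") for name, seq in genome.items()}
    sizes = {name: len(seq) for name, seq in genome.items()}

    te_copies = [a for a in annotations if a.feature_class == "TE"]
    cluster_list = list(config.clusters)

    def in_any_cluster(scaffold: str, start: int, end: int) -> bool:
        return any(
            c.scaffold == scaffold and start < c.end and c.start < end
            for c in cluster_list
        )

    dispersed_copies = [
        c
        for c in te_copies
        if not in_any_cluster(c.interval.scaffold, c.interval.start, c.interval.end)
    ]
    copies_by_family: dict[str, list[FeatureAnnotation]] = {}
    for c in te_copies:
        copies_by_family.setdefault(c.family, []).append(c)

    # ---- read budget ----------------------------------------------------
    n_decoy = [
        int(round(d.density * (d.end - d.start) / 1000.0))
        for d in config.decoy_regions
    ]
    n_rest = config.n_reads - sum(n_decoy)
    if n_rest < 0:
        raise SimulationError("decoy regions demand more reads than n_reads")
    if cluster_list:
        n_disp = int(round(config.dispersed_fraction * n_rest)) if dispersed_copies else 0
        n_cluster = _allocate(n_rest - n_disp, [c.weight for c in cluster_list])
    else:
        n_disp = n_rest if dispersed_copies else 0
        n_cluster = []
    n_background = n_rest - n_disp - sum(n_cluster)

    records: list[_ReadRecord] = []

    # cluster reads
    for ci, (cluster, m) in enumerate(zip(cluster_list, n_cluster)):
        for _ in range(m):
            length, mode = _draw_length(config, rng)
            span = cluster.end - cluster.start
            if span < length:
                raise SimulationError("cluster shorter than a read")
            start = int(rng.integers(cluster.start, cluster.end - length + 1))
            on_cluster_strand = rng.random() < cluster.strand_fraction
            strand = cluster.strand if on_cluster_strand else opposite(cluster.strand)
            records.append(
                _ReadRecord(
                    scaffold=cluster.scaffold,
                    start=start,
                    length=length,
                    strand=strand,
                    origin=f"cluster_{ci}",
                    is_antisense=not on_cluster_strand,
                    mode=mode,
                )
            )

    # dispersed TE reads
    for _ in range(n_disp):
        copy = dispersed_copies[int(rng.integers(0, len(dispersed_copies)))]
        civ = copy.interval
        length, mode = _draw_length(config, rng)
        length = min(length, civ.length)
        start = int(rng.integers(civ.start, civ.end - length + 1))
        anti = rng.random() < config.antisense_fraction
        strand = opposite(civ.strand) if anti else civ.strand
        records.append(
            _ReadRecord(
                scaffold=civ.scaffold,
                start=start,
                length=length,
                strand=strand,
                origin="dispersed",
                family=copy.family,
                is_antisense=anti,
                mode=mode,
                source_copy=copy,
            )
        )

    # decoy reads (sub-threshold density regions)
    for di, (decoy, m) in enumerate(zip(config.decoy_regions, n_decoy)):
        for _ in range(m):
            length, mode = _draw_length(config, rng)
            start = int(rng.integers(decoy.start, decoy.end - length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append(
                _ReadRecord(
                    scaffold=decoy.scaffold,
                    start=start,
                    length=length,
                    strand=strand,
                    origin=f"decoy_{di}",
                    is_antisense=strand == "-",
                    mode=mode,
                )
            )

    # background reads (only when there is nothing else to sample from)
    for _ in range(n_background):
        scaffold = max(sizes, key=lambda s: sizes[s])
        length, mode = _draw_length(config, rng)
        start = int(rng.integers(0, sizes[scaffold] - length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            _ReadRecord(
                scaffold=scaffold,
                start=start,
                length=length,
                strand=strand,
                origin="background",
                is_antisense=strand == "-",
                mode=mode,
            )
        )

    # ---- ping-pong pairs -------------------------------------------------
    overlap = config.pingpong_overlap
    eligible = [
        i
        for i, r in enumerate(records)
        if r.mode == 1 and not r.origin.startswith("decoy")
        and r.length >= overlap
    ]
    n_pair_reads = int(round(config.pingpong_fraction * len(eligible)))
    n_pairs = n_pair_reads // 2
    if n_pairs:
        chosen = rng.choice(len(eligible), size=2 * n_pairs, replace=False)
        anchors = [eligible[i] for i in chosen[:n_pairs]]
        mates = [eligible[i] for i in chosen[n_pairs:]]
        for pi, (ai, mi) in enumerate(zip(anchors, mates)):
            anchor, mate = records[ai], records[mi]
            size = sizes[anchor.scaffold]
            # clamp the anchor so its mate fits on the scaffold
            if anchor.strand == "+":
                mate5 = anchor.five_prime + overlap - 1
                mate_start = mate5 - mate.length + 1
                if mate_start < 0:
                    anchor.start += -mate_start
                    mate_start = 0
                if anchor.end > size:
                    shift = anchor.end - size
                    anchor.start -= shift
                    mate_start -= shift
                mate.strand = "-"
            else:
                mate5 = anchor.five_prime - overlap + 1
                mate_start = mate5
                if mate_start + mate.length > size:
                    shift = mate_start + mate.length - size
                    anchor.start -= shift
                    mate_start -= shift
                if anchor.start < 0:
                    shift = -anchor.start
                    anchor.start += shift
                    mate_start += shift
                mate.strand = "+"
            mate.scaffold = anchor.scaffold
            mate.start = mate_start
            mate.origin = anchor.origin
            mate.family = anchor.family
            mate.source_copy = None  # repositioned; no longer tied to a copy
            anchor.source_copy = None
            anchor.is_antisense = False  # the sense mate of the pair
            mate.is_antisense = True
            anchor.pair_id = mate.pair_id = f"pp{pi}"

    # ---- phased trails ---------------------------------------------------
    trail_candidates = [
        i
        for i, r in enumerate(records)
        if not r.pair_id and not r.origin.startswith("decoy")
        and r.origin != "background"
    ]
    n_phase = int(round(config.phasing_fraction * len(trail_candidates)))
    if n_phase >= 2 and cluster_list:
        chosen = list(rng.choice(len(trail_candidates), size=n_phase, replace=False))
        ti = 0
        pos = 0
        while pos < len(chosen):
            t_size = int(rng.integers(3, 7))
            group = [trail_candidates[i] for i in chosen[pos : pos + t_size]]
            pos += t_size
            if len(group) < 2:
                break
            cluster = cluster_list[int(rng.integers(0, len(cluster_list)))]
            total = sum(records[i].length for i in group)
            span = cluster.end - cluster.start
            if span < total:
                raise SimulationError(
                    "cluster too small for requested trail length"
                )
            start0 = int(rng.integers(cluster.start, cluster.end - total + 1))
            offset = 0
            order = group if cluster.strand == "+" else group
            for gi in order:
                rec = records[gi]
                if cluster.strand == "+":
                    rec.start = start0 + offset
                else:
                    rec.start = start0 + total - offset - rec.length
                offset += rec.length
                rec.scaffold = cluster.scaffold
                rec.strand = cluster.strand
                rec.origin = f"cluster_{cluster_list.index(cluster)}"
                rec.is_antisense = False
                rec.trail_id = f"ph{ti}"
                rec.source_copy = None
            ti += 1

    # ---- multimapping ----------------------------------------------------
    def consensus_offset(rec: _ReadRecord, copy: FeatureAnnotation) -> int:
        civ = copy.interval
        if civ.strand == "+":
            return copy.consensus_start + (rec.start - civ.start)
        return copy.consensus_start + (civ.end - rec.end)

    mm_candidates = [
        i
        for i, r in enumerate(records)
        if r.source_copy is not None and not r.pair_id and not r.trail_id
    ]
    n_mm = min(
        int(round(config.multimap_fraction * config.n_reads)), len(mm_candidates)
    )
    duplicates: list[tuple[int, _ReadRecord]] = []  # (primary index, dup record)
    if n_mm:
        for i in rng.choice(mm_candidates, size=n_mm, replace=False):
            rec = records[int(i)]
            src = rec.source_copy
            coff = consensus_offset(rec, src)
            targets = [
                c
                for c in copies_by_family.get(rec.family, [])
                if c is not src
                and c.consensus_start <= coff
                and coff + rec.length <= c.consensus_start + c.interval.length
            ]
            if not targets:
                continue
            k_req = int(rng.integers(2, config.max_multimap + 1))
            k = min(k_req, 1 + len(targets))
            picked = rng.choice(len(targets), size=k - 1, replace=False)
            rec.mapping_count = k
            for t_idx in picked:
                t = targets[int(t_idx)]
                tiv = t.interval
                rel_same = rec.strand == src.interval.strand
                if tiv.strand == "+":
                    gstart = tiv.start + (coff - t.consensus_start)
                else:
                    gstart = tiv.start + (
                        t.consensus_start + tiv.length - coff - rec.length
                    )
                dup = _ReadRecord(
                    scaffold=tiv.scaffold,
                    start=gstart,
                    length=rec.length,
                    strand=tiv.strand if rel_same else opposite(tiv.strand),
                    origin=rec.origin,
                    family=rec.family,
                    is_antisense=rec.is_antisense,
                    mode=rec.mode,
                    mapping_count=k,
                )
                duplicates.append((int(i), dup))

    # ---- base biases written into the genome ----------------------------
    def write_base(scaffold: str, pos: int, strand: str, base: str) -> None:
        code = ord(base)
        garr[scaffold][pos] = code if strand == "+" else _COMP[code]

    def draw_base(rng_, favored: str, p: float) -> str:
        if rng_.random() < p:
            return favored
        others = [b for b in "ACGT" if b != favored]
        return others[int(rng_.integers(0, 3))]

    # sense-class 10A first, antisense 1U last (primary bias wins)
    for rec in records:
        if not rec.is_antisense and rec.length >= 10:
            base = draw_base(rng, "A", config.a10_bias)
            pos = rec.start + 9 if rec.strand == "+" else rec.end - 10
            write_base(rec.scaffold, pos, rec.strand, base)
    for rec in records:
        base = draw_base(rng, "T", config.u1_bias)  # U in read space
        write_base(rec.scaffold, rec.five_prime, rec.strand, base)

    # ---- materialise reads ----------------------------------------------
    # Duplicate mappings reuse the primary-locus sequence: same-family
    # copies share the consensus subsequence, so duplicate loci match the
    # source slice except at bias-written bases of unrelated reads, which
    # the read sequence must not inherit.
    def extract(scaffold: str, start: int, end: int, strand: str) -> str:
        seq = garr[scaffold][start:end].decode("ascii")
        return revcomp(seq) if strand == "-" else seq

    reads: list[AlignedRead] = []
    primary_seq: dict[int, str] = {}
    for idx, rec in enumerate(records):
        seq = extract(rec.scaffold, rec.start, rec.end, rec.strand)
        primary_seq[idx] = seq
        reads.append(
            AlignedRead(
                read_id=f"r{idx:06d}",
                sequence=seq,
                interval=GenomicInterval(rec.scaffold, rec.start, rec.end, rec.strand),
                mapping_count=rec.mapping_count,
            )
        )
    for pi, dup in duplicates:
        reads.append(
            AlignedRead(
                read_id=f"r{pi:06d}",
                sequence=primary_seq[pi],
                interval=GenomicInterval(dup.scaffold, dup.start, dup.end, dup.strand),
                mapping_count=dup.mapping_count,
            )
        )

    library = SampleLibrary(
        sample=sample if sample is not None else config.sample,
        replicate=replicate if replicate is not None else config.replicate,
        reads=reads,
        mapped_total=len(records),
    )

    # ---- manifest --------------------------------------------------------
    lm = config.length_modes
    rows = []
    for idx, rec in enumerate(records):
        rows.append(
            {
                "read_id": f"r{idx:06d}",
                "origin": rec.origin,
                "family": rec.family,
                "scaffold": rec.scaffold,
                "start": rec.start,
                "end": rec.end,
                "strand": rec.strand,
                "length": rec.length,
                "length_mode": int(round(lm.means[rec.mode])),
                "is_antisense": rec.is_antisense,
                "pingpong_pair_id": rec.pair_id,
                "phased_trail_id": rec.trail_id,
                "mapping_count": rec.mapping_count,
            }
        )
    reads_df = pd.DataFrame(rows)

    n28 = (reads_df["length_mode"] == int(round(lm.means[1]))).sum()
    paired28 = (
        (reads_df["pingpong_pair_id"] != "")
        & (reads_df["length_mode"] == int(round(lm.means[1])))
    ).sum()
    sense_seqs = [
        primary_seq[i]
        for i, rec in enumerate(records)
        if not rec.is_antisense and rec.length >= 10
    ]
    stats = {
        "realized_u1": float(
            np.mean([s[0] == "T" for s in primary_seq.values()])
        ),
        "realized_a10": float(np.mean([s[9] == "A" for s in sense_seqs]))
        if sense_seqs
        else float("nan"),
        "pair_fraction_mode28": float(paired28 / n28) if n28 else 0.0,
        "pair_fraction_all": float((reads_df["pingpong_pair_id"] != "").mean()),
        "antisense_fraction": float(reads_df["is_antisense"].mean()),
    }

    manifest = TruthManifest(reads=reads_df, clusters=cluster_list, stats=stats)
    return library, manifest


def simulate_sample(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[FeatureAnnotation], SampleLibrary, TruthManifest]:
    """Convenience wrapper: genome + annotations + one library."""
    genome, annotations = simulate_genome(config)
    library, manifest = simulate_library(config, genome, annotations)
    return genome, annotations, library, manifest
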