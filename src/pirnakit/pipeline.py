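"""End-to-end orchestration: simulate -> classify -> quantify -> clusters
-> signatures, with a flat config file and a reproducible run directory.

Every stage logs a read-conservation check (apportioned mass versus
distinct read count) and all outputs are plain TSV/BED/FASTA/JSON with
no timestamps, so re-running the same config + seed reproduces the run
directory byte for byte.
"""

from __future__ import annotations

import shutil
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import io as pio
from .classify import (
    ClassRanges,
    apportioned_counts,
    class_summary,
    classify_read,
    length_histogram,
)
from .clusters import call_clusters, cumulative_share
from .model import (
    ClusterCallParams,
    FeatureIndex,
    SampleLibrary,
    distinct_read_count,
    total_weight,
)
from .quantify import rpkm_matrix, sense_antisense_counts
from .signatures import (
    base_frequency_matrix,
    paired_fraction,
    phasing_signature,
    pingpong_histogram,
    split_by_te_strand,
)
from .simulate import SimulationConfig, simulate_genome, simulate_library

#: pipeline defaults, named in one place so they are discoverable and
#: overridable from the config file
DEFAULTS = {
    "pirna_range": (24, 32),
    "sirna_range": (18, 23),
    "cluster_params": ClusterCallParams(),
    "max_overlap": 30,
    "max_distance": 50,
}


class ConfigError(ValueError):
    pass


def load_config(config: str | Path | Mapping) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as handle:
            data = yaml.safe_load(handle)
    else:
        data = dict(config)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    return data


def _validate(cfg: dict) -> None:
    has_sim = "simulate" in cfg
    has_inputs = all(k in cfg for k in ("genome_fasta", "annotations", "alignments"))
    if not (has_sim or has_inputs):
        raise ConfigError(
            "config must provide either a 'simulate' block or all of "
            "'genome_fasta', 'annotations' and 'alignments'"
        )


def _cluster_params(cfg: dict) -> ClusterCallParams:
    block = cfg.get("clusters", {})
    base = DEFAULTS["cluster_params"]
    return ClusterCallParams(
        window_size=block.get("window_size", base.window_size),
        step=block.get("step", base.step),
        min_density=block.get("min_density", base.min_density),
        min_cov_frac=block.get("min_cov_frac", base.min_cov_frac),
        merge_gap=block.get("merge_gap", base.merge_gap),
        strand_bias_threshold=block.get(
            "strand_bias_threshold", base.strand_bias_threshold
        ),
        unique_only=block.get("unique_only", base.unique_only),
    )


def run_pipeline(config: str | Path | Mapping, outdir: str | Path) -> Path:
    """Run all stages and return the populated run directory.

    On stage failure a FAILED marker naming the stage is written and the
    exception re-raised; partial outputs are retained.
    """
    cfg = load_config(config)
    _validate(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    stage = "setup"

    try:
        ranges = ClassRanges(
            pirna=tuple(cfg.get("pirna_range", DEFAULTS["pirna_range"])),
            sirna=tuple(cfg.get("sirna_range", DEFAULTS["sirna_range"])),
        )
        params = _cluster_params(cfg)
        log_lines.append(f"params: pirna_range={ranges.pirna} sirna_range={ranges.sirna}")
        log_lines.append(
            "params: "
            f"window_size={params.window_size} step={params.step} "
            f"min_density={params.min_density} min_cov_frac={params.min_cov_frac} "
            f"merge_gap={params.merge_gap} "
            f"strand_bias_threshold={params.strand_bias_threshold}"
        )

        # ---- inputs -----------------------------------------------------
        stage = "simulate"
        if "simulate" in cfg:
            sim_cfg = SimulationConfig.from_dict(cfg["simulate"])
            genome, annotations = simulate_genome(sim_cfg)
            library, manifest = simulate_library(sim_cfg, genome, annotations)
            pio.write_fasta(genome, outdir / "genome.fa")
            pio.write_bed(annotations, outdir / "annotations.bed")
            pio.write_alignment_table(library.reads, outdir / "reads.bed")
            manifest.to_tsv(outdir / "truth.tsv")
            log_lines.append(
                f"simulate: n_reads={library.mapped_total} "
                f"seed={sim_cfg.seed} sample={library.sample}"
            )
        else:
            genome = pio.read_fasta(cfg["genome_fasta"])
            annotations = pio.read_annotation_bed(cfg["annotations"])
            reads = pio.read_alignment_table(cfg["alignments"])
            library = SampleLibrary(
                sample=cfg.get("sample", "sample"),
                replicate=cfg.get("replicate", 1),
                reads=reads,
                mapped_total=cfg.get("mapped_total", distinct_read_count(reads)),
            )
        scaffold_sizes = {name: len(seq) for name, seq in genome.items()}
        index = FeatureIndex(annotations)
        n_distinct = distinct_read_count(library.reads)

        # ---- classify ---------------------------------------------------
        stage = "classify"
        summary = class_summary(library.reads, index, ranges)
        pd.DataFrame(
            [
                {"label": label, **vals}
                for label, vals in summary.items()
            ]
        ).to_csv(outdir / "class_summary.tsv", sep="\t", index=False)
        by_class = apportioned_counts(library.reads, index, by="feature_class")
        mass = sum(by_class.values())
        log_lines.append(
            f"classify: apportioned_mass={mass:.9f} distinct_reads={n_distinct} "
            f"conserved={abs(mass - n_distinct) < 1e-6}"
        )
        hist_all = length_histogram(library.reads, library.mapped_total)
        hist_te = length_histogram(
            library.reads, library.mapped_total, index=index, te_only=True
        )
        pd.DataFrame(
            {
                "length": sorted(set(hist_all) | set(hist_te)),
            }
        ).assign(
            rpm_all=lambda df: [hist_all.get(l, 0.0) for l in df["length"]],
            rpm_te=lambda df: [hist_te.get(l, 0.0) for l in df["length"]],
        ).to_csv(outdir / "length_histogram.tsv", sep="\t", index=False)

        labels = {
            r.read_id: classify_read(r, index, ranges) for r in library.reads
        }
        pirna_reads = [r for r in library.reads if labels[r.read_id] == "piRNA"]
        sirna_reads = [
            r for r in library.reads if labels[r.read_id] == "siRNA_candidate"
        ]

        # ---- quantify ---------------------------------------------------
        stage = "quantify"
        te_feats = [a for a in annotations if a.feature_class == "TE"]
        sense_m, anti_m = sense_antisense_counts(
            pirna_reads,
            te_feats,
            by="family",
            unit="RPM",
            mapped_total=library.mapped_total,
            sample=library.sample,
        )
        pio.write_matrix_tsv(sense_m, outdir / "sense_rpm.tsv")
        pio.write_matrix_tsv(anti_m, outdir / "antisense_rpm.tsv")
        te_mass = float(sense_m.values.to_numpy().sum() + anti_m.values.to_numpy().sum())
        log_lines.append(f"quantify: te_assigned_rpm={te_mass:.6f}")

        te_rpkm_mean = float("nan")
        if "rnaseq" in cfg:
            rna = cfg["rnaseq"]
            lengths = rna.get("lengths")
            if lengths is None:
                lengths = {}
                for feat in te_feats:
                    lengths[feat.family] = lengths.get(feat.family, 0) + feat.interval.length
            te_rpkm = rpkm_matrix(
                {k: float(v) for k, v in rna["counts"].items()},
                lengths,
                int(rna["library_size"]),
                sample=library.sample,
            )
            pio.write_matrix_tsv(te_rpkm, outdir / "te_rpkm.tsv")
            te_rpkm_mean = float(te_rpkm.values.to_numpy().mean())

        # ---- clusters ---------------------------------------------------
        stage = "clusters"
        called = call_clusters(
            pirna_reads, scaffold_sizes, params, mapped_total=library.mapped_total
        )
        pio.write_bed(called, outdir / "clusters.bed")
        pio.write_cluster_table(called, outdir / "clusters.tsv")
        if called:
            share = cumulative_share(called)
            pd.DataFrame(
                {"rank": np.arange(1, len(share) + 1), "cumulative_fraction": share}
            ).to_csv(outdir / "cluster_cumulative.tsv", sep="\t", index=False)
        log_lines.append(f"clusters: n_called={len(called)}")

        # ---- signatures -------------------------------------------------
        stage = "signatures"
        sig_summary: dict[str, float | int | bool | None] = {}
        te_index = FeatureIndex(te_feats)
        sense_set, anti_set = split_by_te_strand(pirna_reads, te_index)
        if sense_set and anti_set:
            pp = pingpong_histogram(
                sense_set, anti_set, max_overlap=cfg.get("max_overlap", DEFAULTS["max_overlap"])
            )
            pio.write_signature_tsv(pp, outdir / "pingpong.tsv")
            sig_summary["pingpong_z10"] = pp.focal
            sig_summary["pingpong_argmax"] = pp.argmax_offset()
            sig_summary["pingpong_degenerate"] = pp.degenerate
        else:
            sig_summary["pingpong_z10"] = None
        if pirna_reads:
            ph = phasing_signature(
                pirna_reads, max_distance=cfg.get("max_distance", DEFAULTS["max_distance"])
            )
            pio.write_signature_tsv(ph, outdir / "phasing.tsv")
            sig_summary["phasing_z0"] = ph.focal
            sig_summary["phasing_argmax"] = ph.argmax_offset()
            sig_summary["paired_fraction"] = paired_fraction(pirna_reads)
        if sense_set:
            m, u1_s, a10_s = base_frequency_matrix(sense_set)
            m.freqs.to_csv(outdir / "bias_sense.tsv", sep="\t")
            sig_summary["a10_sense"] = a10_s
            sig_summary["u1_sense"] = u1_s
        if anti_set:
            m, u1_a, a10_a = base_frequency_matrix(anti_set)
            m.freqs.to_csv(outdir / "bias_antisense.tsv", sep="\t")
            sig_summary["u1_antisense"] = u1_a
        pio.write_json(sig_summary, outdir / "signature_summary.json")

        # ---- sample summary ---------------------------------------------
        stage = "summary"
        pirna_rpm = total_weight(pirna_reads) * 1e6 / library.mapped_total
        sirna_rpm = total_weight(sirna_reads) * 1e6 / library.mapped_total
        cluster_rpm = float(sum(c.rpm for c in called))
        pd.DataFrame(
            [
                {
                    "sample": library.sample,
                    "replicate": library.replicate,
                    "mapped_total": library.mapped_total,
                    "pirna_rpm": pirna_rpm,
                    "sirna_rpm": sirna_rpm,
                    "te_rpkm_mean": te_rpkm_mean,
                    "cluster_rpm": cluster_rpm,
                    "n_clusters": len(called),
                }
            ]
        ).to_csv(outdir / "sample_summary.tsv", sep="\t", index=False)
        pio.write_json({"config": _jsonable(cfg)}, outdir / "run_manifest.json")
        log_lines.append("status: OK")
    except Exception:
        (outdir / "FAILED").write_text(f"stage: {stage}\n")
        (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
        raise
    (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return outdir


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def compare_samples(
    run_dirs: Sequence[str | Path],
    out_path: str | Path | None = None,
) -> pd.DataFrame:
    """Join per-sample summaries across completed runs.

    The joined table (one row per run) carries piRNA RPM, siRNA RPM, TE
    RPKM and cluster RPM, enabling the piRNA-versus-TE anticorrelation
    readout across developmental samples.  Requires >= 2 runs.
    """
    run_dirs = [Path(d) for d in run_dirs]
    if len(run_dirs) < 2:
        raise ValueError("compare_samples needs at least two completed runs")
    frames = []
    for d in run_dirs:
        summary = d / "sample_summary.tsv"
        if not summary.exists():
            raise ValueError(f"{d} is not a completed run (no sample_summary.tsv)")
        frames.append(pd.read_csv(summary, sep="\t"))
    joined = pd.concat(frames, ignore_index=True)
    if out_path is not None:
        joined.to_csv(out_path, sep="\t", index=False)
    return joined


def pirna_te_rank_correlation(comparison: pd.DataFrame) -> float:
    """Spearman correlation between piRNA RPM and TE RPKM across samples."""
    sub = comparison.dropna(subset=["pirna_rpm", "te_rpkm_mean"])
    if len(sub) < 2:
        raise ValueError("need >= 2 samples with both piRNA RPM and TE RPKM")
    rho, _ = sps.spearmanr(sub["pirna_rpm"], sub["te_rpkm_mean"])
    return float(rho)
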