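"""End-to-end orchestration: data -> distances -> four delimiters -> congruence.

A run is driven by a single YAML config (either real inputs: aligned FASTA +
metadata TSV (+ optional ultrametric newick for GMYC), or a simulation
section) and writes every stage artifact into a run directory so the whole
analysis is regenerable from config + seed alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import abgd as abgd_mod
from . import binclust, congruence, core_io, distances, gmyc, simulate, threshold, trees
from .core_io import BarcodeAlignment, Partition, PhyloTree, ValidationError

logger = logging.getLogger("barcodelim")

NJ_CUTOFF = 0.02          # initial clustering cutoff
BIN_THRESHOLD = 0.022     # BIN-style pre-stage threshold
ABGD_DEFAULTS = abgd_mod.AbgdConfig()  # X=0.1, priors 0.005..0.1


@dataclass
class PipelineConfig:
    fasta: str | None = None
    metadata: str | None = None
    gmyc_tree: str | None = None       # optional user ultrametric newick
    sim: simulate.SimConfig | None = None
    nj_cutoff: float = NJ_CUTOFF
    bin_threshold: float = BIN_THRESHOLD
    bin_inflation: float = 2.0
    abgd: abgd_mod.AbgdConfig = field(default_factory=abgd_mod.AbgdConfig)
    abgd_report_prior: float | None = None  # default: smallest prior
    skip_bin: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_cfg = None
        if "sim" in raw:
            sim_cfg = simulate.SimConfig(**raw.pop("sim"))
        abgd_cfg = abgd_mod.AbgdConfig(**raw.pop("abgd", {}))
        return cls(sim=sim_cfg, abgd=abgd_cfg, **raw)


@dataclass
class PipelineResult:
    run_dir: Path
    alignment: BarcodeAlignment
    dm: distances.DistanceMatrix
    nj_tree: PhyloTree
    partitions: dict[str, Partition]
    gmyc_fit: gmyc.GmycFit
    report: congruence.CongruenceReport
    summary: distances.DistanceSummary
    truth: simulate.SimTruth | None = None


def run_pipeline(cfg: PipelineConfig, run_dir: str | Path) -> PipelineResult:
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    logger.info(
        "pipeline parameters: nj_cutoff=%g bin_threshold=%g bin_inflation=%g "
        "abgd X=%g p_min=%g p_max=%g seed=%d",
        cfg.nj_cutoff, cfg.bin_threshold, cfg.bin_inflation,
        cfg.abgd.relative_gap_X, cfg.abgd.p_min, cfg.abgd.p_max, cfg.seed,
    )

    # --- stage: input ------------------------------------------------------
    truth = None
    if cfg.sim is not None:
        sim_cfg = simulate.with_seed(cfg.sim, cfg.sim.seed or cfg.seed)
        aln, truth = simulate.simulate_dataset(sim_cfg)
        core_io.write_alignment(aln, run_dir / "alignment.fasta",
                                run_dir / "metadata.tsv")
        core_io.write_partition(truth.species_partition,
                                run_dir / "truth_partition.tsv")
        core_io.write_tree(truth.true_tree, run_dir / "true_tree.nwk")
    elif cfg.fasta and cfg.metadata:
        aln = core_io.read_alignment(cfg.fasta, cfg.metadata)
    else:
        raise ValidationError("config must name fasta+metadata or a sim section")
    logger.info("input: %d specimens x %d sites", len(aln), aln.length)

    # --- stage: distances --------------------------------------------------
    dm = _stage("distances", lambda: distances.pairwise_k2p(aln),
                run_dir / "k2p.tsv")
    dm.write_tsv(run_dir / "k2p.tsv")

    # --- stage: NJ tree + 2% clusters --------------------------------------
    nj_tree = _stage("nj_tree", lambda: trees.neighbor_joining(dm),
                     run_dir / "nj_tree.nwk")
    core_io.write_tree(nj_tree, run_dir / "nj_tree.nwk")
    nj_part = _stage(
        "threshold",
        lambda: threshold.threshold_clusters(dm, cfg.nj_cutoff, method="NJ2"),
        run_dir / "partition_nj2.tsv",
    )
    core_io.write_partition(nj_part, run_dir / "partition_nj2.tsv")

    # --- stage: ABGD -------------------------------------------------------
    abgd_parts = _stage("abgd", lambda: abgd_mod.abgd_partition(dm, cfg.abgd),
                        run_dir / "abgd_group_counts.tsv")
    with open(run_dir / "abgd_group_counts.tsv", "w") as fh:
        fh.write("prior_P\tn_groups\n")
        for prior, count in abgd_mod.group_counts(abgd_parts):
            fh.write(f"{prior:.6f}\t{count}\n")
    report_prior = cfg.abgd_report_prior or min(abgd_parts)
    abgd_part = abgd_parts[min(abgd_parts, key=lambda p: abs(p - report_prior))]
    core_io.write_partition(abgd_part, run_dir / "partition_abgd.tsv")

    # --- stage: GMYC (unique haplotypes, ultrametric tree) -----------------
    def fit_gmyc():
        collapsed, mapping = distances.collapse_haplotypes(aln)
        logger.info("GMYC haplotypes: %d of %d specimens unique",
                    len(collapsed), len(aln))
        if cfg.gmyc_tree:
            tree = core_io.read_tree(cfg.gmyc_tree)
            if not tree.is_ultrametric:
                raise ValidationError(f"{cfg.gmyc_tree} is not ultrametric")
            keep = set(collapsed.ids)
            if set(tree.leaf_labels) != keep:
                raise ValidationError(
                    "user tree leaves do not match unique haplotypes"
                )
        else:
            tree = trees.upgma(distances.pairwise_k2p(collapsed))
        fit = gmyc.gmyc_fit(tree)
        part = distances.expand_partition(fit.partition(), mapping)
        return fit, part

    fit, gmyc_part = _stage("gmyc", fit_gmyc, run_dir / "partition_gmyc.tsv")
    core_io.write_partition(gmyc_part, run_dir / "partition_gmyc.tsv")
    _write_gmyc_summary(fit, run_dir / "gmyc_fit.tsv")

    # --- stage: BIN-style --------------------------------------------------
    partitions = {"NJ2": nj_part, "ABGD": abgd_part, "GMYC": gmyc_part}
    bin_part = None
    if not cfg.skip_bin:
        bin_part = _stage(
            "bin",
            lambda: binclust.bin_partition(dm, cfg.bin_threshold,
                                           cfg.bin_inflation),
            run_dir / "partition_bin.tsv",
        )
        core_io.write_partition(bin_part, run_dir / "partition_bin.tsv")
        partitions["BIN"] = bin_part

    # --- stage: congruence + reports ---------------------------------------
    report = _stage(
        "congruence",
        lambda: congruence.classify_patterns(nj_part, abgd_part, gmyc_part,
                                             bin_part),
        run_dir / "congruence.tsv",
    )
    report.to_frame().to_csv(run_dir / "congruence.tsv", sep="\t", index=False)
    core_io.write_partition(report.final_partition, run_dir / "final_otus.tsv")
    pcts = congruence.pattern_percentages(report)
    with open(run_dir / "pattern_summary.tsv", "w") as fh:
        fh.write("pattern\tn_otus\tpercent\n")
        for pat, count, pct in zip(congruence.PATTERNS,
                                   report.pattern_counts(), pcts):
            fh.write(f"{pat}\t{count}\t{pct}\n")

    clade_labels = {
        sid: (m.clade_label or "") for sid, m in aln.metadata.items()
    } if aln.metadata else None
    counts_table = congruence.method_count_table(
        list(partitions.values()), clade_labels
    )
    counts_table.to_csv(run_dir / "method_counts.tsv", sep="\t")

    summary = distances.distance_summaries(dm, nj_part, clade_labels)
    for name, frame in summary.to_frames().items():
        frame.to_csv(run_dir / f"distance_{name}.tsv", sep="\t",
                     index=(name == "clade_matrix"))
    logger.info(
        "final OTUs: %d (patterns A/B/C/D = %s)", report.n_final_otus,
        "/".join(str(c) for c in report.pattern_counts()),
    )
    return PipelineResult(
        run_dir=run_dir, alignment=aln, dm=dm, nj_tree=nj_tree,
        partitions=partitions, gmyc_fit=fit, report=report, summary=summary,
        truth=truth,
    )


def _stage(name: str, fn, artifact: Path):
    try:
        result = fn()
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {name!r} failed (artifact {artifact}): {exc}"
        ) from exc
    logger.info("stage %s done", name)
    return result


def _write_gmyc_summary(fit: gmyc.GmycFit, path: Path) -> None:
    import pandas as pd

    pd.DataFrame([{
        "threshold_time": fit.threshold_time,
        "n_entities": fit.n_entities,
        "ci_low": fit.ci_entities[0],
        "ci_high": fit.ci_entities[1],
        "lambda_yule": fit.lambda_yule,
        "lambda_coal": fit.lambda_coal,
        "p_yule": fit.p_yule,
        "p_coal": fit.p_coal,
        "logL_mixed": fit.logL_mixed,
        "logL_null": fit.logL_null,
        "LR": fit.LR,
        "p_value": fit.p_value,
        "converged": fit.converged,
    }]).to_csv(path, sep="\t", index=False)
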