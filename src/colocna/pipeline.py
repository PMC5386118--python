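"""End-to-end orchestration of the discovery-and-corroboration strategy.

The run mirrors the study flow: simulate (or load) a trio cohort,
contrast lesions against self and panel references, smooth and call
segments, extract recurrent minimal common regions, confirm them with a
median-filter second caller, keep candidate-sized regions, annotate
genes, filter by differential expression, and corroborate with
comparative-CT quantification, LOH scoring and bisulfite methylation
classification.  Every stage writes its table; a machine-readable
summary closes the run.  With a fixed seed the whole bundle is
byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as cio
from . import sim
from .candidates import (
    annotate_genes,
    count_candidate_genes,
    ddct_report,
    differential_expression_filter,
)
from .regions import (
    confirm_regions,
    filter_candidate_regions,
    find_minimal_common_regions,
    label_group_occurrence,
)
from .segmentation import (
    AberrantSegment,
    call_segments,
    compute_log2_ratio,
    median_smooth,
    pairwise_nonpairwise_conservation,
    select_best_fit_reference,
    smooth_consecutive,
)
from .twohit import (
    GenotypePair,
    classify_methylation,
    cohort_methylation_summary,
    loh_frequency,
    methylated_clone_count,
    score_loh,
)

__all__ = ["StageError", "run_pipeline", "scenario_from_config", "match_planted_segments"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


def scenario_from_config(cfg: cio.PipelineConfig) -> tuple[pd.DataFrame, sim.SimConfig]:
    """Build the probe map and planted-truth design from a run config.

    The stock scenario plants one shared loss (three carriers), one
    shared gain (two carriers) and one private loss, places a four-fold
    genomic deficit on a gene inside the shared loss, and seeds LOH and
    methylation truths.  Segment spans scale with the map so the design
    stays valid at reduced scale; two trios are the minimum.
    """
    if cfg.n_trios < 2:
        raise ValueError("the stock scenario needs at least 2 trios")
    snp_map = sim.simulate_snp_map(
        cfg.n_chromosomes, cfg.snps_per_chromosome, cfg.probe_spacing, cfg.seed
    )
    n = cfg.snps_per_chromosome
    sp = cfg.probe_spacing
    last = f"chr{cfg.n_chromosomes}"
    seg_len = max(4 * cfg.min_snps, min(40, n // 8))
    planted = [
        sim.PlantedSegment(
            "chr1", (n // 5) * sp, (n // 5 + seg_len) * sp, "loss", -1.0,
            frozenset({"A1", "T1", "T2"}),
        ),
        sim.PlantedSegment(
            last, (2 * n // 5) * sp, (2 * n // 5 + seg_len + 20) * sp, "gain", 1.0,
            frozenset({"A2", "T2"}),
        ),
        sim.PlantedSegment(
            last, (4 * n // 5) * sp, (4 * n // 5 + seg_len) * sp, "loss", -1.0,
            frozenset({f"T{cfg.n_trios}"}),
        ),
    ]
    gene_models = sim.simulate_gene_models(snp_map)
    loss_seg = planted[0]
    in_loss = gene_models[
        (gene_models["chromosome"] == loss_seg.chromosome)
        & (gene_models["start"] <= loss_seg.end)
        & (gene_models["end"] >= loss_seg.start)
    ]
    target = in_loss["symbol"].iloc[0] if len(in_loss) else gene_models["symbol"].iloc[0]
    qpcr = [
        sim.QpcrTruth("P1", target, "A", 0.25, "genomic"),
        sim.QpcrTruth("P1", target, "T", 0.25, "genomic"),
        sim.QpcrTruth("P2", target, "A", 1.0, "genomic"),
        sim.QpcrTruth("P2", target, "T", 0.5, "genomic"),
        sim.QpcrTruth("P1", target, "T", 0.25, "cDNA"),
        sim.QpcrTruth("P2", target, "T", 1.0, "cDNA"),
    ]
    loh = [(f"P{i}", "rs2230601", "LOH") for i in range(1, 6)] + [
        (f"P{i}", "rs965639", "LOH") for i in range(1, 9)
    ]
    # 26 assayed tumors: 4 extensive, 4 moderate, 18 unmethylated
    methyl = (
        [(f"P{i}", "extensive") for i in range(1, 5)]
        + [(f"P{i}", "moderate") for i in range(5, 9)]
        + [(f"P{i}", "unmethylated") for i in range(9, 27)]
    )
    config = sim.SimConfig(
        n_trios=cfg.n_trios,
        n_extra_adenomas=cfg.n_extra_adenomas,
        n_controls=cfg.n_controls,
        n_chromosomes=cfg.n_chromosomes,
        snps_per_chromosome=cfg.snps_per_chromosome,
        probe_spacing=cfg.probe_spacing,
        noise_sd=cfg.noise_sd,
        planted_segments=planted,
        qpcr_truth=qpcr,
        loh_truth=loh,
        methylation_truth=methyl,
        seed=cfg.seed,
    )
    return snp_map, config


# ---------------------------------------------------------------------------
# truth-matching harness
# ---------------------------------------------------------------------------

def _probe_index(snp_map: pd.DataFrame) -> dict[tuple[str, int], int]:
    out = {}
    for chrom, grp in snp_map.groupby("chromosome", sort=False):
        for i, p in enumerate(grp["position"].to_numpy()):
            out[(str(chrom), int(p))] = i
    return out


def match_planted_segments(
    planted: Sequence[sim.PlantedSegment],
    called: Sequence[AberrantSegment],
    snp_map: pd.DataFrame,
    slack_probes: int = 2,
) -> tuple[float, float, int]:
    """Score called segments against planted truth per carrier.

    A truth unit is one (planted segment, carrier).  A call matches a
    truth unit when sample, chromosome and state agree and both
    boundaries lie within ``slack_probes`` probes of the planted ones.
    Returns ``(recall, precision, max_boundary_error)`` with the error in
    probes over matched pairs; recall and precision are 1.0 for an empty
    truth/call set respectively.
    """
    idx = _probe_index(snp_map)
    pos_per_chrom = {
        str(c): g["position"].to_numpy() for c, g in snp_map.groupby("chromosome", sort=False)
    }

    def probe_of(chrom: str, pos: int, side: str) -> int:
        key = (chrom, pos)
        if key in idx:
            return idx[key]
        arr = pos_per_chrom[chrom]
        # planted coordinates may fall between probes; snap to the probe span
        if side == "start":
            return int(np.searchsorted(arr, pos, side="left"))
        return int(np.searchsorted(arr, pos, side="right")) - 1

    truth_units = [
        (seg, carrier) for seg in planted for carrier in sorted(seg.carriers)
    ]
    matched_truth = set()
    matched_call = set()
    max_err = 0
    for t, (seg, carrier) in enumerate(truth_units):
        t_lo = probe_of(seg.chromosome, seg.start, "start")
        t_hi = probe_of(seg.chromosome, seg.end, "end")
        for c, call in enumerate(called):
            if (
                call.sample != carrier
                or call.chromosome != seg.chromosome
                or call.state != seg.state
            ):
                continue
            c_lo = idx[(call.chromosome, call.start)]
            c_hi = idx[(call.chromosome, call.end)]
            err = max(abs(c_lo - t_lo), abs(c_hi - t_hi))
            if err <= slack_probes:
                matched_truth.add(t)
                matched_call.add(c)
                max_err = max(max_err, err)
    recall = len(matched_truth) / len(truth_units) if truth_units else 1.0
    precision = len(matched_call) / len(called) if called else 1.0
    return recall, precision, max_err


# ---------------------------------------------------------------------------
# orchestrator
# ---------------------------------------------------------------------------

def _segment_lesions_pairwise(
    matrix: pd.DataFrame, snp_map: pd.DataFrame, cfg: cio.PipelineConfig, n_trios: int
) -> list[AberrantSegment]:
    segs: list[AberrantSegment] = []
    for i in range(1, n_trios + 1):
        normal = matrix[f"N{i}"]
        for lesion in (f"A{i}", f"T{i}"):
            ratio = compute_log2_ratio(matrix[lesion], normal, cfg.epsilon)
            smoothed = smooth_consecutive(ratio, snp_map, cfg.window)
            segs += call_segments(
                smoothed, snp_map, lesion,
                cfg.gain_threshold, cfg.loss_threshold, cfg.min_snps,
            )
    return segs


def _segment_lesions_nonpairwise(
    matrix: pd.DataFrame,
    snp_map: pd.DataFrame,
    cfg: cio.PipelineConfig,
    lesions: Sequence[str],
    controls: Sequence[str],
    smoother,
) -> list[AberrantSegment]:
    segs: list[AberrantSegment] = []
    panel = matrix[list(controls)]
    for lesion in lesions:
        profile, _ = select_best_fit_reference(
            matrix[lesion], panel, cfg.k_reference, cfg.epsilon
        )
        ratio = compute_log2_ratio(matrix[lesion], profile, cfg.epsilon)
        smoothed = smoother(ratio, snp_map, cfg.window)
        segs += call_segments(
            smoothed, snp_map, lesion,
            cfg.gain_threshold, cfg.loss_threshold, cfg.min_snps,
        )
    return segs


def run_pipeline(cfg: cio.PipelineConfig) -> dict:
    """Execute the full strategy and return the run summary.

    All stage outputs land in ``cfg.out_dir``; the summary is also
    written there as ``summary.json``.  Any stage failure raises
    :class:`StageError` naming the stage, leaving earlier outputs in
    place.
    """
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    summary: dict = {"seed": cfg.seed, "config_hash": chash}
    stage = "configure"
    try:
        stage = "simulate"
        if cfg.intensity_path and cfg.sample_sheet_path:
            snp_map, matrix = cio.read_matrix_tsv(cfg.intensity_path)
            sheet = cio.read_table_tsv(cfg.sample_sheet_path)
            sim_cfg = None
            truth = None
            lesions = sheet.loc[sheet["class"].isin(["A", "T"]), "sample_id"].tolist()
            controls = sheet.loc[sheet["class"] == "C", "sample_id"].tolist()
            n_trios = int((sheet["class"] == "N").sum())
        else:
            snp_map, sim_cfg = scenario_from_config(cfg)
            matrix, sheet, truth = sim.simulate_cohort(snp_map, sim_cfg)
            lesions = sim_cfg.lesions
            controls = sim_cfg.controls
            n_trios = sim_cfg.n_trios
            cio.write_matrix_tsv(matrix, snp_map, out / "intensity.tsv", chash)
            cio.write_table_tsv(sheet, out / "sample_sheet.tsv", chash)

        stage = "segment-pairwise"
        segs_pw = _segment_lesions_pairwise(matrix, snp_map, cfg, n_trios)
        cio.write_segments_tsv(segs_pw, out / "segments_pairwise.tsv", chash)

        stage = "segment-nonpairwise"
        segs_npw = _segment_lesions_nonpairwise(
            matrix, snp_map, cfg, lesions, controls, smooth_consecutive
        )
        cio.write_segments_tsv(segs_npw, out / "segments_nonpairwise.tsv", chash)
        cio.write_bed(segs_npw, out / "segments_nonpairwise.bed")

        stage = "conservation"
        conservation = pairwise_nonpairwise_conservation(
            segs_pw, segs_npw, cfg.conservation_coverage
        )
        summary["n_segments_pairwise"] = len(segs_pw)
        summary["n_segments_nonpairwise"] = len(segs_npw)
        summary["conservation_pairwise_in_nonpairwise"] = conservation

        stage = "minimal-common-regions"
        mcrs = find_minimal_common_regions(segs_npw, cfg.min_support, cfg.min_size)

        stage = "confirm"
        second = _segment_lesions_nonpairwise(
            matrix, snp_map, cfg, lesions, controls, median_smooth
        )
        mcrs = confirm_regions(mcrs, second, cfg.reciprocal_overlap, cfg.min_support)

        stage = "group-labels"
        mcrs = [
            replace(m, groups=label_group_occurrence(m, sheet)) for m in mcrs
        ]
        cio.write_mcr_tsv(mcrs, out / "mcr.tsv", chash)
        cio.write_bed(mcrs, out / "mcr.bed")
        summary["n_mcrs"] = len(mcrs)
        summary["n_mcrs_gain"] = sum(m.state == "gain" for m in mcrs)
        summary["n_mcrs_loss"] = sum(m.state == "loss" for m in mcrs)
        summary["n_mcrs_confirmed"] = sum(bool(m.confirmed) for m in mcrs)

        stage = "candidate-filter"
        candidates = filter_candidate_regions(mcrs, cfg.max_size)
        cio.write_mcr_tsv(candidates, out / "candidate_regions.tsv", chash)
        summary["n_candidate_regions"] = len(candidates)

        stage = "annotate"
        gene_models = sim.simulate_gene_models(snp_map)
        annotation = annotate_genes(
            candidates, gene_models, region_assembly="sim1", gene_assembly="sim1"
        )
        cio.write_table_tsv(
            pd.DataFrame(
                {
                    "chromosome": [m.chromosome for m in candidates],
                    "start": [m.start for m in candidates],
                    "end": [m.end for m in candidates],
                    "state": [m.state for m in candidates],
                    "genes": [",".join(g) for g in annotation],
                }
            ),
            out / "gene_annotation.tsv",
            chash,
        )
        summary["n_candidate_genes"] = count_candidate_genes(annotation)

        stage = "differential-expression"
        loss_genes = sorted(
            {
                g
                for m, genes in zip(candidates, annotation)
                for g in genes
                if m.state == "loss"
            }
        )
        all_genes = gene_models["symbol"].tolist()
        expr, labels = sim.simulate_expression(
            all_genes, loss_genes, seed=cfg.seed + 1
        )
        de = differential_expression_filter(expr, labels, cfg.de_alpha)
        cio.write_table_tsv(de, out / "de_genes.tsv", chash)
        summary["n_de_genes"] = len(de)
        summary["n_de_down"] = int((de["direction"] == "down").sum())

        stage = "qpcr"
        if sim_cfg is not None and sim_cfg.qpcr_truth:
            qpcr = sim.simulate_qpcr(
                sim_cfg.qpcr_truth, seed=cfg.seed + 2, noise_sd=sim_cfg.qpcr_noise_sd
            )
            cio.write_table_tsv(qpcr, out / "qpcr.tsv", chash)
            report = ddct_report(
                qpcr, decrease_threshold=cfg.decrease_threshold,
                increase_threshold=cfg.increase_threshold,
            )
            cio.write_table_tsv(report, out / "ddct_report.tsv", chash)
            summary["n_qpcr_lesions"] = len(report)
            summary["n_qpcr_decreased"] = int((report["status"] == "decreased").sum())

        stage = "loh"
        if sim_cfg is not None:
            genotypes, n_unreal = sim.simulate_genotypes(
                cfg.n_loh_pairs, sim_cfg.marker_mafs, sim_cfg.loh_truth,
                seed=cfg.seed + 3,
            )
            cio.write_table_tsv(genotypes, out / "genotypes.tsv", chash)
            calls = [
                score_loh(
                    GenotypePair(
                        r.pair_id, r.marker, r.normal_call,
                        (r.tumor_call_1, r.tumor_call_2),
                    )
                )
                for r in genotypes.itertuples()
            ]
            loh_rows = []
            for marker in sorted(sim_cfg.marker_mafs):
                freq, n_loh, n_inf = loh_frequency(
                    [c for c in calls if c.marker == marker]
                )
                loh_rows.append((marker, freq, n_loh, n_inf))
                summary[f"loh_pct_{marker}"] = freq
                summary[f"loh_informative_{marker}"] = n_inf
            summary["loh_unrealizable_planted"] = n_unreal
            cio.write_table_tsv(
                pd.DataFrame(
                    loh_rows, columns=["marker", "loh_pct", "n_loh", "n_informative"]
                ),
                out / "loh_summary.tsv",
                chash,
            )

        stage = "methylation"
        if sim_cfg is not None and sim_cfg.methylation_truth:
            rows = []
            recovered = 0
            for i, (sample, target) in enumerate(sim_cfg.methylation_truth):
                clones = sim.simulate_bisulfite_clones(
                    target, cfg.n_clones, cfg.n_cpg,
                    seed=cfg.seed + 10 + i,
                    clone_rule_fraction=cfg.clone_rule_fraction,
                )
                count = methylated_clone_count(clones, cfg.clone_rule_fraction)
                cls = classify_methylation(count, cfg.n_clones, sample)
                recovered += cls.label == target
                rows.append((sample, target, count, cls.label))
            report = pd.DataFrame(
                rows, columns=["sample", "planted_class", "methylated_clones", "class"]
            )
            cio.write_table_tsv(report, out / "methylation_report.tsv", chash)
            meth_summary = cohort_methylation_summary(report["class"].tolist())
            for label, (n, pct) in meth_summary.items():
                summary[f"methylation_{label}_n"] = n
                summary[f"methylation_{label}_pct"] = pct
            summary["methylation_truth_recovered"] = recovered / len(rows)

        stage = "truth-matching"
        if truth is not None:
            recall, precision, max_err = match_planted_segments(
                truth.planted_segments, segs_npw, snp_map
            )
            summary["segment_recall"] = recall
            summary["segment_precision"] = precision
            summary["segment_max_boundary_error_probes"] = max_err
            n_expected = len(truth.expected_mcrs)
            hit = 0
            slack = 2 * cfg.probe_spacing
            for chrom, start, end, state, supp in truth.expected_mcrs:
                # recovered when the expected span (minus boundary slack) is
                # nearly covered by MCRs carrying at least its supporter set
                core_lo, core_hi = start + slack, end - slack
                covered = 0
                for m in mcrs:
                    if (
                        m.chromosome == chrom
                        and m.state == state
                        and m.supporting_samples >= supp
                    ):
                        covered += max(
                            0, min(m.end, core_hi) - max(m.start, core_lo) + 1
                        )
                if core_hi >= core_lo and covered >= 0.9 * (core_hi - core_lo + 1):
                    hit += 1
            summary["mcr_recall"] = hit / n_expected if n_expected else 1.0

        stage = "summary"
        cfg.to_yaml(out / "config.yaml")
        (out / "summary.json").write_text(
            json.dumps(summary, sort_keys=True, indent=2) + "\n"
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage context is the contract
        raise StageError(stage, exc) from exc
    return summary
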