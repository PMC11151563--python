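"""End-to-end orchestration over a workspace of input files.

The workspace layout is the one the simulator emits (and the one a user
prepares for real data): transcripts.gtf, counts.tsv + samples.tsv,
optionally tissue_counts.tsv + tissue_samples.tsv, chrom.sizes,
term_map.tsv + term_names.tsv.  Every stage writes plain TSVs with a
header row into the output directory; all coordinates are 1-based
inclusive.  Given the same inputs and configuration the outputs are
byte-identical across runs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation, classify, enrichment, expression, features, windows
from .annotation import MRNA, TranscriptSet
from .config import PipelineConfig
from .evaluate import score_leaf_calls, score_salt_calls
from .expression import ExpressionResult, SampleSheet

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

SWEEP_CUTOFFS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 2))


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     dtype={"chrom": str, "length": int})
    return dict(zip(df["chrom"], df["length"]))


def normalize_stage(
    counts: pd.DataFrame, ts: TranscriptSet
) -> ExpressionResult:
    factors = expression.tmm_factors(counts)
    return expression.fpkm(counts, factors, ts)


def run_pipeline(
    indir: str | Path,
    outdir: str | Path,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Chain every stage on one workspace; returns a summary dict."""
    cfg = cfg or PipelineConfig()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    ts = annotation.read_gtf(indir / "transcripts.gtf")
    coding_path = indir / "coding_flags.tsv"
    if coding_path.exists():
        ts = annotation.apply_coding_flags(ts, annotation.read_coding_flags(coding_path))

    retained, rejections = annotation.filter_lncrna_candidates(
        ts, cfg.min_length, cfg.min_exons
    )
    _write(rejections, outdir / "rejections.tsv")
    summary["n_lncrna_retained"] = len(retained)
    summary["n_lncrna_rejected"] = len(rejections)

    sheet = SampleSheet.read_tsv(indir / "samples.tsv")
    counts = expression.read_counts(indir / "counts.tsv", sheet)
    expr = normalize_stage(counts, ts)
    _write(expr.tmm_factor.rename_axis("sample_id").reset_index(), outdir / "tmm_factors.tsv")
    _write(expr.fpkm.rename_axis("transcript_id"), outdir / "fpkm.tsv", index=True)

    lnc_ids = [i for i in retained.ids if i in counts.index]
    fct = expression.fold_change_table(expr, sheet, pseudocount=cfg.pseudocount).loc[lnc_ids]
    _write(fct.rename_axis("transcript_id"), outdir / "fold_changes.tsv", index=True)

    rule_cfg = classify.ClassificationConfig(cfg.strong_threshold, cfg.weak_threshold)
    calls = classify.call_all(fct, rule_cfg)
    _write(calls.rename_axis("transcript_id"), outdir / "salt_calls.tsv", index=True)
    summary["calls"] = classify.summarize_calls(calls)

    ct = classify.crosstalk(calls, fct)
    _write(ct.fc_correlations, outdir / "crosstalk.tsv")
    _write(pd.DataFrame({"transcript_id": sorted(ct.overlap_up)}), outdir / "overlap_up.tsv")
    _write(pd.DataFrame({"transcript_id": sorted(ct.overlap_down)}), outdir / "overlap_down.tsv")
    summary["overlap_up"] = ct.overlap_up_count
    summary["overlap_down"] = ct.overlap_down_count

    sizes_path = indir / "chrom.sizes"
    chrom_lengths = read_chrom_sizes(sizes_path) if sizes_path.exists() else ts.chrom_lengths
    bins = windows.make_bins(chrom_lengths, cfg.window_size)
    bins = windows.assign_counts(bins, ts, calls, anchor=cfg.anchor)
    _write(bins, outdir / "window_counts.tsv")
    _write(windows.per_chromosome_totals(bins), outdir / "chromosome_totals.tsv")

    feats = features.compute_features(retained)
    _write(feats.rename_axis("transcript_id"), outdir / "features.tsv", index=True)
    feat_summary, ecdfs, ks = features.compare_groups(feats, calls)
    _write(feat_summary, outdir / "feature_summary.tsv")
    _write(ks, outdir / "feature_ks.tsv")
    ecdf_rows = []
    for (group, feat), table in ecdfs.items():
        table = table.assign(group=group, feature=feat)
        ecdf_rows.append(table[["group", "feature", "value", "ecdf"]])
    if ecdf_rows:
        _write(pd.concat(ecdf_rows, ignore_index=True), outdir / "feature_ecdf.tsv")

    tissue_counts_path = indir / "tissue_counts.tsv"
    if tissue_counts_path.exists():
        tissue_sheet = SampleSheet.read_tsv(indir / "tissue_samples.tsv")
        tissue_counts = expression.read_counts(tissue_counts_path, tissue_sheet)
        tissue_expr = normalize_stage(tissue_counts, ts)
        profiles = features.tissue_profiles(
            tissue_expr, tissue_sheet, cfg.tissue_cutoff, cfg.target_tissue
        ).loc[lnc_ids]
        _write(profiles.rename_axis("transcript_id"), outdir / "tissue_profiles.tsv", index=True)
        groups = {
            "short_SA": calls.index[calls["short_label"] != "none"],
            "long_SA": calls.index[calls["long_label"] != "none"],
            "SNA": calls.index[~calls["is_SA"]],
        }
        sweep = features.specificity_sweep(profiles, SWEEP_CUTOFFS, groups)
        _write(sweep.reset_index(), outdir / "specificity_sweep.tsv")
        summary["n_leaf_specific"] = int(profiles[f"{cfg.target_tissue}_specific"].sum())

    term_map_path = indir / "term_map.tsv"
    if term_map_path.exists():
        names_path = indir / "term_names.tsv"
        tmap = enrichment.TermMap.read_tsv(
            term_map_path, names_path if names_path.exists() else None
        )
        sa_ids = calls.index[calls["is_SA"]]
        mrna_ids = [t.transcript_id for t in ts.by_biotype(MRNA) if t.transcript_id in expr.fpkm.index]
        # correlate on log2(FPKM + 1): Pearson on the linear scale is
        # dominated by the few highest-expression samples
        log_fpkm = np.log2(expr.fpkm + 1.0)
        edges = enrichment.coexpression_edges(
            log_fpkm.loc[log_fpkm.index.intersection(sa_ids)],
            log_fpkm.loc[mrna_ids],
            cfg.r_cutoff,
            cfg.fdr_cutoff,
        )
        _write(edges, outdir / "coexpression_edges.tsv")
        summary["n_edges"] = len(edges)
        if cfg.enrichment_mode == "group":
            results = enrichment.annotate_lncrna_groups(
                edges, calls, tmap, mode="group", top_n=cfg.top_n
            )
            for group, res in results.items():
                _write(res, outdir / f"enrichment_{group}.tsv")
            summary["enriched_groups"] = sorted(results)
        else:
            per_lnc, ranking, sif = enrichment.annotate_lncrna_groups(
                edges, calls, tmap, mode="per_lncrna",
                top_n=cfg.top_n, fdr_cutoff=cfg.fdr_cutoff,
            )
            _write(ranking, outdir / "enrichment_term_ranking.tsv")
            _write(sif, outdir / "lncrna_term_network.sif")
            summary["n_annotated_lncrnas"] = len(per_lnc)

    truth_path = indir / "truth_transcripts.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t", index_col=0)
        summary["truth_scores"] = score_salt_calls(calls, truth)
        if tissue_counts_path.exists() and "true_leaf_specific" in truth:
            summary["truth_scores"].update(
                score_leaf_calls(profiles, truth, cfg.target_tissue)
            )
    logger.info("pipeline summary: %s", summary)
    return summary
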