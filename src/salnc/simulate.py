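"""Synthetic study generator with planted ground truth.

Emulates the structure of the salt-stress study this pipeline targets: a
multi-chromosome genome carrying lncRNA and mRNA transcript models, a
negative-binomial count matrix over a control and four salt conditions
(24 h / 48 h short-term, 14 d / 28 d long-term), a five-tissue expression
panel, and a GO/KEGG-style term map.  Every planted signal (salt effects,
leaf specificity, co-expression blocks, enriched terms) is recorded in a
truth ledger so each pipeline stage can be scored without re-derivation.

Counts follow the gamma-Poisson (negative binomial) model with mean m and
variance m + dispersion * m**2 — the count model underlying TMM-based
normalization.  Per-sample depth factors are drawn log-uniformly in
[0.5, 2] so the TMM correction is load-bearing rather than a no-op.
Co-expression between a lncRNA and its partner mRNA block is induced by a
shared per-sample Gaussian factor added to both log2 means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    LNCRNA,
    MRNA,
    GenomicInterval,
    TranscriptModel,
    TranscriptSet,
    write_gtf,
)
from .expression import CONDITIONS, TISSUES, SampleSheet
from .enrichment import TermMap

logger = logging.getLogger(__name__)

_SLOT_SIZE = 3000  # bp reserved per transcript; bounds every genomic span


@dataclass
class SimulationConfig:
    """Study-scale knobs; the defaults are the simulated study conditions."""

    seed: int = 0
    n_chroms: int = 5
    chrom_length: int = 2_000_000
    n_lncrna: int = 2000
    n_mrna: int = 1000
    replicates_per_condition: int = 3
    nb_dispersion: float = 0.1
    baseline_mean_range: tuple[float, float] = (50.0, 500.0)
    planted_fraction_up: float = 0.10
    planted_fraction_down: float = 0.10
    effect_size: float = 2.0
    depth_range: tuple[float, float] = (0.5, 2.0)
    tissue_concentration: float = 3.0
    planted_leaf_fraction: float = 0.2
    planted_leaf_weight: float = 0.9
    tissue_replicates: int = 2
    n_terms: int = 30
    planted_term_count: int = 5
    term_background_rate: float = 0.05
    coexpr_block_size: int = 10
    n_coexpr_lnc: int = 5
    latent_sd: float = 2.0
    spiked_short: int = 2
    spiked_single_exon: int = 2
    spiked_overlapping: int = 2

    def __post_init__(self) -> None:
        if self.planted_fraction_up + self.planted_fraction_down > 1:
            raise ValueError("planted fractions must sum to <= 1 per regime")
        for name in (
            "n_chroms", "chrom_length", "n_lncrna", "n_mrna",
            "replicates_per_condition", "tissue_replicates", "n_terms",
            "coexpr_block_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 < self.planted_leaf_weight < 1:
            raise ValueError("planted_leaf_weight must lie in (0, 1)")
        spiked = self.spiked_short + self.spiked_single_exon + self.spiked_overlapping
        if spiked > self.n_lncrna:
            raise ValueError("spiked failures exceed n_lncrna")
        capacity = self.n_chroms * (self.chrom_length // _SLOT_SIZE)
        if self.n_lncrna + self.n_mrna > capacity:
            raise ValueError(
                f"transcripts cannot fit: need {self.n_lncrna + self.n_mrna} "
                f"slots of {_SLOT_SIZE} bp, genome holds {capacity}"
            )

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


def _exon_chain(rng, start: int, n_exons: int, first_len, other_len, intron_len):
    exons = []
    pos = start
    for j in range(n_exons):
        lo, hi = first_len if j == 0 else other_len
        length = int(rng.integers(lo, hi + 1))
        exons.append(GenomicInterval(pos, pos + length - 1))
        pos += length + int(rng.integers(intron_len[0], intron_len[1] + 1))
    return tuple(exons)


def simulate_annotation(cfg: SimulationConfig, rng: np.random.Generator):
    """Transcript models plus the structural part of the truth ledger.

    Non-spiked lncRNAs pass the candidate filter by construction (first
    exon >= 150 bp so the mature length clears 200, 2-5 exons, placed in
    genome slots disjoint from every mRNA).  Spiked failures exercise
    each rejection reason: too short, single-exon, mRNA-exon overlap.
    """
    n_slots_per_chrom = cfg.chrom_length // _SLOT_SIZE
    slots = [
        (f"chr{c + 1}", s * _SLOT_SIZE + 1)
        for c in range(cfg.n_chroms)
        for s in range(n_slots_per_chrom)
    ]
    order = rng.permutation(len(slots))
    strands = np.where(rng.random(cfg.n_mrna + cfg.n_lncrna) < 0.5, "+", "-")

    transcripts: list[TranscriptModel] = []
    truth_rows: list[dict] = []
    slot_i = 0

    mrnas: list[TranscriptModel] = []
    for i in range(cfg.n_mrna):
        chrom, start = slots[order[slot_i]]
        slot_i += 1
        exons = _exon_chain(
            rng, start + int(rng.integers(0, 50)),
            int(rng.integers(2, 7)), (150, 300), (150, 300), (80, 200),
        )
        t = TranscriptModel(
            f"MRNA{i:05d}", f"GM{i:05d}", chrom, str(strands[i]), exons, MRNA
        )
        mrnas.append(t)
        truth_rows.append(
            {"transcript_id": t.transcript_id, "biotype": MRNA,
             "passes_filter": False, "fail_reason": "", "spiked": ""}
        )
    transcripts.extend(mrnas)

    n_spiked = cfg.spiked_short + cfg.spiked_single_exon + cfg.spiked_overlapping
    spike_kinds = (
        ["length"] * cfg.spiked_short
        + ["exons"] * cfg.spiked_single_exon
        + ["overlap"] * cfg.spiked_overlapping
        + [""] * (cfg.n_lncrna - n_spiked)
    )
    for i in range(cfg.n_lncrna):
        kind = spike_kinds[i]
        strand = str(strands[cfg.n_mrna + i])
        if kind == "overlap" and mrnas:
            # reuse the first two exons of a random mRNA: guaranteed overlap,
            # length and exon count still pass
            host = mrnas[int(rng.integers(0, len(mrnas)))]
            exons, chrom = host.exons[:2], host.chrom
            slot_i += 1  # keep slot consumption deterministic across kinds
        else:
            chrom, start = slots[order[slot_i]]
            slot_i += 1
            start += int(rng.integers(0, 50))
            if kind == "length":
                exons = (
                    GenomicInterval(start, start + 59),
                    GenomicInterval(start + 160, start + 239),
                )
            elif kind == "exons":
                exons = (GenomicInterval(start, start + 499),)
            else:
                exons = _exon_chain(
                    rng, start, int(rng.integers(2, 6)),
                    (150, 300), (80, 300), (80, 200),
                )
        t = TranscriptModel(
            f"LNC{i:05d}", f"GL{i:05d}", chrom, strand, exons, LNCRNA
        )
        transcripts.append(t)
        truth_rows.append(
            {"transcript_id": t.transcript_id, "biotype": LNCRNA,
             "passes_filter": kind == "", "fail_reason": kind, "spiked": kind}
        )
    truth = pd.DataFrame(truth_rows).set_index("transcript_id")
    return TranscriptSet(transcripts, cfg.chrom_lengths), truth


def _draw_labels(rng, n: int, p_up: float, p_down: float) -> np.ndarray:
    u = rng.random(n)
    out = np.full(n, "none", dtype=object)
    out[u < p_up] = "up"
    out[(u >= p_up) & (u < p_up + p_down)] = "down"
    return out


def _nb_sample(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    return rng.negative_binomial(size, size / (size + mean))


def simulate_counts(cfg: SimulationConfig, ts: TranscriptSet, truth: pd.DataFrame,
                    rng: np.random.Generator):
    """Salt-experiment counts, sample sheet and the expression truth columns.

    A lncRNA planted up in the short regime gets +effect_size log2 units
    added to its mean in every 24 h and 48 h sample (mirrored for down;
    analogous in 14 d / 28 d for the long regime), so the planted effect
    vector satisfies the classification rules at the mean.  Co-expression
    blocks share a per-sample latent factor between one lncRNA and
    ``coexpr_block_size`` mRNAs.
    """
    ids = list(truth.index)
    n = len(ids)
    lnc_mask = (truth["biotype"] == LNCRNA).to_numpy()
    passing = (truth["passes_filter"]).to_numpy()

    baseline = np.exp(
        rng.uniform(np.log(cfg.baseline_mean_range[0]),
                    np.log(cfg.baseline_mean_range[1]), size=n)
    )
    short = np.full(n, "none", dtype=object)
    long_ = np.full(n, "none", dtype=object)
    short[lnc_mask] = _draw_labels(
        rng, int(lnc_mask.sum()), cfg.planted_fraction_up, cfg.planted_fraction_down
    )
    long_[lnc_mask] = _draw_labels(
        rng, int(lnc_mask.sum()), cfg.planted_fraction_up, cfg.planted_fraction_down
    )
    # spiked transcripts never reach classification; keep their truth silent
    short[lnc_mask & ~passing] = "none"
    long_[lnc_mask & ~passing] = "none"

    # co-expression blocks: one passing lncRNA + a disjoint mRNA set each
    block_id = np.full(n, "", dtype=object)
    idx = {tid: i for i, tid in enumerate(ids)}
    candidates = [i for i in range(n) if lnc_mask[i] and passing[i]]
    planted_first = [i for i in candidates if short[i] != "none" or long_[i] != "none"]
    pool = planted_first + [i for i in candidates if i not in set(planted_first)]
    n_blocks = min(cfg.n_coexpr_lnc, len(pool))
    mrna_ids = [i for i in range(n) if not lnc_mask[i]]
    mrna_perm = rng.permutation(len(mrna_ids))
    blocks: list[tuple[int, list[int]]] = []
    for b in range(n_blocks):
        members = mrna_perm[b * cfg.coexpr_block_size:(b + 1) * cfg.coexpr_block_size]
        if len(members) < cfg.coexpr_block_size:
            break
        lnc_i = pool[b]
        member_idx = [mrna_ids[j] for j in members]
        blocks.append((lnc_i, member_idx))
        block_id[lnc_i] = f"B{b}"
        for j in member_idx:
            block_id[j] = f"B{b}"

    samples, cond_of = [], []
    for cond in CONDITIONS:
        for r in range(1, cfg.replicates_per_condition + 1):
            samples.append(f"{cond}_{r}")
            cond_of.append(cond)
    n_samples = len(samples)
    cond_effect = {c: np.zeros(n) for c in CONDITIONS}
    e = cfg.effect_size
    for regime, conds in (("short", ("24h", "48h")), ("long", ("14d", "28d"))):
        labels = short if regime == "short" else long_
        delta = np.where(labels == "up", e, np.where(labels == "down", -e, 0.0))
        for c in conds:
            cond_effect[c] = cond_effect[c] + delta

    log2_depth = rng.uniform(
        np.log2(cfg.depth_range[0]), np.log2(cfg.depth_range[1]), size=n_samples
    )
    log2_mean = (
        np.log2(baseline)[:, None]
        + np.stack([cond_effect[c] for c in cond_of], axis=1)
        + log2_depth[None, :]
    )
    for b, (lnc_i, member_idx) in enumerate(blocks):
        z = rng.normal(0.0, 1.0, size=n_samples)
        bump = cfg.latent_sd * z
        log2_mean[lnc_i] += bump
        # partner mRNAs share both the latent factor and the lncRNA's salt
        # response: co-expression of a salt-responsive regulator and its
        # targets includes the condition signal itself
        lnc_cond = np.array([cond_effect[c][lnc_i] for c in cond_of])
        for j in member_idx:
            log2_mean[j] += bump + lnc_cond

    counts = _nb_sample(rng, 2.0 ** log2_mean, cfg.nb_dispersion)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=ids, columns=samples)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "condition": cond_of,
                "tissue": "none",
                "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
            }
        )
    )
    truth = truth.copy()
    truth["true_short"] = short
    truth["true_long"] = long_
    truth["block_id"] = block_id
    truth["baseline_mean"] = baseline
    return counts_df, sheet, truth


def simulate_tissue_panel(cfg: SimulationConfig, ts: TranscriptSet,
                          truth: pd.DataFrame, rng: np.random.Generator):
    """Five-tissue panel with a planted leaf-specific lncRNA subset.

    Planted transcripts put ``planted_leaf_weight`` of their expression
    mass in leaf (the rest spread over the other tissues); the remainder
    draw symmetric-Dirichlet tissue weights, giving typical specificity
    scores around 0.25-0.35 at the default concentration.
    """
    ids = list(truth.index)
    n = len(ids)
    lnc_mask = (truth["biotype"] == LNCRNA).to_numpy()
    passing = truth["passes_filter"].to_numpy()
    eligible = np.where(lnc_mask & passing)[0]
    n_planted = int(round(cfg.planted_leaf_fraction * len(eligible)))
    planted = rng.choice(eligible, size=n_planted, replace=False) if n_planted else []
    leaf_flag = np.zeros(n, dtype=bool)
    leaf_flag[list(planted)] = True

    n_t = len(TISSUES)
    weights = rng.dirichlet(np.full(n_t, cfg.tissue_concentration), size=n)
    if n_planted:
        rest = rng.dirichlet(np.ones(n_t - 1), size=n_planted)
        leaf_i = TISSUES.index("leaf")
        w = np.empty((n_planted, n_t))
        w[:, leaf_i] = cfg.planted_leaf_weight
        others = [j for j in range(n_t) if j != leaf_i]
        w[:, others] = (1.0 - cfg.planted_leaf_weight) * rest
        weights[list(planted)] = w

    baseline = truth["baseline_mean"].to_numpy() if "baseline_mean" in truth else (
        np.exp(rng.uniform(np.log(cfg.baseline_mean_range[0]),
                           np.log(cfg.baseline_mean_range[1]), size=n))
    )
    samples, tissue_of = [], []
    for t in TISSUES:
        for r in range(1, cfg.tissue_replicates + 1):
            samples.append(f"{t}_{r}")
            tissue_of.append(t)
    depth = 2.0 ** rng.uniform(
        np.log2(cfg.depth_range[0]), np.log2(cfg.depth_range[1]), size=len(samples)
    )
    tissue_idx = np.array([TISSUES.index(t) for t in tissue_of])
    mean = baseline[:, None] * n_t * weights[:, tissue_idx] * depth[None, :]
    counts = _nb_sample(rng, mean, cfg.nb_dispersion)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=ids, columns=samples)
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "condition": "none",
                "tissue": tissue_of,
                "replicate": [int(s.rsplit("_", 1)[1]) for s in samples],
            }
        )
    )
    truth = truth.copy()
    truth["true_leaf_specific"] = leaf_flag
    return counts_df, sheet, truth


def simulate_term_map(cfg: SimulationConfig, truth: pd.DataFrame,
                      rng: np.random.Generator):
    """Term map with planted enrichment in the co-expression blocks.

    Each planted term annotates every mRNA of one block plus background
    mRNAs at ``term_background_rate``; null terms annotate background
    only, so a planted term is maximally overrepresented in the partner
    set of its block's lncRNA.
    """
    mrna_ids = [t for t in truth.index if truth.loc[t, "biotype"] == MRNA]
    block_of = truth["block_id"] if "block_id" in truth else pd.Series("", index=truth.index)
    blocks = sorted(
        {b for b in block_of.loc[mrna_ids].unique() if b},
        key=lambda s: int(s[1:]),
    )
    n_planted = min(cfg.planted_term_count, len(blocks))
    mapping: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    term_rows = []

    def _annotate(term: str, members) -> None:
        for m in members:
            mapping.setdefault(m, set()).add(term)

    for b in range(n_planted):
        term = f"TERM_P{b:03d}"
        names[term] = f"planted process {b}"
        block_members = [m for m in mrna_ids if block_of[m] == blocks[b]]
        background = [m for m in mrna_ids if rng.random() < cfg.term_background_rate]
        _annotate(term, set(block_members) | set(background))
        term_rows.append({"term_id": term, "planted": True, "block_id": blocks[b]})
    for j in range(cfg.n_terms - n_planted):
        term = f"TERM_N{j:03d}"
        names[term] = f"background process {j}"
        members = [m for m in mrna_ids if rng.random() < cfg.term_background_rate]
        _annotate(term, members)
        term_rows.append({"term_id": term, "planted": False, "block_id": ""})
    tmap = TermMap({m: frozenset(t) for m, t in mapping.items()}, names, "GO-BP")
    terms_truth = pd.DataFrame(term_rows, columns=["term_id", "planted", "block_id"])
    return tmap, terms_truth


@dataclass
class SimulatedStudy:
    """Everything one seed produces, plus the truth ledger."""

    cfg: SimulationConfig
    ts: TranscriptSet
    counts: pd.DataFrame
    sheet: SampleSheet
    tissue_counts: pd.DataFrame
    tissue_sheet: SampleSheet
    term_map: TermMap
    truth_transcripts: pd.DataFrame
    truth_terms: pd.DataFrame

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.cfg.chrom_lengths

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(self.ts, outdir / "transcripts.gtf")
        self.counts.rename_axis("transcript_id").to_csv(
            outdir / "counts.tsv", sep="\t"
        )
        self.sheet.write_tsv(outdir / "samples.tsv")
        self.tissue_counts.rename_axis("transcript_id").to_csv(
            outdir / "tissue_counts.tsv", sep="\t"
        )
        self.tissue_sheet.write_tsv(outdir / "tissue_samples.tsv")
        pd.DataFrame(
            {"chrom": list(self.chrom_lengths), "length": list(self.chrom_lengths.values())}
        ).to_csv(outdir / "chrom.sizes", sep="\t", index=False, header=False)
        self.term_map.write_tsv(outdir / "term_map.tsv", outdir / "term_names.tsv")
        self.truth_transcripts.to_csv(outdir / "truth_transcripts.tsv", sep="\t")
        self.truth_terms.to_csv(outdir / "truth_terms.tsv", sep="\t", index=False)


def simulate_study(cfg: SimulationConfig) -> SimulatedStudy:
    """Run the full generator under one seed (fully deterministic)."""
    rng = np.random.default_rng(cfg.seed)
    ts, truth = simulate_annotation(cfg, rng)
    counts, sheet, truth = simulate_counts(cfg, ts, truth, rng)
    tissue_counts, tissue_sheet, truth = simulate_tissue_panel(cfg, ts, truth, rng)
    tmap, terms_truth = simulate_term_map(cfg, truth, rng)
    logger.info(
        "simulated study: %d transcripts, %d salt samples, %d tissue samples, %d terms",
        len(ts), counts.shape[1], tissue_counts.shape[1], len(terms_truth),
    )
    return SimulatedStudy(
        cfg, ts, counts, sheet, tissue_counts, tissue_sheet, tmap, truth, terms_truth
    )
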