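"""Chromosome-window density of salt-associated lncRNAs.

Each chromosome is tiled with fixed-width bins (default 200 kb, step equal
to width, last bin truncated at the chromosome end) and each called lncRNA
is assigned to exactly one bin by an anchor coordinate.  A transcript
qualifying in both regimes increments both the short_SA and long_SA
category in its bin; SNA transcripts increment SNA.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .annotation import TranscriptSet

CATEGORIES = ("short_SA", "long_SA", "SNA")
ANCHORS = ("span_start", "midpoint")


def make_bins(
    chrom_lengths: Mapping[str, int], window_size: int = 200_000
) -> pd.DataFrame:
    """Zero-count bins tiling [1, length] for every chromosome."""
    if window_size < 1:
        raise ValueError(f"window_size must be >= 1, got {window_size}")
    rows = []
    for chrom, length in chrom_lengths.items():
        if length < 1:
            raise ValueError(f"chromosome {chrom}: non-positive length {length}")
        n_bins = int(np.ceil(length / window_size))
        for i in range(n_bins):
            start = i * window_size + 1
            end = min((i + 1) * window_size, length)
            rows.append({"chrom": chrom, "bin_index": i + 1, "start": start, "end": end})
    bins = pd.DataFrame(rows, columns=["chrom", "bin_index", "start", "end"])
    for cat in CATEGORIES:
        bins[cat] = 0
    return bins


def _anchor_position(t, anchor: str) -> int:
    if anchor == "span_start":
        return t.span_start
    if anchor == "midpoint":
        return (t.span_start + t.span_end) // 2
    raise ValueError(f"unknown anchor {anchor!r}; choose from {ANCHORS}")


def assign_counts(
    bins: pd.DataFrame,
    ts: TranscriptSet,
    calls: pd.DataFrame,
    anchor: str = "span_start",
) -> pd.DataFrame:
    """Fill bin counts from salt calls.

    Categories: short_SA when short_label != none, long_SA when
    long_label != none (a transcript may count in both), SNA when is_SA
    is false.
    """
    bins = bins.copy()
    # window width is constant per chromosome; recover it from bin 1
    widths = bins[bins["bin_index"] == 1].set_index("chrom")
    window = {c: int(r["end"] - r["start"] + 1) for c, r in widths.iterrows()}
    max_bin = bins.groupby("chrom")["bin_index"].max().to_dict()
    index = {(c, b): i for i, (c, b) in enumerate(zip(bins["chrom"], bins["bin_index"]))}
    counts = bins[list(CATEGORIES)].to_numpy().copy()
    for tid in calls.index:
        t = ts[tid]
        if t.chrom not in window:
            raise ValueError(f"transcript {tid} on chrom {t.chrom!r} absent from bins")
        pos = _anchor_position(t, anchor)
        b = min((pos - 1) // window[t.chrom] + 1, max_bin[t.chrom])
        i = index[(t.chrom, b)]
        row = calls.loc[tid]
        if row["short_label"] != "none":
            counts[i, 0] += 1
        if row["long_label"] != "none":
            counts[i, 1] += 1
        if not row["is_SA"]:
            counts[i, 2] += 1
    bins[list(CATEGORIES)] = counts
    return bins


def per_chromosome_totals(bins: pd.DataFrame) -> pd.DataFrame:
    """Column sums of bin counts per chromosome."""
    return bins.groupby("chrom", sort=False)[list(CATEGORIES)].sum().reset_index()
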