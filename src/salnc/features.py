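"""Sequence features and tissue-specificity of lncRNAs.

The tissue-specific score of a transcript is the maximum, over tissues, of
its fractional expression (mean FPKM in one tissue divided by the sum of
mean FPKMs across all tissues).  A transcript whose leaf fraction strictly
exceeds the cutoff (default 0.6) is leaf-specific; for any cutoff above
0.5 that fraction is automatically the maximum, so the call is equivalent
to "tissue-specific score > cutoff attained in leaf".
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptSet
from .expression import ExpressionResult, SampleSheet

logger = logging.getLogger(__name__)

GROUPS = ("short_SA", "long_SA", "SNA")
SCALAR_FEATURES = ("transcript_length", "genomic_span", "exon_count")
POOLED_FEATURES = ("exon_size", "intron_size")


def compute_features(ts: TranscriptSet) -> pd.DataFrame:
    """Per-transcript structural features.

    Introns are the gaps between consecutive sorted exons; exon/intron
    size collections are kept as comma-joined strings for TSV round-trip
    alongside scalar summaries.
    """
    rows = []
    for t in ts:
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "transcript_length": t.transcript_length,
                "genomic_span": t.genomic_span,
                "exon_count": t.exon_count,
                "exon_sizes": ",".join(map(str, t.exon_sizes)),
                "intron_sizes": ",".join(map(str, t.intron_sizes)),
            }
        )
    cols = [
        "transcript_id", "transcript_length", "genomic_span",
        "exon_count", "exon_sizes", "intron_sizes",
    ]
    return pd.DataFrame(rows, columns=cols).set_index("transcript_id")


def _group_members(calls: pd.DataFrame) -> dict[str, pd.Index]:
    return {
        "short_SA": calls.index[calls["short_label"] != "none"],
        "long_SA": calls.index[calls["long_label"] != "none"],
        "SNA": calls.index[~calls["is_SA"]],
    }


def _pooled_sizes(features: pd.DataFrame, ids: pd.Index, column: str) -> np.ndarray:
    vals: list[int] = []
    for s in features.loc[ids, column]:
        if s:
            vals.extend(int(v) for v in s.split(","))
    return np.asarray(vals, dtype=float)


def ecdf_table(values: np.ndarray) -> pd.DataFrame:
    """Empirical CDF evaluated at the sorted sample points."""
    x = np.sort(np.asarray(values, dtype=float))
    return pd.DataFrame({"value": x, "ecdf": np.arange(1, x.size + 1) / x.size})


def compare_groups(
    features: pd.DataFrame, calls: pd.DataFrame
) -> tuple[pd.DataFrame, dict[tuple[str, str], pd.DataFrame], pd.DataFrame]:
    """Summaries, ECDF tables and pairwise KS statistics per feature and group.

    Exon and intron sizes are pooled over a group's transcripts; the KS
    statistic is descriptive (no test is attached to the comparison).
    """
    members = _group_members(calls)
    data: dict[tuple[str, str], np.ndarray] = {}
    for group, ids in members.items():
        if len(ids) == 0:
            logger.warning("compare_groups: group %s empty, omitted", group)
            continue
        for feat in SCALAR_FEATURES:
            data[(group, feat)] = features.loc[ids, feat].to_numpy(float)
        for feat, col in zip(POOLED_FEATURES, ("exon_sizes", "intron_sizes")):
            data[(group, feat)] = _pooled_sizes(features, ids, col)

    summary_rows = []
    ecdfs: dict[tuple[str, str], pd.DataFrame] = {}
    for (group, feat), vals in data.items():
        if vals.size == 0:
            continue
        summary_rows.append(
            {
                "group": group,
                "feature": feat,
                "n": vals.size,
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
            }
        )
        ecdfs[(group, feat)] = ecdf_table(vals)

    ks_rows = []
    present = [g for g in GROUPS if any(k[0] == g for k in data)]
    for feat in SCALAR_FEATURES + POOLED_FEATURES:
        for i, g1 in enumerate(present):
            for g2 in present[i + 1:]:
                a, b = data.get((g1, feat)), data.get((g2, feat))
                if a is None or b is None or a.size == 0 or b.size == 0:
                    continue
                ks = stats.ks_2samp(a, b)
                ks_rows.append(
                    {"feature": feat, "group1": g1, "group2": g2,
                     "ks_statistic": float(ks.statistic)}
                )
    return pd.DataFrame(summary_rows), ecdfs, pd.DataFrame(ks_rows)


def tissue_profiles(
    expr: ExpressionResult,
    sheet: SampleSheet,
    cutoff: float = 0.6,
    target_tissue: str = "leaf",
) -> pd.DataFrame:
    """Fractional expression across tissues, specificity score and target call.

    Per-tissue expression is the mean FPKM over that tissue's samples.
    Transcripts with zero total expression get NA fractions and score and
    are never called specific.
    """
    tissues = sheet.tissues_present
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues with samples")
    if target_tissue not in tissues:
        raise ValueError(f"target tissue {target_tissue!r} absent from sample sheet")
    means = pd.DataFrame(
        {t: expr.fpkm[sheet.samples_for(tissue=t)].mean(axis=1) for t in tissues}
    )
    total = means.sum(axis=1)
    fractions = means.div(total, axis=0)
    fractions[total == 0] = np.nan
    defined = total > 0
    score = fractions.max(axis=1)
    argmax = pd.Series(pd.NA, index=fractions.index, dtype=object)
    if defined.any():
        argmax[defined] = fractions[defined].idxmax(axis=1)
    specific = (fractions[target_tissue] > cutoff).fillna(False)
    out = fractions.add_prefix("frac_")
    out["score"] = score
    out["argmax_tissue"] = argmax
    out[f"{target_tissue}_specific"] = specific
    return out


def specificity_sweep(
    profiles: pd.DataFrame,
    cutoffs,
    groups: dict[str, pd.Index] | None = None,
) -> pd.DataFrame:
    """Percentage of transcripts with score strictly above each cutoff.

    ``groups`` maps column name -> transcript ids; default is one column
    over all profiled transcripts.  Transcripts with undefined (NA) score
    are excluded from denominators.
    """
    if groups is None:
        groups = {"all": profiles.index}
    rows = []
    for cutoff in cutoffs:
        row = {"cutoff": float(cutoff)}
        for name, ids in groups.items():
            scores = profiles.loc[profiles.index.intersection(ids), "score"].dropna()
            row[name] = 100.0 * float((scores > cutoff).mean()) if len(scores) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("cutoff")
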