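"""Count input, TMM normalization, FPKM and log2 fold changes.

TMM (trimmed mean of M-values) computes per-sample scaling factors from
doubly trimmed, precision-weighted log ratios against a reference sample;
here it follows the canonical algorithm of the edgeR implementation so the
factors agree with that reference to numerical precision:

* reference column = the one whose 0.75 count quantile divided by library
  size is closest to the mean of that statistic across samples;
* for sample *s* vs reference *r*, over rows with nonzero counts in both,
  M = log2((x_s/N_s)/(x_r/N_r)), A = (log2(x_s/N_s)+log2(x_r/N_r))/2 and
  the asymptotic variance v = (N_s-x_s)/(N_s x_s) + (N_r-x_r)/(N_r x_r);
* rows in the top/bottom 30% of M or 5% of A are trimmed (rank-based,
  average ties) and the factor is 2**(sum(M/v)/sum(1/v)) over the rest;
* factors are finally divided by their geometric mean so they multiply to 1.

FPKM uses the TMM-effective library size (column sum times factor), so
normalization composes with the count-to-FPKM transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .annotation import TranscriptSet

logger = logging.getLogger(__name__)

CONDITIONS = ("CK", "24h", "48h", "14d", "28d")
TISSUES = ("leaf", "flower", "root", "seed", "stem")
NONE_LABEL = "none"

#: fold-change table column per treatment condition
FC_COLUMNS = {"24h": "fc24", "48h": "fc48", "14d": "fc14", "28d": "fc28"}


@dataclass
class SampleSheet:
    """Sample metadata: condition and/or tissue plus replicate number."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "condition", "tissue", "replicate"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        f = self.frame
        if f["sample_id"].duplicated().any():
            dups = f.loc[f["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        bad_cond = ~f["condition"].isin(CONDITIONS + (NONE_LABEL,))
        if bad_cond.any():
            raise ValueError(
                f"unknown condition labels: {sorted(f.loc[bad_cond, 'condition'].unique())}"
            )
        bad_tissue = ~f["tissue"].isin(TISSUES + (NONE_LABEL,))
        if bad_tissue.any():
            raise ValueError(
                f"unknown tissue labels: {sorted(f.loc[bad_tissue, 'tissue'].unique())}"
            )
        unassigned = (f["condition"] == NONE_LABEL) & (f["tissue"] == NONE_LABEL)
        if unassigned.any():
            raise ValueError(
                "samples with neither condition nor tissue: "
                f"{f.loc[unassigned, 'sample_id'].tolist()}"
            )
        if (f["replicate"].astype(int) < 1).any():
            raise ValueError("replicate numbers must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def samples_for(self, condition: str | None = None, tissue: str | None = None) -> list[str]:
        f = self.frame
        keep = pd.Series(True, index=f.index)
        if condition is not None:
            if condition not in CONDITIONS:
                raise ValueError(f"unknown condition {condition!r}")
            keep &= f["condition"] == condition
        if tissue is not None:
            if tissue not in TISSUES:
                raise ValueError(f"unknown tissue {tissue!r}")
            keep &= f["tissue"] == tissue
        return f.loc[keep, "sample_id"].tolist()

    @property
    def tissues_present(self) -> list[str]:
        present = set(self.frame["tissue"]) - {NONE_LABEL}
        return [t for t in TISSUES if t in present]

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))

    def write_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path, sheet: SampleSheet) -> pd.DataFrame:
    """Read a transcripts x samples TSV of non-negative integer counts."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = [s for s in df.columns if s not in set(sheet.sample_ids)]
    if unknown:
        raise ValueError(f"samples absent from sample sheet: {unknown}")
    if df.index.duplicated().any():
        raise ValueError("duplicate transcript ids in counts")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        if not np.allclose(values, np.round(values), atol=0, rtol=0):
            raise ValueError("counts must be integers")
        df = df.round().astype(np.int64)
    if (df.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return df.astype(np.int64)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    both = (obs > 0) & (ref > 0)
    o = obs[both].astype(float)
    r = ref[both].astype(float)
    log_r = np.log2((o / lib_obs) / (r / lib_ref))
    abs_e = (np.log2(o / lib_obs) + np.log2(r / lib_ref)) / 2.0
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    keep = (rank_m >= lo_l) & (rank_m <= hi_l) & (rank_a >= lo_s) & (rank_a <= hi_s)
    if keep.sum() < 2:
        logger.warning("TMM: fewer than 2 untrimmed rows; falling back to factor 1")
        return 1.0
    f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> pd.Series:
    """TMM normalization factors, geometric-mean-centered to multiply to 1."""
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = x.sum(axis=0)
    if (lib <= 0).any():
        zero_cols = [c for c, s in zip(counts.columns, lib) if s <= 0]
        raise ValueError(f"all-zero count columns: {zero_cols}")
    # reference: 0.75 quantile of counts over library size closest to the mean
    f75 = np.quantile(x, 0.75, axis=0) / lib
    if np.median(f75) < 1e-20:
        ref_idx = int(np.argmax(np.sqrt(x).sum(axis=0)))
    else:
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(x[:, i], x[:, ref_idx], lib[i], lib[ref_idx], trim_m, trim_a)
            for i in range(x.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


@dataclass
class ExpressionResult:
    """TMM factors, effective library sizes and the FPKM matrix."""

    fpkm: pd.DataFrame
    tmm_factor: pd.Series
    effective_lib_size: pd.Series


def fpkm(
    counts: pd.DataFrame,
    factors: pd.Series,
    ts: TranscriptSet,
) -> ExpressionResult:
    """Fragments per kilobase of transcript per million mapped fragments.

    fpkm[i, s] = counts[i, s] * 1e9 / (effective_lib_size[s] * length[i]),
    with effective_lib_size[s] = column_sum[s] * tmm_factor[s].
    """
    missing = [i for i in counts.index if i not in ts]
    if missing:
        raise ValueError(f"transcripts missing from annotation: {missing[:5]}")
    lengths = np.array([ts[i].transcript_length for i in counts.index], dtype=float)
    factors = factors.reindex(counts.columns)
    eff = counts.sum(axis=0).astype(float) * factors
    values = counts.to_numpy(dtype=float) * 1e9 / (
        eff.to_numpy()[None, :] * lengths[:, None]
    )
    return ExpressionResult(
        fpkm=pd.DataFrame(values, index=counts.index, columns=counts.columns),
        tmm_factor=factors,
        effective_lib_size=eff.rename("effective_lib_size"),
    )


def log2fc(
    expr: ExpressionResult,
    sheet: SampleSheet,
    treatment: str,
    control: str = "CK",
    pseudocount: float = 1.0,
    drop_unexpressed: bool = False,
) -> pd.Series:
    """Per-transcript log2 of (mean treatment FPKM + c) / (mean control FPKM + c).

    Transcripts with zero FPKM in every replicate of both groups get 0.0,
    or NA when ``drop_unexpressed`` is set; such transcripts can never
    satisfy a salt-association rule either way.
    """
    t_samples = sheet.samples_for(condition=treatment)
    c_samples = sheet.samples_for(condition=control)
    if not t_samples or not c_samples:
        raise ValueError(
            f"need >=1 sample per condition ({treatment}: {len(t_samples)}, "
            f"{control}: {len(c_samples)})"
        )
    t_mean = expr.fpkm[t_samples].mean(axis=1)
    c_mean = expr.fpkm[c_samples].mean(axis=1)
    fc = np.log2((t_mean + pseudocount) / (c_mean + pseudocount))
    if drop_unexpressed:
        silent = (expr.fpkm[t_samples + c_samples] == 0).all(axis=1)
        fc[silent] = np.nan
    return fc.rename(f"log2fc_{treatment}_vs_{control}")


def fold_change_table(
    expr: ExpressionResult,
    sheet: SampleSheet,
    control: str = "CK",
    pseudocount: float = 1.0,
    drop_unexpressed: bool = False,
) -> pd.DataFrame:
    """log2 fold changes of every treatment condition vs control.

    Columns fc24, fc48 (short-term regime) and fc14, fc28 (long-term
    regime), indexed by transcript.
    """
    cols = {}
    for condition, column in FC_COLUMNS.items():
        if sheet.samples_for(condition=condition):
            cols[column] = log2fc(
                expr, sheet, condition, control, pseudocount, drop_unexpressed
            )
    if not cols:
        raise ValueError("no treatment conditions present in sample sheet")
    return pd.DataFrame(cols)
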