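"""Compound fold-change rules for salt-associated lncRNA calls.

Within each treatment regime (short-term: 24 h / 48 h vs control;
long-term: 14 d / 28 d vs control) a transcript is called *up* when both
log2 fold changes are positive and at least one exceeds the strong
threshold (printed rule: > 1 in one time point and > 0 in the other),
and *down* symmetrically with negated thresholds.  A transcript carrying
a non-none label in either regime is salt-associated (SA); the rest are
salt-non-associated (SNA).  All inequalities are strict: a fold change
equal to a threshold never qualifies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LABELS = ("up", "down", "none")

#: regime pairs for cross-regime fold-change correlation (y, x)
CROSSTALK_PAIRS = (
    ("fc14", "fc24"),
    ("fc28", "fc24"),
    ("fc14", "fc48"),
    ("fc28", "fc48"),
)


@dataclass(frozen=True)
class ClassificationConfig:
    strong_threshold: float = 1.0
    weak_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not self.strong_threshold > self.weak_threshold >= 0:
            raise ValueError(
                "require strong_threshold > weak_threshold >= 0, got "
                f"{self.strong_threshold} / {self.weak_threshold}"
            )


DEFAULT_CONFIG = ClassificationConfig()


def _label_pair(a: float, b: float, cfg: ClassificationConfig) -> str:
    """Shared kernel for both regimes.

    The printed disjunctive rule (a > 1 & b > 0) | (a > 0 & b > 1) is
    algebraically the compact form a > 0 & b > 0 & (a > 1 | b > 1); the
    same holds for the long-term regime's wording, so one kernel serves
    both (property-tested).
    """
    if math.isnan(a) or math.isnan(b):
        return "none"
    s, w = cfg.strong_threshold, cfg.weak_threshold
    if a > w and b > w and (a > s or b > s):
        return "up"
    if a < -w and b < -w and (a < -s or b < -s):
        return "down"
    return "none"


def classify_short(
    fc24: float, fc48: float, cfg: ClassificationConfig = DEFAULT_CONFIG
) -> str:
    """Label from the 24 h and 48 h vs control fold changes."""
    return _label_pair(fc24, fc48, cfg)


def classify_long(
    fc14: float, fc28: float, cfg: ClassificationConfig = DEFAULT_CONFIG
) -> str:
    """Label from the 14 d and 28 d vs control fold changes."""
    return _label_pair(fc14, fc28, cfg)


def _label_vector(a: np.ndarray, b: np.ndarray, cfg: ClassificationConfig) -> np.ndarray:
    s, w = cfg.strong_threshold, cfg.weak_threshold
    up = (a > w) & (b > w) & ((a > s) | (b > s))
    down = (a < -w) & (b < -w) & ((a < -s) | (b < -s))
    out = np.full(a.shape, "none", dtype=object)
    out[up] = "up"
    out[down] = "down"
    return out


def call_all(
    fct: pd.DataFrame, cfg: ClassificationConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """One salt-association call per lncRNA.

    ``fct`` carries columns fc24, fc48, fc14, fc28 indexed by transcript.
    Returns those columns plus short_label, long_label and is_SA.
    NaN in either member of a regime pair yields "none" for that regime.
    """
    if fct.index.duplicated().any():
        dups = fct.index[fct.index.duplicated()].tolist()
        raise ValueError(f"duplicate transcript ids: {dups[:5]}")
    calls = fct.copy()
    for col in ("fc24", "fc48", "fc14", "fc28"):
        if col not in calls:
            calls[col] = np.nan
    calls["short_label"] = _label_vector(
        calls["fc24"].to_numpy(float), calls["fc48"].to_numpy(float), cfg
    )
    calls["long_label"] = _label_vector(
        calls["fc14"].to_numpy(float), calls["fc28"].to_numpy(float), cfg
    )
    calls["is_SA"] = (calls["short_label"] != "none") | (calls["long_label"] != "none")
    logger.info("salt calls: %s", summarize_calls(calls))
    return calls


def summarize_calls(calls: pd.DataFrame) -> dict[str, int]:
    return {
        "short_up": int((calls["short_label"] == "up").sum()),
        "short_down": int((calls["short_label"] == "down").sum()),
        "long_up": int((calls["long_label"] == "up").sum()),
        "long_down": int((calls["long_label"] == "down").sum()),
        "SA": int(calls["is_SA"].sum()),
        "SNA": int((~calls["is_SA"]).sum()),
    }


@dataclass
class CrosstalkResult:
    """Cross-regime overlap sets and fold-change correlations."""

    overlap_up: frozenset
    overlap_down: frozenset
    fc_correlations: pd.DataFrame  # columns pair, n, r, p

    @property
    def overlap_up_count(self) -> int:
        return len(self.overlap_up)

    @property
    def overlap_down_count(self) -> int:
        return len(self.overlap_down)


def crosstalk(calls: pd.DataFrame, fct: pd.DataFrame) -> CrosstalkResult:
    """Short/long overlap and Pearson correlation of fold changes.

    Correlations are computed over all lncRNAs (SA and SNA alike) with
    both fold changes defined, for each of the four regime pairs.
    """
    shared = calls.index.intersection(fct.index)
    overlap_up = frozenset(
        calls.index[(calls["short_label"] == "up") & (calls["long_label"] == "up")]
    )
    overlap_down = frozenset(
        calls.index[(calls["short_label"] == "down") & (calls["long_label"] == "down")]
    )
    rows = []
    for y, x in CROSSTALK_PAIRS:
        xv = fct.loc[shared, x].to_numpy(float)
        yv = fct.loc[shared, y].to_numpy(float)
        ok = np.isfinite(xv) & np.isfinite(yv)
        n = int(ok.sum())
        if n < 3:
            logger.warning("crosstalk %s~%s: only %d finite pairs, r set to NA", y, x, n)
            r = p = np.nan
        else:
            r, p = stats.pearsonr(xv[ok], yv[ok])
        rows.append({"pair": f"{y}_vs_{x}", "n": n, "r": r, "p": p})
    return CrosstalkResult(overlap_up, overlap_down, pd.DataFrame(rows))
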