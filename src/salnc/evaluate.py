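"""Scoring of pipeline output against a synthetic truth ledger."""

from __future__ import annotations

import pandas as pd


def score_salt_calls(calls: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Direction-aware sensitivity/precision per regime, plus SA false-positive rate.

    Sensitivity: fraction of planted (truth-labeled) transcripts whose
    called label matches the planted direction.  Precision: fraction of
    called transcripts whose planted direction matches.  sa_fpr: fraction
    of truth-unlabeled transcripts called salt-associated in either regime.
    """
    shared = calls.index.intersection(truth.index)
    calls = calls.loc[shared]
    truth = truth.loc[shared]
    out: dict[str, float] = {}
    for regime, call_col, truth_col in (
        ("short", "short_label", "true_short"),
        ("long", "long_label", "true_long"),
    ):
        called = calls[call_col]
        planted = truth[truth_col]
        pos = planted != "none"
        called_pos = called != "none"
        out[f"sensitivity_{regime}"] = (
            float((called[pos] == planted[pos]).mean()) if pos.any() else float("nan")
        )
        out[f"precision_{regime}"] = (
            float((planted[called_pos] == called[called_pos]).mean())
            if called_pos.any()
            else float("nan")
        )
    null = (truth["true_short"] == "none") & (truth["true_long"] == "none")
    out["sa_fpr"] = float(calls.loc[null, "is_SA"].mean()) if null.any() else float("nan")
    return out


def score_leaf_calls(
    profiles: pd.DataFrame, truth: pd.DataFrame, target_tissue: str = "leaf"
) -> dict[str, float]:
    """Sensitivity on planted leaf-specific transcripts and null call rate."""
    col = f"{target_tissue}_specific"
    shared = profiles.index.intersection(truth.index)
    called = profiles.loc[shared, col].astype(bool)
    planted = truth.loc[shared, "true_leaf_specific"].astype(bool)
    out = {
        "leaf_sensitivity": float(called[planted].mean()) if planted.any() else float("nan"),
        "leaf_null_rate": float(called[~planted].mean()) if (~planted).any() else float("nan"),
    }
    return out
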