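"""Guilt-by-association functional annotation of lncRNAs.

A lncRNA inherits the functions enriched among its co-expressed coding
partners: all lncRNA x mRNA Pearson correlations are computed across the
shared samples, Benjamini-Hochberg adjusted jointly, and pairs with
r > 0.5 and adjusted p < 0.05 become co-expression edges.  The mRNA sets
reached through those edges are then tested term-by-term with the
hypergeometric upper tail against the annotated background universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GROUP_NAMES = ("short_up", "short_down", "long_up", "long_down", "both_up", "both_down")


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson r with two-sided p (t-distribution, n-2 df).

    Returns (nan, nan) when either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-d vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("pearson_with_p: zero-variance input, returning NA")
        return (np.nan, np.nan)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def coexpression_edges(
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    r_cutoff: float = 0.5,
    fdr_cutoff: float = 0.05,
    samples: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Retained lncRNA-mRNA co-expression edges.

    Every pair is tested; BH adjustment is applied jointly over all
    tested pairs; an edge is retained iff r > r_cutoff (one-sided
    positive, as anti-correlated partners are not co-expressed) and
    adjusted p < fdr_cutoff.  Zero-variance rows are skipped.
    """
    if samples is None:
        samples = [s for s in lnc_expr.columns if s in set(mrna_expr.columns)]
    samples = list(samples)
    n = len(samples)
    if n < 3:
        raise ValueError(f"need >= 3 shared samples, got {n}")
    L = lnc_expr[samples].to_numpy(float)
    M = mrna_expr[samples].to_numpy(float)

    def _standardize(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centered = a - a.mean(axis=1, keepdims=True)
        norm = np.sqrt((centered ** 2).sum(axis=1, keepdims=True))
        ok = norm[:, 0] > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(norm > 0, centered / norm, np.nan)
        return z, ok

    zl, ok_l = _standardize(L)
    zm, ok_m = _standardize(M)
    if (~ok_l).any() or (~ok_m).any():
        logger.warning(
            "coexpression_edges: skipping %d lncRNA and %d mRNA zero-variance rows",
            int((~ok_l).sum()), int((~ok_m).sum()),
        )
    r = np.clip(zl[ok_l] @ zm[ok_m].T, -1.0, 1.0)
    # two-sided p via the t transform; |r| = 1 maps to p = 0
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0] = 0.0
    lnc_ids = np.asarray(lnc_expr.index)[ok_l]
    mrna_ids = np.asarray(mrna_expr.index)[ok_m]
    edges = pd.DataFrame(
        {
            "lnc_id": np.repeat(lnc_ids, len(mrna_ids)),
            "mrna_id": np.tile(mrna_ids, len(lnc_ids)),
            "r": r.ravel(),
            "p": p.ravel(),
        }
    )
    edges["p_adj"] = bh_adjust(edges["p"].to_numpy())
    retained = edges[(edges["r"] > r_cutoff) & (edges["p_adj"] < fdr_cutoff)]
    logger.info(
        "coexpression: %d/%d pairs retained (r > %g, BH p < %g)",
        len(retained), len(edges), r_cutoff, fdr_cutoff,
    )
    return retained.reset_index(drop=True)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= min(K, n) and k <= n <= N and K <= N):
        raise ValueError(f"infeasible hypergeometric configuration k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class TermMap:
    """Flat mRNA -> term annotation with term names."""

    mrna_to_terms: dict[str, frozenset[str]]
    names: dict[str, str] = field(default_factory=dict)
    namespace: str = "GO-BP"

    def __post_init__(self) -> None:
        self.mrna_to_terms = {
            m: frozenset(t) for m, t in self.mrna_to_terms.items()
        }

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.mrna_to_terms)

    def term_to_mrnas(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for m, terms in self.mrna_to_terms.items():
            for t in terms:
                out.setdefault(t, set()).add(m)
        return {t: frozenset(ms) for t, ms in out.items()}

    def name_of(self, term_id: str) -> str:
        return self.names.get(term_id, term_id)

    @classmethod
    def read_tsv(
        cls, path: str | Path, names_path: str | Path | None = None
    ) -> "TermMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"mrna_id", "term_id"} <= set(df.columns):
            raise ValueError("term map needs columns mrna_id, term_id")
        mapping: dict[str, set[str]] = {}
        for m, t in zip(df["mrna_id"], df["term_id"]):
            mapping.setdefault(m, set()).add(t)
        names: dict[str, str] = {}
        namespace = "GO-BP"
        if names_path is not None:
            nd = pd.read_csv(names_path, sep="\t", dtype=str)
            names = dict(zip(nd["term_id"], nd["name"]))
            if "namespace" in nd.columns and len(nd):
                namespace = nd["namespace"].iloc[0]
        return cls({m: frozenset(t) for m, t in mapping.items()}, names, namespace)

    def write_tsv(self, path: str | Path, names_path: str | Path | None = None) -> None:
        rows = [
            {"mrna_id": m, "term_id": t}
            for m in sorted(self.mrna_to_terms)
            for t in sorted(self.mrna_to_terms[m])
        ]
        pd.DataFrame(rows, columns=["mrna_id", "term_id"]).to_csv(
            path, sep="\t", index=False
        )
        if names_path is not None:
            pd.DataFrame(
                {
                    "term_id": sorted(self.names),
                    "name": [self.names[t] for t in sorted(self.names)],
                    "namespace": self.namespace,
                }
            ).to_csv(names_path, sep="\t", index=False)


def enrich(
    query_mrnas: Iterable[str],
    tmap: TermMap,
    background: Iterable[str] | None = None,
    top_n: int = 20,
    min_background_hits: int = 2,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of a query mRNA set.

    The background defaults to all annotated mRNAs in the term map (the
    hypergeometric model needs a closed annotated universe).  A term is
    tested only when it hits the query at least once and annotates at
    least ``min_background_hits`` background mRNAs.  Rows are ranked by
    ascending p, ties broken by descending k then term_id; the leading
    ``top_n`` rows are flagged.
    """
    columns = ["term_id", "term_name", "k", "n", "K", "N", "p", "p_adj", "rank", "top"]
    background = frozenset(tmap.universe if background is None else background)
    query = frozenset(query_mrnas) & background
    if not query:
        logger.warning("enrich: empty (or unannotated) query")
        return pd.DataFrame(columns=columns)
    N, n = len(background), len(query)
    rows = []
    for term, members in tmap.term_to_mrnas().items():
        members &= background
        K = len(members)
        k = len(members & query)
        if k == 0 or K < min_background_hits:
            continue
        rows.append(
            {
                "term_id": term,
                "term_name": tmap.name_of(term),
                "k": k, "n": n, "K": K, "N": N,
                "p": hypergeom_upper(k, K, n, N),
            }
        )
    if not rows:
        return pd.DataFrame(columns=columns)
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df = df.sort_values(
        ["p", "k", "term_id"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["top"] = df["rank"] <= top_n
    return df[columns]


def _call_groups(calls: pd.DataFrame) -> dict[str, pd.Index]:
    short_up = calls["short_label"] == "up"
    short_down = calls["short_label"] == "down"
    long_up = calls["long_label"] == "up"
    long_down = calls["long_label"] == "down"
    return {
        "short_up": calls.index[short_up],
        "short_down": calls.index[short_down],
        "long_up": calls.index[long_up],
        "long_down": calls.index[long_down],
        "both_up": calls.index[short_up & long_up],
        "both_down": calls.index[short_down & long_down],
    }


def annotate_lncrna_groups(
    edges: pd.DataFrame,
    calls: pd.DataFrame,
    tmap: TermMap,
    mode: str = "group",
    top_n: int = 20,
    fdr_cutoff: float = 0.05,
):
    """Enrichment per salt-call group, pooled or per-lncRNA.

    mode="group": the query for each group (short_up, short_down,
    long_up, long_down, both_up, both_down) is the union of co-expressed
    mRNAs over the group's lncRNAs; returns {group: enrichment frame}.

    mode="per_lncrna": each lncRNA is enriched on its own partner set;
    terms are then ranked by how many lncRNAs carry them among their
    significant results (adjusted p < fdr_cutoff), ties broken by
    term_id.  Returns (per-lncRNA results, ranking frame, bipartite
    lncRNA-term edge list in SIF-style 3 columns).
    """
    partners = {
        lnc: frozenset(sub["mrna_id"])
        for lnc, sub in edges.groupby("lnc_id", sort=False)
    }
    if mode == "group":
        results: dict[str, pd.DataFrame] = {}
        for group, ids in _call_groups(calls).items():
            query: set[str] = set()
            for lnc in ids:
                query |= partners.get(lnc, frozenset())
            if not query:
                logger.warning("annotate_lncrna_groups: group %s has no edges, skipped", group)
                continue
            results[group] = enrich(query, tmap, top_n=top_n)
        return results
    if mode == "per_lncrna":
        per_lnc: dict[str, pd.DataFrame] = {}
        term_counts: dict[str, int] = {}
        sif_rows = []
        for lnc in calls.index:
            query = partners.get(lnc)
            if not query:
                continue
            res = enrich(query, tmap, top_n=top_n)
            per_lnc[lnc] = res
            for term in res.loc[res["p_adj"] < fdr_cutoff, "term_id"]:
                term_counts[term] = term_counts.get(term, 0) + 1
                sif_rows.append({"lnc_id": lnc, "interaction": "annotated_with", "term_id": term})
        ranking = pd.DataFrame(
            [
                {"term_id": t, "term_name": tmap.name_of(t), "n_lncrnas": c}
                for t, c in term_counts.items()
            ],
            columns=["term_id", "term_name", "n_lncrnas"],
        )
        if len(ranking):
            ranking = ranking.sort_values(
                ["n_lncrnas", "term_id"], ascending=[False, True]
            ).reset_index(drop=True)
            ranking["rank"] = np.arange(1, len(ranking) + 1)
        else:
            ranking["rank"] = pd.Series(dtype=int)
        sif = pd.DataFrame(sif_rows, columns=["lnc_id", "interaction", "term_id"])
        return per_lnc, ranking, sif
    raise ValueError(f"unknown mode {mode!r}; use 'group' or 'per_lncrna'")
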