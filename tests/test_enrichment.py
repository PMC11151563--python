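from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from salnc.enrichment import (
    TermMap,
    annotate_lncrna_groups,
    bh_adjust,
    coexpression_edges,
    enrich,
    hypergeom_upper,
    pearson_with_p,
)


def bh_step_up(p):
    """Direct step-up formula: independent oracle for bh_adjust."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, m * p[idx] / rank)
        adj[idx] = running
    return adj


def hypergeom_enumerate(k, K, n, N):
    """Exact upper tail by summing the exact pmf with rational arithmetic."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


class TestPearson:
    def test_identity(self):
        x = [1.0, 2.0, 5.0, 7.0]
        r, p = pearson_with_p(x, x)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors(self):
        x = [-3.0, -1.0, 1.0, 3.0]
        y = [1.0, -1.0, -1.0, 1.0]  # orthogonal to centered x
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_textbook_formula_on_fixed_vectors(self):
        from scipy.stats import t as t_dist
        x = np.array([2.0, 4.0, 5.0, 4.0, 6.0, 9.0])
        y = np.array([1.0, 3.0, 2.0, 5.0, 5.0, 8.0])
        n = len(x)
        cx, cy = x - x.mean(), y - y.mean()
        r_ref = (cx @ cy) / np.sqrt((cx @ cx) * (cy @ cy))
        t = r_ref * np.sqrt((n - 2) / (1 - r_ref ** 2))
        p_ref = 2 * t_dist.sf(abs(t), df=n - 2)
        r, p = pearson_with_p(x, y)
        assert r == pytest.approx(r_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_zero_variance_gives_na(self):
        r, p = pearson_with_p([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(r) and np.isnan(p)

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_p([1.0, 2.0], [3.0, 4.0])


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_all_equal_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 7), [0.2] * 7)

    def test_matches_step_up_oracle(self):
        rng = np.random.default_rng(19)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 150)))
            np.testing.assert_allclose(bh_adjust(p), bh_step_up(p), atol=1e-12)

    def test_permutation_equivariant_and_bounded(self):
        rng = np.random.default_rng(20)
        p = rng.uniform(size=40)
        perm = rng.permutation(40)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]), atol=1e-12)
        assert (bh_adjust(p) <= 1.0).all()
        assert (bh_adjust(p) >= p).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestHypergeom:
    def test_worked_case(self):
        assert hypergeom_upper(2, 4, 3, 10) == pytest.approx(1 / 3, abs=1e-12)

    def test_k_zero_is_one(self):
        assert hypergeom_upper(0, 4, 3, 10) == 1.0

    def test_forced_outcome(self):
        assert hypergeom_upper(3, 3, 3, 3) == pytest.approx(1.0)

    def test_matches_enumeration_on_sample(self):
        rng = np.random.default_rng(29)
        for _ in range(200):
            N = int(rng.integers(1, 13))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom_upper(k, K, n, N) == pytest.approx(
                hypergeom_enumerate(k, K, n, N), abs=1e-12
            )

    def test_non_increasing_in_k(self):
        values = [hypergeom_upper(k, 6, 5, 20) for k in range(6)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_infeasible_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper(5, 4, 3, 10)
        with pytest.raises(ValueError):
            hypergeom_upper(1, 11, 3, 10)


def _expr_frame(rows, prefix):
    return pd.DataFrame(
        rows,
        index=[f"{prefix}{i}" for i in range(len(rows))],
        columns=[f"s{j}" for j in range(len(rows[0]))],
    ).astype(float)


class TestCoexpression:
    def test_identical_profile_retained(self):
        rng = np.random.default_rng(41)
        v = rng.gamma(2, 5, size=10)
        lnc = _expr_frame([v], "L")
        mrna = _expr_frame([v, rng.gamma(2, 5, size=10)], "M")
        edges = coexpression_edges(lnc, mrna)
        assert ("L0", "M0") in set(zip(edges["lnc_id"], edges["mrna_id"]))

    def test_anticorrelated_not_retained(self):
        v = np.arange(10, dtype=float)
        edges = coexpression_edges(_expr_frame([v], "L"), _expr_frame([-v], "M"))
        assert len(edges) == 0

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(43)
        shared = rng.normal(size=12)
        lnc_rows = [shared + rng.normal(0, 0.3, 12) for _ in range(3)]
        mrna_rows = [shared + rng.normal(0, 0.3, 12) for _ in range(2)] + [
            rng.normal(size=12) for _ in range(3)
        ]
        lnc = _expr_frame(lnc_rows, "L")
        mrna = _expr_frame(mrna_rows, "M")
        edges = coexpression_edges(lnc, mrna, r_cutoff=0.5, fdr_cutoff=0.05)

        rows = []
        for li in lnc.index:
            for mi in mrna.index:
                r, p = pearson_with_p(lnc.loc[li], mrna.loc[mi])
                rows.append((li, mi, r, p))
        p_adj = bh_step_up([r[3] for r in rows])
        expected = {
            (li, mi)
            for (li, mi, r, _), q in zip(rows, p_adj)
            if r > 0.5 and q < 0.05
        }
        assert set(zip(edges["lnc_id"], edges["mrna_id"])) == expected
        for _, e in edges.iterrows():
            r_ref = next(r for li, mi, r, _ in rows if (li, mi) == (e["lnc_id"], e["mrna_id"]))
            assert e["r"] == pytest.approx(r_ref, abs=1e-10)

    def test_edge_set_shrinks_with_stricter_cutoffs(self):
        rng = np.random.default_rng(47)
        shared = rng.normal(size=15)
        lnc = _expr_frame([shared + rng.normal(0, s, 15) for s in (0.2, 0.5, 1.0)], "L")
        mrna = _expr_frame([shared + rng.normal(0, s, 15) for s in (0.2, 0.5, 1.0, 2.0)], "M")
        loose = coexpression_edges(lnc, mrna, r_cutoff=0.3, fdr_cutoff=0.2)
        tight_r = coexpression_edges(lnc, mrna, r_cutoff=0.8, fdr_cutoff=0.2)
        tight_q = coexpression_edges(lnc, mrna, r_cutoff=0.3, fdr_cutoff=0.001)
        pairs = lambda e: set(zip(e["lnc_id"], e["mrna_id"]))
        assert pairs(tight_r) <= pairs(loose)
        assert pairs(tight_q) <= pairs(loose)

    def test_too_few_samples_rejected(self):
        lnc = _expr_frame([[1.0, 2.0]], "L")
        with pytest.raises(ValueError, match="3 shared"):
            coexpression_edges(lnc, lnc)


@pytest.fixture
def planted_map():
    mapping = {}
    # term T_hit annotates m0..m7; T_bg spread thin over the rest
    for i in range(40):
        terms = set()
        if i < 8:
            terms.add("T_hit")
        if i % 5 == 0:
            terms.add("T_bg")
        terms.add("T_all") if i < 39 else None
        mapping[f"m{i}"] = frozenset(terms) or frozenset({"T_none"})
    return TermMap(mapping, {"T_hit": "planted process"})


class TestEnrich:
    def test_planted_term_ranks_first(self, planted_map):
        res = enrich([f"m{i}" for i in range(8)], planted_map)
        assert res.iloc[0]["term_id"] == "T_hit"
        assert res.iloc[0]["k"] == 8
        assert res.iloc[0]["p"] == pytest.approx(
            hypergeom_enumerate(8, 8, 8, len(planted_map.universe)), abs=1e-12
        )

    def test_unannotated_query_is_empty(self, planted_map):
        assert enrich(["ghost1", "ghost2"], planted_map).empty

    def test_universal_term_has_p_one(self):
        tmap = TermMap({f"m{i}": frozenset({"T_u"}) for i in range(10)})
        res = enrich([f"m{i}" for i in range(4)], tmap)
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_tie_break_by_term_id(self):
        mapping = {
            "m0": frozenset({"T_b", "T_a"}),
            "m1": frozenset({"T_b", "T_a"}),
            "m2": frozenset(),
            "m3": frozenset(),
        }
        res = enrich(["m0", "m1"], TermMap(mapping))
        assert res["term_id"].tolist() == ["T_a", "T_b"]

    def test_top_n_flag(self, planted_map):
        res = enrich([f"m{i}" for i in range(8)], planted_map, top_n=1)
        assert res["top"].sum() == 1 and res.iloc[0]["top"]

    def test_row_invariants(self, planted_map):
        res = enrich([f"m{i}" for i in range(0, 40, 3)], planted_map)
        for _, row in res.iterrows():
            assert 0 <= row["k"] <= min(row["K"], row["n"]) <= row["N"]
            assert row["p_adj"] >= row["p"] - 1e-15


class TestGroupAnnotation:
    def _edges(self, mapping):
        rows = [
            {"lnc_id": l, "mrna_id": m, "r": 0.9, "p": 1e-6, "p_adj": 1e-5}
            for l, ms in mapping.items()
            for m in ms
        ]
        return pd.DataFrame(rows)

    def _calls(self, ids, short, long_):
        df = pd.DataFrame(index=ids)
        df["short_label"], df["long_label"] = short, long_
        df["is_SA"] = (df["short_label"] != "none") | (df["long_label"] != "none")
        return df

    def test_group_query_is_union(self, planted_map):
        edges = self._edges({"l1": ["m1", "m2"], "l2": ["m2", "m3"]})
        calls = self._calls(["l1", "l2"], ["up", "up"], ["none", "none"])
        res = annotate_lncrna_groups(edges, calls, planted_map, mode="group")
        assert res["short_up"].iloc[0]["n"] == 3  # |{m1, m2, m3}|

    def test_planted_group_enrichment(self, planted_map):
        edges = self._edges({"l1": [f"m{i}" for i in range(8)]})
        calls = self._calls(["l1"], ["up"], ["up"])
        res = annotate_lncrna_groups(edges, calls, planted_map, mode="group")
        for group in ("short_up", "long_up", "both_up"):
            assert res[group].iloc[0]["term_id"] == "T_hit"

    def test_per_lncrna_ranking_order(self, planted_map):
        edges = self._edges(
            {f"l{i}": [f"m{j}" for j in range(8)] for i in range(3)}
        )
        calls = self._calls(
            [f"l{i}" for i in range(3)], ["up"] * 3, ["none"] * 3
        )
        _per, ranking, sif = annotate_lncrna_groups(
            edges, calls, planted_map, mode="per_lncrna"
        )
        assert ranking.iloc[0]["term_id"] == "T_hit"
        assert ranking.iloc[0]["n_lncrnas"] == 3
        assert set(sif.columns) == {"lnc_id", "interaction", "term_id"}
        assert (sif["interaction"] == "annotated_with").all()


class TestTermMapIO:
    def test_round_trip(self, tmp_path, planted_map):
        p, names = tmp_path / "map.tsv", tmp_path / "names.tsv"
        planted_map.write_tsv(p, names)
        back = TermMap.read_tsv(p, names)
        original = {m: t for m, t in planted_map.mrna_to_terms.items() if t}
        assert back.mrna_to_terms == original
        assert back.names["T_hit"] == "planted process"
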