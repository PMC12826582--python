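"""Hypergeometric enrichment, Cohen's kappa, and the term network."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenoanchor import build_network, hypergeom_enrich, kappa


def make_universe(n):
    return {f"g{i}" for i in range(n)}


class TestHypergeomEnrich:
    def test_closed_form_perfect_overlap(self):
        universe = make_universe(20)
        query = {f"g{i}" for i in range(5)}
        gmt = {"term": set(query)}
        out = hypergeom_enrich(query, gmt, universe)
        assert out.loc[0, "pvalue"] == pytest.approx(1 / comb(20, 5), rel=1e-12)

    def test_zero_overlap_p_one(self):
        universe = make_universe(30)
        out = hypergeom_enrich(
            {"g0", "g1"}, {"term": {"g10", "g11"}}, universe
        )
        assert out.loc[0, "pvalue"] == pytest.approx(1.0)

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            hypergeom_enrich({"zz"}, {}, make_universe(5))

    def test_planted_term_ranks_first(self):
        rng = np.random.default_rng(0)
        universe = make_universe(500)
        query = {f"g{i}" for i in range(30)}
        gmt = {"planted": set(query)}
        for t in range(20):
            gmt[f"null{t}"] = set(rng.choice(sorted(universe), 30, replace=False))
        out = hypergeom_enrich(query, gmt, universe)
        assert out.loc[0, "term"] == "planted"

    def test_null_pvalues_roughly_uniform(self):
        # disjoint random terms against a random query: KS vs uniform
        from scipy.stats import kstest

        rng = np.random.default_rng(1)
        universe = sorted(make_universe(2000))
        pvals = []
        for seed in range(300):
            rng2 = np.random.default_rng(seed)
            term = set(rng2.choice(universe, 10, replace=False))
            query = set(rng2.choice(universe, 100, replace=False))
            out = hypergeom_enrich(query, {"t": term}, set(universe))
            pvals.append(out.loc[0, "pvalue"])
        # discrete p-values are conservative; only reject gross miscalibration
        stat, p = kstest(pvals, "uniform")
        assert (np.array(pvals) < 0.05).mean() < 0.08


class TestKappa:
    def test_identical_sets_give_one(self):
        u = make_universe(50)
        a = {f"g{i}" for i in range(10)}
        assert kappa(a, set(a), u) == pytest.approx(1.0)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(2)
        u = sorted(make_universe(100))
        for seed in range(50):
            r = np.random.default_rng(seed)
            a = set(r.choice(u, r.integers(1, 60), replace=False))
            b = set(r.choice(u, r.integers(1, 60), replace=False))
            k1 = kappa(a, b, set(u))
            k2 = kappa(b, a, set(u))
            assert k1 == pytest.approx(k2)
            assert -1.0 <= k1 <= 1.0

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        u = sorted(make_universe(80))
        for seed in range(50):
            r = np.random.default_rng(seed)
            A = set(r.choice(u, r.integers(1, 50), replace=False))
            B = set(r.choice(u, r.integers(1, 50), replace=False))
            a = len(A & B)
            b = len(A - B)
            c = len(B - A)
            d = len(u) - a - b - c
            n = len(u)
            po = (a + d) / n
            pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
            expected = (po - pe) / (1 - pe) if pe < 1 else 1.0
            assert kappa(A, B, set(u)) == pytest.approx(expected, abs=1e-12)

    def test_complementary_halves_negative(self):
        u = make_universe(20)
        a = {f"g{i}" for i in range(10)}
        b = u - a
        assert kappa(a, b, u) < 0


def _enrichment_frame(terms, pvals=None):
    import pandas as pd

    pvals = pvals or {t: 0.01 for t in terms}
    return pd.DataFrame(
        dict(term=list(terms), pvalue=[pvals[t] for t in terms],
             padj=[pvals[t] for t in terms], enriched=True)
    )


class TestBuildNetwork:
    def test_disjoint_terms_no_edge(self):
        u = make_universe(40)
        gmt = {"t1": {f"g{i}" for i in range(10)},
               "t2": {f"g{i}" for i in range(10, 20)}}
        net = build_network(_enrichment_frame(gmt), gmt, u)
        assert net.graph.number_of_edges() == 0
        assert net.groups["group"].nunique() == 2

    def test_identical_terms_one_group(self):
        u = make_universe(40)
        genes = {f"g{i}" for i in range(12)}
        gmt = {"t1": set(genes), "t2": set(genes)}
        net = build_network(_enrichment_frame(gmt), gmt, u)
        assert net.graph.has_edge("t1", "t2")
        assert net.groups["group"].nunique() == 1

    def test_group_label_is_lowest_p_member(self):
        u = make_universe(40)
        genes = {f"g{i}" for i in range(12)}
        gmt = {"t1": set(genes), "t2": set(genes)}
        net = build_network(
            _enrichment_frame(gmt, {"t1": 0.04, "t2": 0.001}), gmt, u
        )
        assert (net.groups["group_label"] == "t2").all()

    def test_hand_computed_adjacency(self):
        # five terms over a 30-gene universe; kappas hand-checked
        u = make_universe(30)
        gmt = {
            "a": {f"g{i}" for i in range(10)},
            "b": {f"g{i}" for i in range(8)} | {"g20", "g21"},   # near-copy of a
            "c": {f"g{i}" for i in range(15, 25)},
            "d": {f"g{i}" for i in range(15, 25)},               # identical to c
            "e": {"g28", "g29"},
        }
        def k(x, y):
            return kappa(gmt[x], gmt[y], u)
        net = build_network(_enrichment_frame(gmt), gmt, u, kappa_threshold=0.35)
        for x, y in [("a", "b"), ("c", "d")]:
            assert k(x, y) >= 0.35
            assert net.graph.has_edge(x, y)
        for x, y in [("a", "c"), ("a", "e"), ("c", "e"), ("b", "d")]:
            assert k(x, y) < 0.35
            assert not net.graph.has_edge(x, y)

    def test_raising_kappa_threshold_never_adds_edges(self):
        rng = np.random.default_rng(5)
        u = sorted(make_universe(60))
        gmt = {f"t{i}": set(rng.choice(u, 15, replace=False)) for i in range(6)}
        frame = _enrichment_frame(gmt)
        edges = {}
        for thr in (0.2, 0.35, 0.5, 0.8):
            net = build_network(frame, gmt, set(u), kappa_threshold=thr)
            edges[thr] = set(map(tuple, map(sorted, net.graph.edges())))
        assert edges[0.8] <= edges[0.5] <= edges[0.35] <= edges[0.2]

    def test_group_count_nondecreasing_in_merge_threshold(self):
        # stricter merging -> fewer merges -> at least as many groups
        rng = np.random.default_rng(6)
        u = sorted(make_universe(60))
        gmt = {f"t{i}": set(rng.choice(u, 20, replace=False)) for i in range(8)}
        frame = _enrichment_frame(gmt)
        counts = [
            build_network(frame, gmt, set(u), overlap_threshold=thr)
            .groups["group"].nunique()
            for thr in (0.2, 0.5, 0.9)
        ]
        assert counts == sorted(counts)

    def test_no_enriched_terms_empty_network(self):
        import pandas as pd

        empty = pd.DataFrame(columns=["term", "pvalue", "padj", "enriched"])
        net = build_network(empty, {}, make_universe(10))
        assert net.graph.number_of_nodes() == 0
        assert net.groups.empty


class TestKappaProperties:
    """Invariants of the kappa statistic under arbitrary membership pairs."""

    @staticmethod
    def _to_sets(idx_a, idx_b, n):
        u = {f"g{i}" for i in range(n)}
        a = {f"g{i % n}" for i in idx_a}
        b = {f"g{i % n}" for i in idx_b}
        return a, b, u

    @given(
        st.lists(st.integers(0, 59), min_size=1, max_size=40),
        st.lists(st.integers(0, 59), min_size=1, max_size=40),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_symmetric_bounded_and_one_iff_identical(self, idx_a, idx_b):
        a, b, u = self._to_sets(idx_a, idx_b, 60)
        k_ab = kappa(a, b, u)
        k_ba = kappa(b, a, u)
        assert k_ab == pytest.approx(k_ba, abs=1e-12)
        assert -1.0 - 1e-12 <= k_ab <= 1.0 + 1e-12
        if a == b and a != u:
            assert k_ab == pytest.approx(1.0)
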