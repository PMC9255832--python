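"""ROC/AUC, enrichment, annotation odds ratios and mode-combination tests."""

import itertools

import numpy as np
import pytest
from scipy import stats

from phostf.evaluate import (
    EdgeClassSpec, candidate_edges, signed_roc, pooled_signed_roc,
    enrichment_test, go_shared_odds, mode_combination_chi2,
    select_top_go_edges,
)
from conftest import random_network


def mann_whitney_auc(pos_scores, neg_scores):
    """Brute-force AUC: pairwise comparison count / (n+ * n-)."""
    wins = 0.0
    for p in pos_scores:
        for q in neg_scores:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos_scores) * len(neg_scores))


class TestSignedROC:
    def test_perfect_scores_give_auc_one(self, rng):
        net = random_network(rng, density=0.4)
        _, _, auc = signed_roc(np.abs(net.W) + (net.W != 0),
                               net.W, EdgeClassSpec("P", "T"), net)
        assert auc == 1.0

    def test_matches_brute_force_mann_whitney(self, rng):
        for _ in range(10):
            net = random_network(rng, density=0.4)
            scores = rng.normal(size=net.W.shape)
            for spec in (EdgeClassSpec("P", "T"), EdgeClassSpec("P", "R", "+")
                         if False else EdgeClassSpec("P", "T", "+"),
                         EdgeClassSpec("T", "V", "-")):
                ti, si = candidate_edges(net, spec)
                t = net.W[ti, si]
                s = scores[ti, si]
                if spec.sign == "any":
                    sc, lab = np.abs(s), t != 0
                elif spec.sign == "+":
                    sc, lab = s, t > 0
                else:
                    sc, lab = -s, t < 0
                if lab.all() or not lab.any():
                    continue
                _, _, auc = signed_roc(scores, net.W, spec, net)
                oracle = mann_whitney_auc(sc[lab], sc[~lab])
                assert auc == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        net = random_network(rng, density=0.4)
        scores = np.abs(rng.normal(size=net.W.shape))
        spec = EdgeClassSpec("P", "T")
        _, _, a1 = signed_roc(scores, net.W, spec, net)
        _, _, a2 = signed_roc(np.exp(3 * scores), net.W, spec, net)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_random_scores_near_half(self, rng):
        nets, scores, truths = [], [], []
        for _ in range(6):
            net = random_network(rng, n_pk=4, n_pp=2, n_tf=4, n_o=6,
                                 density=0.3)
            nets.append(net)
            truths.append(net.W)
            scores.append(rng.normal(size=net.W.shape))
        _, _, auc = pooled_signed_roc(scores, truths,
                                      EdgeClassSpec("T", "V"), nets)
        n_cand = sum(len(candidate_edges(n, EdgeClassSpec("T", "V"))[0])
                     for n in nets)
        se = 3 / np.sqrt(n_cand)   # conservative 3-SE band
        assert abs(auc - 0.5) < max(3 * se, 0.15)

    def test_single_class_raises(self, rng):
        net = random_network(rng)
        truth = np.zeros_like(net.W)   # no positives anywhere
        with pytest.raises(ValueError, match="undefined"):
            signed_roc(np.abs(net.W), truth, EdgeClassSpec("P", "T"), net)

    def test_candidates_exclude_diagonal_and_masked(self, rng):
        net = random_network(rng)
        ti, si = candidate_edges(net, EdgeClassSpec("P", "P"))
        assert np.all(ti != si)
        assert all(net.M_P[t, s] for t, s in zip(ti, si))


class TestEnrichment:
    def test_table_10_90_10_890(self):
        universe = {(i, 0) for i in range(1000)}
        known = {(i, 0) for i in range(20)}
        predicted = {(i, 0) for i in range(10)} | \
                    {(i, 0) for i in range(20, 110)}
        # a=10 b=90 c=10 d=890
        odds, p = enrichment_test(predicted, known, universe)
        assert odds == pytest.approx(10 * 890 / (90 * 10), rel=1e-6)
        oracle = stats.hypergeom.sf(10 - 1, 1000, 20, 100)
        assert p == pytest.approx(oracle, rel=1e-8)

    def test_exact_hypergeometric_on_small_tables(self, rng):
        for _ in range(20):
            n_total = int(rng.integers(20, 200))
            n_known = int(rng.integers(1, n_total // 2))
            n_pred = int(rng.integers(1, n_total - 1))
            universe = set(range(n_total))
            known = set(rng.choice(n_total, n_known, replace=False).tolist())
            predicted = set(rng.choice(n_total, n_pred, replace=False).tolist())
            a = len(predicted & known)
            try:
                _, p = enrichment_test(predicted, known, universe)
            except ValueError:
                continue
            oracle = stats.hypergeom.sf(a - 1, n_total, n_known, n_pred)
            assert p == pytest.approx(oracle, rel=1e-8)

    def test_deficit_gives_p_near_one(self):
        universe = set(range(200))
        known = set(range(50))
        predicted = set(range(50, 150))
        _, p = enrichment_test(predicted, known, universe)
        assert p > 0.999

    def test_degenerate_margin_raises(self):
        universe = set(range(10))
        with pytest.raises(ValueError, match="degenerate"):
            enrichment_test(set(), set(range(3)), universe)


class TestGOSharedOdds:
    def test_equal_sharing_rates_or_one(self):
        ann = {f"g{i}": {"t1"} for i in range(10)} | \
              {f"h{i}": set() for i in range(10)}
        edges = [(f"g{i}", f"g{i+1}") for i in range(5)] + \
                [(f"h{i}", f"h{i+1}") for i in range(5)]
        non_edges = [(f"g{i}", f"g{i+2}") for i in range(5)] + \
                    [(f"h{i}", f"h{i+2}") for i in range(5)]
        or_, (lo, hi), _ = go_shared_odds(edges, non_edges, ann)
        assert or_ == pytest.approx(1.0)

    def test_matches_brute_force_counter(self, rng):
        genes = [f"g{i}" for i in range(20)]
        ann = {g: set(rng.choice(10, rng.integers(0, 5), replace=False)
                      .tolist()) for g in genes}
        pairs = list(itertools.combinations(genes, 2))
        rng.shuffle(pairs)
        edges, non_edges = pairs[:60], pairs[60:150]
        for min_shared in (1, 2, 3):
            def cnt(ps):
                return sum(1 for (u, v) in ps
                           if len(ann[u] & ann[v]) >= min_shared)
            a, b = cnt(edges), len(edges) - cnt(edges)
            c, d = cnt(non_edges), len(non_edges) - cnt(non_edges)
            or_, _, corrected = go_shared_odds(edges, non_edges, ann,
                                               min_shared)
            if corrected:
                expect = ((a + .5) * (d + .5)) / ((b + .5) * (c + .5))
            else:
                expect = (a * d) / (b * c)
            assert or_ == pytest.approx(expect)

    def test_planted_enrichment_recovered(self, rng):
        # inferred edges share terms twice as often as uninferred ones
        ann = {}
        edges, non_edges = [], []
        for i in range(400):
            u, v = f"a{i}", f"b{i}"
            share = rng.random() < 0.6
            ann[u] = {"x"} if share else {"x"}
            ann[v] = {"x"} if share else {"y"}
            edges.append((u, v))
        for i in range(400):
            u, v = f"c{i}", f"d{i}"
            share = rng.random() < 0.3
            ann[u] = {"x"}
            ann[v] = {"x"} if share else {"y"}
            non_edges.append((u, v))
        or_, (lo, hi), _ = go_shared_odds(edges, non_edges, ann)
        true_or = (0.6 / 0.4) / (0.3 / 0.7)
        assert lo < true_or < hi


class TestModeCombination:
    def test_hand_built_counts(self):
        edges = []
        modes = {}
        # observed table rows(sign +,-) x cols(mode +,-) = 60,40 / 40,60
        k = 0
        for (sgn, mode), cnt in [((1, 1), 60), ((1, -1), 40),
                                 ((-1, 1), 40), ((-1, -1), 60)]:
            for _ in range(cnt):
                tf = f"T{k}"
                modes[tf] = mode
                edges.append((f"P{k}", tf, sgn))
                k += 1
        obs, exp, p, pct, warn = mode_combination_chi2(edges, modes)
        assert np.allclose(exp, 50)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        # oracle: scipy's uncorrected contingency chi-square on the table
        chi2_ref = stats.chi2_contingency(obs, correction=False)[0]
        assert chi2 == pytest.approx(chi2_ref)
        assert np.allclose(np.abs(pct), 20.0)
        assert p == pytest.approx(stats.chi2.sf(chi2_ref, 1), rel=1e-10)

    def test_independent_signs_not_flagged(self, rng):
        modes = {f"T{i}": (1 if rng.random() < 0.7 else -1) for i in range(40)}
        edges = [(f"P{j}", f"T{int(rng.integers(40))}",
                  1 if rng.random() < 0.3 else -1) for j in range(2000)]
        _, _, p, pct, _ = mode_combination_chi2(edges, modes)
        assert p > 0.01
        assert np.nanmax(np.abs(pct)) < 15

    def test_planted_negneg_excess_detected(self, rng):
        """A 21% Neg.-Neg. over-representation at n=8776 is detected with
        overwhelming significance."""
        n = 8776
        frac_neg_edge, frac_rep_tf = 0.7, 0.3
        base = np.outer([1 - frac_neg_edge, frac_neg_edge],
                        [1 - frac_rep_tf, frac_rep_tf]) * n
        planted = base.copy()
        excess = 0.21 * base[1, 1]
        # diagonal mass shift keeps both margins (hence the expected table)
        planted[1, 1] += excess
        planted[0, 0] += excess
        planted[0, 1] -= excess
        planted[1, 0] -= excess
        edges, modes = [], {}
        k = 0
        for (si, mi), cnt in np.ndenumerate(planted):
            sgn = 1 if si == 0 else -1
            mode = 1 if mi == 0 else -1
            for _ in range(int(round(cnt))):
                tf = f"T{k}"
                modes[tf] = mode
                edges.append((f"P{k}", tf, sgn))
                k += 1
        _, _, p, pct, _ = mode_combination_chi2(edges, modes)
        assert p < 1e-7
        assert pct[1, 1] > 10   # Neg.-Neg. over-represented


class TestTopGOEdges:
    def test_no_shared_terms_empty(self):
        ann = {"a": {"1"}, "b": {"2"}}
        assert select_top_go_edges([("a", "b", 0.9)], ann) == []

    def test_dedup_across_thresholds(self):
        ann = {f"g{i}": set("abcdef") for i in range(8)}
        edges = [(f"g{i}", f"g{i+1}", w)
                 for i, w in enumerate([3.0, 2.0, -2.5, -3.5])]
        out = select_top_go_edges(edges, ann)
        assert len(out) == 4    # same extremes qualify at every threshold

    def test_matches_exhaustive_enumeration(self, rng):
        genes = [f"g{i}" for i in range(12)]
        ann = {g: set(rng.choice(8, rng.integers(0, 7), replace=False)
                      .tolist()) for g in genes}
        edges = [(a, b, float(rng.normal()))
                 for a, b in itertools.combinations(genes, 2)]
        got = {(s, t) for s, t, _ in select_top_go_edges(edges, ann)}
        expect = set()
        for thr in range(1, 7):
            qual = sorted((e for e in edges
                           if len(ann[e[0]] & ann[e[1]]) >= thr),
                          key=lambda e: e[2])
            for e in qual[:2] + qual[-2:]:
                expect.add((e[0], e[1]))
        assert got == expect
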