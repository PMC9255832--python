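"""Node-value adjustment, evidence combination, TF modes and FDR filtering."""

import numpy as np
import pytest
from scipy import stats

from phostf.priors import (
    BindingRecord, adjust_perturbed_logfc, combine_edge_pvalues,
    build_tv_mask, classify_tf_mode, wilcoxon_initialize_pt,
    fdr_filter_inferred_edges,
)
from conftest import make_nodes


class TestAdjustLogfc:
    def test_ko_adds_minus_four(self):
        X = np.array([[-1.2], [0.3]])
        out = adjust_perturbed_logfc(X, [{0}], ["KO"])
        assert out[0, 0] == pytest.approx(-5.2)
        assert out[1, 0] == 0.3

    def test_oe_adds_plus_one(self):
        X = np.zeros((2, 1))
        out = adjust_perturbed_logfc(X, [{1}], ["OE"])
        assert out[1, 0] == pytest.approx(1.0)

    def test_non_perturbed_bitwise_unchanged(self, rng):
        X = rng.normal(size=(5, 3))
        out = adjust_perturbed_logfc(X, [{0}, {1}, {2}], ["KO"] * 3)
        mask = np.ones_like(X, bool)
        mask[0, 0] = mask[1, 1] = mask[2, 2] = False
        assert np.array_equal(out[mask], X[mask])

    def test_unmeasured_gets_bare_adjustment(self):
        X = np.array([[0.7], [0.0]])
        measured = np.array([[True], [False]])
        with pytest.warns(UserWarning, match="unmeasured"):
            out = adjust_perturbed_logfc(X, [{1}], ["KO"], measured=measured)
        assert out[1, 0] == pytest.approx(-4.0)


class TestCombinePvalues:
    def test_single_source_passthrough(self):
        out = combine_edge_pvalues([BindingRecord("T1", "g1", 0.05)])
        assert out[("T1", "g1")] == pytest.approx(0.05)

    def test_two_sources(self):
        recs = [BindingRecord("T1", "g1", 0.05, "a"),
                BindingRecord("T1", "g1", 0.05, "b")]
        out = combine_edge_pvalues(recs)
        oracle = stats.chi2.sf(-2 * (np.log(0.05) + np.log(0.05)), 4)
        assert out[("T1", "g1")] == pytest.approx(oracle)
        assert out[("T1", "g1")] == pytest.approx(0.0175, abs=5e-4)

    def test_all_ones_stay_one(self):
        recs = [BindingRecord("T1", "g1", 1.0, str(i)) for i in range(3)]
        assert combine_edge_pvalues(recs)[("T1", "g1")] == pytest.approx(1.0)

    def test_zero_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamp"):
            out = combine_edge_pvalues([BindingRecord("T1", "g1", 0.0)])
        assert out[("T1", "g1")] > 0


class TestTVMask:
    def test_matches_brute_force_bh(self, rng):
        nodes = make_nodes(n_tf=3, n_o=5)
        tfs = list(nodes.tf)
        targets = list(nodes.other)
        pvals = {}
        k = 0
        for tf in tfs:
            for tgt in targets:
                pvals[(tf, tgt)] = float(rng.uniform(0, 0.5))
                k += 1
        q = 0.2
        mask = build_tv_mask(pvals, nodes, q_threshold=q)
        # exhaustive BH: largest k with p_(k) <= q*k/m survives
        ps = np.sort(np.array(list(pvals.values())))
        m = len(ps)
        thresh = 0.0
        for i in range(m, 0, -1):
            if ps[i - 1] <= q * i / m:
                thresh = ps[i - 1]
                break
        idx = nodes.index()
        for (tf, tgt), p in pvals.items():
            assert mask[idx[tgt], idx[tf]] == (p <= thresh)

    def test_all_below_line_all_kept(self):
        nodes = make_nodes(n_tf=2, n_o=2)
        pvals = {("T0", "O0"): 1e-6, ("T1", "O1"): 1e-5}
        mask = build_tv_mask(pvals, nodes, q_threshold=0.2)
        assert mask.sum() == 2

    def test_q_zero_empty(self):
        nodes = make_nodes()
        assert build_tv_mask({("T0", "O0"): 1e-9}, nodes, 0.0).sum() == 0

    def test_empty_evidence_warns(self):
        nodes = make_nodes()
        with pytest.warns(UserWarning, match="no binding evidence"):
            mask = build_tv_mask({}, nodes)
        assert mask.sum() == 0


class TestTFMode:
    def test_go_has_priority(self):
        recs = [BindingRecord("T1", "g", 1e-9, mode="repressing")]
        out = classify_tf_mode("T1", go_evidence={"T1": 1},
                               interaction_evidence=recs)
        assert out.sign == 1 and out.provenance == "GO"

    def test_interaction_pvalue_comparison(self):
        recs = [BindingRecord("T1", "g1", 1e-6, mode="activating"),
                BindingRecord("T1", "g2", 0.3, mode="repressing")]
        out = classify_tf_mode("T1", interaction_evidence=recs)
        assert out.sign == 1 and out.provenance == "interaction-evidence"

    def test_ko_mean_logfc_channel(self):
        prof = np.array([0.0, -0.9, -0.7, 0.1])
        out = classify_tf_mode("T1", ko_profiles={"T1": prof},
                               regulon=[1, 2])
        assert out.sign == 1 and out.provenance == "KO-mean-logFC"

    def test_correlation_channel(self, rng):
        X = np.zeros((3, 30))
        X[0] = rng.normal(size=30)
        X[1] = -X[0] + 0.01 * rng.normal(size=30)
        X[2] = rng.normal(size=30)
        out = classify_tf_mode("T1", expression_matrix=X, regulon=[1],
                               tf_index=0)
        assert out.sign == -1 and out.provenance == "correlation"

    def test_record_order_irrelevant(self, rng):
        recs = [BindingRecord("T1", f"g{i}",
                              float(rng.uniform(0.001, 0.9)),
                              dataset=str(i),
                              mode="activating" if i % 2 else "repressing")
                for i in range(10)]
        ref = classify_tf_mode("T1", interaction_evidence=recs)
        for _ in range(5):
            rng.shuffle(recs)
            assert classify_tf_mode("T1", interaction_evidence=recs) == ref

    def test_no_evidence_raises(self):
        with pytest.raises(ValueError, match="decisive"):
            classify_tf_mode("T1")


class TestWilcoxonInit:
    def _setup(self, rng, shift):
        nodes = make_nodes(n_pk=2, n_pp=0, n_tf=2, n_o=40)
        prof = rng.normal(0, 0.1, nodes.n)
        regulon = [g for g in nodes.other[:10]]
        idx = nodes.index()
        for g in regulon:
            prof[idx[g]] += shift
        return nodes, prof, regulon

    def test_no_signal_gives_near_zero_magnitude(self, rng):
        # regulon |logFC| below the rest -> one-sided p near 1 -> |w| near 0
        nodes = make_nodes(n_pk=2, n_pp=0, n_tf=2, n_o=40)
        idx = nodes.index()
        prof = rng.normal(0, 0.5, nodes.n)
        regulon = list(nodes.other[:10])
        for g in regulon:
            prof[idx[g]] = 1e-4
        W0 = wilcoxon_initialize_pt({"K0": prof}, {"T0": regulon},
                                    {"T0": 1}, nodes, sigma=0.01)
        assert abs(W0[idx["T0"], idx["K0"]]) < 1e-3

    def test_magnitude_monotone_in_p(self):
        nodes = make_nodes(n_pk=1, n_pp=0, n_tf=1, n_o=30)
        sigma = 0.01
        mags = []
        for shift in (0.0, 0.3, 1.0, 3.0):
            rng = np.random.default_rng(0)
            prof = rng.normal(0, 0.1, nodes.n)
            idx = nodes.index()
            regulon = list(nodes.other[:10])
            for g in regulon:
                prof[idx[g]] += shift
            W0 = wilcoxon_initialize_pt({"K0": prof}, {"T0": regulon},
                                        {"T0": 1}, nodes, sigma=sigma)
            mags.append(abs(W0[idx["T0"], idx["K0"]]))
        assert mags == sorted(mags)

    def test_sign_rule_activator_regulon_down(self, rng):
        """Regulon of an activator TF drops under P knockout: the P was
        activating the TF, so the initial sign must be positive."""
        nodes, prof, regulon = self._setup(rng, -1.0)
        W0 = wilcoxon_initialize_pt({"K0": prof}, {"T0": regulon},
                                    {"T0": 1}, nodes, sigma=0.01)
        idx = nodes.index()
        assert W0[idx["T0"], idx["K0"]] > 0

    def test_sign_rule_neg_neg_motif(self):
        """Simulated deactivation of a repressor: losing the deactivator
        makes the repressor more active, the regulon drops, and Eq-style
        sign propagation recovers a deactivating (negative) initial weight
        matching the true edge."""
        from phostf.networks import NodeSets, RegulatoryNetwork
        from phostf.generate import parameterize_network
        from phostf.simulate import Perturbation, generate_logfc_dataset
        classes = {"P": "PP", "T": "TF", "V1": "O", "V2": "O", "V3": "O"}
        nodes = NodeSets.from_classes(classes)
        idx = nodes.index()
        W = np.zeros((nodes.n, nodes.n))
        W[idx["T"], idx["P"]] = -0.6            # P deactivates T
        for v in ("V1", "V2", "V3"):
            W[idx[v], idx["T"]] = -0.9          # T represses its regulon
        net = RegulatoryNetwork(nodes, W)
        kin, promoter = parameterize_network(net, seed=5)
        data, _ = generate_logfc_dataset(
            net, kin, promoter, [Perturbation(genes=(idx["P"],))])
        regulon = ["V1", "V2", "V3"]
        assert all(data.X[idx[v], 0] < 0 for v in regulon)   # regulon drops
        W0 = wilcoxon_initialize_pt({"P": data.X[:, 0]}, {"T": regulon},
                                    {"T": -1}, nodes, sigma=0.01)
        assert W0[idx["T"], idx["P"]] < 0

    def test_small_regulon_warns(self, rng):
        nodes, prof, _ = self._setup(rng, 0.0)
        with pytest.warns(UserWarning, match="too small"):
            wilcoxon_initialize_pt({"K0": prof}, {"T0": ["O0"]},
                                   {"T0": 1}, nodes)


class TestFDRFilter:
    def test_matches_brute_force(self, rng):
        null = rng.normal(0, 1, 5000) ** 2
        scores = {f"e{i}": float(s)
                  for i, s in enumerate(rng.normal(0, 2, 40) ** 2)}
        q = 0.05
        kept = fdr_filter_inferred_edges(scores, null, q=q)
        # oracle: empirical p then exhaustive BH
        null_sorted = np.sort(null)
        ps = {e: (1 + np.sum(null_sorted >= s)) / (1 + len(null))
              for e, s in scores.items()}
        items = sorted(ps.items(), key=lambda kv: kv[1])
        m = len(items)
        cut = 0
        for i, (e, p) in enumerate(items, 1):
            if p <= q * i / m:
                cut = i
        expect = {e for e, _ in items[:cut]}
        assert set(kept) == expect

    def test_spiked_scores_kept(self, rng):
        null = np.abs(rng.normal(0, 1, 5000))
        scores = {f"s{i}": 15.0 + i for i in range(5)}
        kept = fdr_filter_inferred_edges(scores, null, q=0.05)
        assert set(kept) == set(scores)

    def test_sub_null_scores_dropped(self, rng):
        null = np.abs(rng.normal(0, 1, 5000))
        scores = {f"s{i}": 1e-4 for i in range(5)}
        assert fdr_filter_inferred_edges(scores, null, q=0.05) == {}

    def test_small_null_refused(self, rng):
        with pytest.raises(ValueError, match="null sample too small"):
            fdr_filter_inferred_edges({"e": 1.0}, rng.normal(size=50), q=0.05)
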