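"""Benchmarking and plausibility statistics for inferred networks.

Signed ROC/AUC per edge class (e.g. P→T restricted to activating edges),
Fisher-exact enrichment of predictions against known interactions, odds
ratios for shared GO annotations, a χ² test for the independence of
secondary- and primary-regulation modes, and top-pathway edge selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve, auc as _trapezoid_auc

from .networks import NodeSets, RegulatoryNetwork

__all__ = [
    "EdgeClassSpec",
    "EvaluationReport",
    "candidate_edges",
    "signed_roc",
    "pooled_signed_roc",
    "enrichment_test",
    "go_shared_odds",
    "mode_combination_chi2",
    "select_top_go_edges",
]

_SOURCE_CLASSES = {"P", "PK", "PP", "T"}
_TARGET_CLASSES = {"P", "T", "V", "R", "O"}


@dataclass(frozen=True)
class EdgeClassSpec:
    """Edge class d(source, target, sign) with sign in {any, +, -}."""

    source: str
    target: str
    sign: str = "any"

    def __post_init__(self):
        if self.source not in _SOURCE_CLASSES:
            raise ValueError(f"unknown source class {self.source!r}")
        if self.target not in _TARGET_CLASSES:
            raise ValueError(f"unknown target class {self.target!r}")
        if self.sign not in {"any", "+", "-"}:
            raise ValueError(f"sign must be any/+/-, got {self.sign!r}")

    def __str__(self):
        s = "" if self.sign == "any" else f",{self.sign}"
        return f"d({self.source},{self.target}{s})"


def candidate_edges(network: RegulatoryNetwork,
                    spec: EdgeClassSpec) -> tuple[np.ndarray, np.ndarray]:
    """(target_idx, source_idx) arrays of mask-allowed, class-matching edges.

    Mask-forbidden and diagonal entries are structurally untrainable and are
    excluded, so they cannot artificially deflate the false-positive rate.
    """
    nodes = network.nodes
    n = nodes.n
    src = np.zeros(n, bool)
    src[nodes.indices(spec.source)] = True
    tgt = np.zeros(n, bool)
    tgt[nodes.indices(spec.target)] = True
    allowed = (network.M_T | network.M_P) & tgt[:, None] & src[None, :]
    np.fill_diagonal(allowed, False)
    return np.nonzero(allowed)


def _scores_labels(scores: np.ndarray, truth: np.ndarray,
                   spec: EdgeClassSpec, network: RegulatoryNetwork):
    ti, si = candidate_edges(network, spec)
    s = scores[ti, si]
    t = truth[ti, si]
    if spec.sign == "any":
        return np.abs(s), t != 0
    if spec.sign == "+":
        return s, t > 0
    return -s, t < 0


def pooled_signed_roc(scores_list, truth_list, spec: EdgeClassSpec,
                      networks) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC over the merged candidate-edge list of several networks.

    ``scores_list`` holds signed weight matrices (inferred W); ``truth_list``
    the matching ground-truth signed adjacency matrices.  Prediction at
    threshold θ is w > θ for "+", w < -θ for "-", |w| > θ for "any".
    Returns (fpr, tpr, auc) with trapezoid AUC; ties share a threshold step.
    """
    ss, ll = [], []
    for scores, truth, net in zip(scores_list, truth_list, networks):
        s, lab = _scores_labels(np.asarray(scores, float),
                                np.asarray(truth, float), spec, net)
        ss.append(s)
        ll.append(lab)
    s = np.concatenate(ss)
    lab = np.concatenate(ll)
    if lab.all() or not lab.any():
        raise ValueError(f"AUC undefined for {spec}: candidate set has "
                         f"{int(lab.sum())} positives of {lab.size}")
    fpr, tpr, _ = roc_curve(lab, s)
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def signed_roc(scores: np.ndarray, truth: np.ndarray, spec: EdgeClassSpec,
               network: RegulatoryNetwork):
    """Single-network convenience wrapper around :func:`pooled_signed_roc`."""
    return pooled_signed_roc([scores], [truth], spec, [network])


def enrichment_test(predicted: set, known: set,
                    universe: set) -> tuple[float, float]:
    """Fisher's exact test for over-representation of known edges.

    2×2 table {predicted, not} × {known, not} over the candidate universe;
    returns (odds ratio, one-sided p).
    """
    if not known <= universe or not predicted <= universe:
        raise ValueError("predicted and known sets must be within the universe")
    a = len(predicted & known)
    b = len(predicted - known)
    c = len(known - predicted)
    d = len(universe) - a - b - c
    table = np.array([[a, b], [c, d]])
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError(f"degenerate 2x2 table (zero margin): {table.tolist()}")
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p)


def _shared_terms(edge, annotations) -> int:
    u, v = edge
    return len(annotations.get(u, set()) & annotations.get(v, set()))


def go_shared_odds(edges, non_edges, annotations: dict,
                   min_shared: int = 1) -> tuple[float, tuple[float, float], bool]:
    """Odds ratio of sharing ≥ min_shared annotation terms, inferred vs not.

    Returns (OR, (lo, hi) Woolf 95% CI, corrected) where ``corrected`` flags
    a Haldane–Anscombe 0.5 adjustment applied for an empty cell.  Pairs with
    an unannotated endpoint count as sharing zero terms.
    """
    edges = list(edges)
    non_edges = list(non_edges)
    a = sum(1 for e in edges if _shared_terms(e, annotations) >= min_shared)
    b = len(edges) - a
    c = sum(1 for e in non_edges if _shared_terms(e, annotations) >= min_shared)
    d = len(non_edges) - c
    cells = np.array([a, b, c, d], dtype=float)
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt((1 / cells).sum())
    lo, hi = np.exp(np.log(or_) - 1.96 * se), np.exp(np.log(or_) + 1.96 * se)
    return float(or_), (float(lo), float(hi)), corrected


def mode_combination_chi2(pt_edges, tf_modes: dict,
                          ) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, list]:
    """χ² independence test of secondary-edge sign vs TF mode.

    ``pt_edges`` is an iterable of (source, target_tf, sign) with sign ±1;
    ``tf_modes`` maps each target TF to ±1 (activator/repressor).  Expected
    counts follow the independence product rule: e.g. expected Pos.-Pos. is
    (fraction of positive edges) × (fraction onto activators) × total.
    Returns (observed 2×2, expected 2×2, p, percent deviations, warnings);
    rows = edge sign (+, -), columns = TF mode (+, -).
    """
    obs = np.zeros((2, 2))
    for src, tgt, sign in pt_edges:
        mode = tf_modes[tgt]
        obs[0 if sign > 0 else 1, 0 if mode > 0 else 1] += 1
    total = obs.sum()
    if total == 0:
        raise ValueError("no edges to test")
    frac_sign = obs.sum(axis=1) / total
    frac_mode = obs.sum(axis=0) / total
    expected = np.outer(frac_sign, frac_mode) * total
    warnings = []
    if np.any(expected < 5):
        warnings.append("expected cell count < 5; chi-square approximation weak")
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(np.where(expected > 0,
                                  (obs - expected) ** 2 / expected, 0.0))
        pct = np.where(expected > 0, 100.0 * (obs - expected) / expected, np.nan)
    p = float(stats.chi2.sf(chi2, df=1))
    return obs, expected, p, pct, warnings


def select_top_go_edges(scored_edges, annotations: dict,
                        thresholds=range(1, 7), per_threshold: int = 4) -> list:
    """Union over shared-term thresholds of extreme-weight edges.

    ``scored_edges`` is an iterable of (source, target, weight).  For each
    threshold t, among edges whose endpoints share ≥ t annotation terms, the
    per_threshold/2 most positive and most negative weights are taken; the
    deduplicated union across thresholds is returned sorted by |weight|.
    """
    half = per_threshold // 2
    chosen = {}
    for t in thresholds:
        qual = [(s, g, w) for (s, g, w) in scored_edges
                if _shared_terms((s, g), annotations) >= t]
        if not qual:
            continue
        by_w = sorted(qual, key=lambda e: e[2])
        for e in by_w[-half:] + by_w[:half]:
            chosen[(e[0], e[1])] = e
    return sorted(chosen.values(), key=lambda e: -abs(e[2]))
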