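"""Deterministic example networks for testing and demonstration.

``fig1_motifs``    — four disconnected 3-node motifs P → T → V covering all
                     combinations of activating/deactivating phosphorylation
                     with activating/repressing transcription regulation.
``fig2_ambiguity`` — a 6-node network (3 secondary regulators of which two
                     are functionally redundant through a strong P→P edge,
                     2 TFs, 1 target, 6 true edges) on which perturbation
                     data cannot distinguish direct from relayed regulation.
``identifiable_small`` — a random acyclic-in-P network where every regulator
                     knocked out once makes all true edges identifiable.
``yeast_like``     — a small network plus replicated noisy knockout logFC
                     columns mimicking a compendium of mutant expression
                     profiles.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .networks import NodeSets, RegulatoryNetwork, write_edge_list, write_node_sets
from .generate import (GenerationProfile, build_network, parameterize_network)
from .simulate import Perturbation, generate_logfc_dataset
from .io import write_logfc_matrix, write_experiment_manifest

__all__ = ["fig1_motifs", "fig2_ambiguity", "identifiable_small",
           "yeast_like", "make_fixture"]


def _net(classes: dict[str, str], edges: list[tuple[str, str, float]]
         ) -> RegulatoryNetwork:
    nodes = NodeSets.from_classes(classes)
    idx = nodes.index()
    W = np.zeros((nodes.n, nodes.n))
    for src, tgt, w in edges:
        W[idx[tgt], idx[src]] = w
    return RegulatoryNetwork(nodes, W)


def fig1_motifs() -> RegulatoryNetwork:
    """Four P → T → V motifs, one per regulation-mode combination.

    Motif m has secondary regulator Pm phosphorylating TF Tm (sign sp) and
    Tm transcriptionally regulating target Vm (sign st), with (sp, st) in
    {(+,+), (+,−), (−,+), (−,−)} for m = 1..4.
    """
    classes, edges = {}, []
    combos = [(1, 1), (1, -1), (-1, 1), (-1, -1)]
    for m, (sp, st) in enumerate(combos, start=1):
        p, t, v = f"P{m}", f"T{m}", f"V{m}"
        classes.update({p: "PK" if sp > 0 else "PP", t: "TF", v: "O"})
        edges.append((p, t, 0.6 * sp))
        edges.append((t, v, 0.9 * st))
    return _net(classes, edges)


def fig2_ambiguity() -> RegulatoryNetwork:
    """Six nodes, six true edges, with P1/P2 functionally redundant.

    P2 activates P1 strongly and P1 activates T1, so the total effects of
    P1 and P2 on everything downstream nearly coincide; inference from
    knockouts alone tends to symmetrize the pair (extra P1→P2 and P2→T1
    edges) while still recovering all six true interactions.
    """
    classes = {"P1": "PK", "P2": "PK", "P3": "PP",
               "T1": "TF", "T2": "TF", "V1": "O"}
    edges = [
        ("T1", "V1", 1.0),
        ("T2", "V1", -1.0),
        ("T1", "T2", 0.8),
        ("P1", "T1", 0.7),
        ("P2", "P1", 0.9),
        ("P3", "T2", 0.7),
    ]
    return _net(classes, edges)


def identifiable_small(seed: int = 0, n: int = 12) -> RegulatoryNetwork:
    """Small random network whose edges are identifiable from single KOs.

    Secondary regulators act directly on TFs only (no P→P relays — a
    secondary regulator whose entire effect routes through one other
    regulator is indistinguishable from a direct edge, as the redundant-
    pair example shows), and every regulator has at least one target, so
    noiseless knockouts of every regulator pin down all weights.
    """
    rng = np.random.default_rng(seed)
    n_p = max(2, n // 4)
    n_t = max(2, n // 4)
    classes = {}
    names = [f"N{i:02d}" for i in range(n)]
    for i, name in enumerate(names):
        if i < n_p:
            classes[name] = "PK" if i % 2 == 0 else "PP"
        elif i < n_p + n_t:
            classes[name] = "TF"
        else:
            classes[name] = "O"
    nodes = NodeSets.from_classes(classes)
    idx = nodes.index()
    p = list(nodes.p)
    t = list(nodes.tf)
    o = list(nodes.other)
    edges = []

    def w():
        return float(rng.uniform(0.4, 0.9) * rng.choice([-1, 1]))

    # every P regulates 1-2 TFs directly
    for a in range(len(p)):
        k = 1 + int(rng.integers(2))
        for tf in rng.choice(t, size=min(k, len(t)), replace=False):
            edges.append((p[a], str(tf), w()))
    # each TF regulates ≥1 target over O and P
    for tf in t:
        k = 1 + int(rng.integers(2))
        tgts = rng.choice(o + [x for x in p], size=k, replace=False)
        for tgt in tgts:
            edges.append((tf, str(tgt), w()))
    for tgt in o:  # every observed gene gets at least one TF input
        if not any(e[1] == tgt for e in edges):
            edges.append((t[int(rng.integers(len(t)))], tgt, w()))
    W = np.zeros((nodes.n, nodes.n))
    for src, tgt, wv in edges:
        W[idx[tgt], idx[src]] = wv
    np.fill_diagonal(W, 0.0)
    return RegulatoryNetwork(nodes, W)


def yeast_like(seed: int = 0, n: int = 30, replicates: int = 2,
               noise_sigma: float = 0.2):
    """Small noisy knockout compendium with replicate experiments.

    Returns (network, kinetics, promoter, dataset, manifest rows); the
    dataset holds ``replicates`` noisy copies of every regulator knockout.
    """
    rng = np.random.default_rng(seed)
    profile = GenerationProfile(
        n_nodes=n, n_tf=max(3, n // 5), n_p=max(3, n // 5),
        mean_pt=n * 0.13, mean_pp=n * 0.08, mean_tp=n * 0.15,
        mean_tt=n * 0.12, mean_to=n * 0.8)
    net, kin, promoter = build_network(profile, seed=seed)
    nodes = net.nodes
    reg_idx = [nodes.index()[v] for v in nodes.regulators]
    perts = [Perturbation(genes=(i,), kind="KO")
             for i in reg_idx for _ in range(replicates)]
    data, _ = generate_logfc_dataset(net, kin, promoter, perts,
                                     noise_sigma=noise_sigma, rng=rng)
    manifest = []
    for k, pert in enumerate(perts):
        for g in pert.genes:
            manifest.append((f"exp{k:03d}", nodes.all_nodes[g], "KO"))
    return net, kin, promoter, data, manifest


def make_fixture(name: str, seed: int, outdir) -> Path:
    """Write a named fixture bundle (network, node sets, manifest, logFC)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfgmeta = {"fixture": name, "seed": seed}
    if name == "fig1_motifs":
        net = fig1_motifs()
    elif name == "fig2_ambiguity":
        net = fig2_ambiguity()
    elif name == "identifiable_small":
        net = identifiable_small(seed)
    elif name == "yeast_like":
        net, kin, promoter, data, manifest = yeast_like(seed)
        write_edge_list(net, outdir / "network.tsv")
        write_node_sets(net.nodes, outdir / "nodes.tsv")
        write_experiment_manifest(manifest, outdir / "experiments.tsv", cfgmeta)
        exps = sorted(set(r[0] for r in manifest))
        write_logfc_matrix(data.X, net.nodes.all_nodes, exps,
                           outdir / "logfc.tsv", cfgmeta)
        return outdir
    else:
        raise ValueError(f"unknown fixture {name!r}")
    kin, promoter = parameterize_network(net, seed=seed)
    nodes = net.nodes
    reg_idx = [nodes.index()[v] for v in nodes.regulators]
    perts = [Perturbation(genes=(i,), kind="KO") for i in reg_idx]
    data, _ = generate_logfc_dataset(net, kin, promoter, perts)
    manifest = [(f"exp{k:03d}", nodes.all_nodes[p.genes[0]], "KO")
                for k, p in enumerate(perts)]
    write_edge_list(net, outdir / "network.tsv")
    write_node_sets(nodes, outdir / "nodes.tsv")
    write_experiment_manifest(manifest, outdir / "experiments.tsv", cfgmeta)
    write_logfc_matrix(data.X, nodes.all_nodes,
                       [m[0] for m in manifest], outdir / "logfc.tsv", cfgmeta)
    return outdir
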