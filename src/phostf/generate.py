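"""Random construction of ground-truth phospho-transcription networks.

Produces 100-node-scale networks whose class sizes and edge-type counts
match, in expectation, the benchmark profile (≈20 TFs, ≈20 kinases and
phosphatases, with mean counts of 13 P→T, 13 P→P, 25 T→P, 21 T→T and
102 T→O edges per 100 nodes), together with all kinetic parameters and a
promoter model for the ODE simulator.

Topology may be seeded from a template adjacency matrix (e.g. a DREAM-style
network); by default a scale-free surrogate grown by preferential attachment
supplies the degree structure, so no external data is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import NodeSets, RegulatoryNetwork
from .simulate import KineticParams, PromoterModel, PromoterModule

__all__ = [
    "GenerationProfile",
    "TemplateAdjacency",
    "build_network",
    "parameterize_network",
    "sample_passive_rates",
    "normalize_weights_per_target",
    "scale_free_template",
]


@dataclass
class GenerationProfile:
    """Target statistics for one generated network.

    Edge-count means are per network; actual counts are Poisson-distributed
    around them so an ensemble matches the profile in expectation.
    """

    n_nodes: int = 100
    n_tf: int = 20
    n_p: int = 20
    mean_pt: float = 13.0    # P → T edges
    mean_pp: float = 13.0    # P → P
    mean_tp: float = 25.0    # T → P
    mean_tt: float = 21.0    # T → T
    mean_to: float = 102.0   # T → O
    frac_pk: float = 0.75            # kinase share of P (rest phosphatases)
    tf_activator_frac: float = 0.75  # share of TFs acting as activators
    lam_decay: float = 0.8           # base decay rate (1/time)
    w_min: float = 0.2               # edge magnitudes before normalization
    w_max: float = 1.0
    k_log_spread: float = 1.0        # log10 spread of promoter dissociation
                                     # constants around the operating point
    competition_prob: float = 0.5    # chance a multi-input promoter's TFs
                                     # compete for one binding site

    def __post_init__(self):
        if self.n_tf + self.n_p > self.n_nodes:
            raise ValueError("profile infeasible: n_tf + n_p > n_nodes")
        for f in ("mean_pt", "mean_pp", "mean_tp", "mean_tt", "mean_to"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be nonnegative")


@dataclass
class TemplateAdjacency:
    """Source-topology seed: a square adjacency matrix without self-loops."""

    A: np.ndarray

    def __post_init__(self):
        self.A = np.asarray(self.A)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("template adjacency must be square")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("template must not contain self-loops")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def out_degrees(self) -> np.ndarray:
        return (self.A != 0).sum(axis=0)

    def in_degrees(self) -> np.ndarray:
        return (self.A != 0).sum(axis=1)


def scale_free_template(n: int, seed: int, m_edges: int = 2) -> TemplateAdjacency:
    """Grow a scale-free directed topology by preferential attachment.

    Each new node attaches to ``m_edges`` existing nodes chosen with
    probability proportional to (degree + 1); edge direction is from the
    higher-degree endpoint, emulating hub regulators.
    """
    rng = np.random.default_rng(seed)
    A = np.zeros((n, n), dtype=int)
    deg = np.zeros(n)
    for v in range(1, n):
        pool = np.arange(v)
        w = deg[:v] + 1.0
        k = min(m_edges, v)
        targets = rng.choice(pool, size=k, replace=False, p=w / w.sum())
        for u in targets:
            src, tgt = (u, v) if deg[u] >= deg[v] else (v, u)
            A[tgt, src] = 1
            deg[u] += 1
            deg[v] += 1
    return TemplateAdjacency(A)


def sample_passive_rates(n_pos_edges: int, n_neg_edges: int,
                         lam_decay: float) -> tuple[float, float]:
    """Passive activation/deactivation rates (λ⁺, λ⁻) for one protein.

    A protein with no incoming secondary edges keeps both rates at the base
    decay rate.  Otherwise the passive rates counterbalance the active
    regulation: λ⁺ is the decay rate scaled by the fraction of deactivating
    edges and λ⁻ by the fraction of activating edges, so active and passive
    conversion budgets stay on the decay scale.
    """
    if n_pos_edges < 0 or n_neg_edges < 0:
        raise ValueError("edge counts must be nonnegative")
    tot = n_pos_edges + n_neg_edges
    if tot == 0:
        return lam_decay, lam_decay
    return (lam_decay * n_neg_edges / tot, lam_decay * n_pos_edges / tot)


def normalize_weights_per_target(w_pos: np.ndarray, w_neg: np.ndarray,
                                 budget: float) -> tuple[np.ndarray, np.ndarray]:
    """Scale each target row so its total incoming rate equals ``budget``.

    Relative proportions within a row are preserved; rows with no incoming
    edges are left unchanged.  Keeping the per-target rate budget on the
    decay scale keeps every edge's effect observable (no regulator saturates
    its target on its own).
    """
    w_pos = np.asarray(w_pos, dtype=float).copy()
    w_neg = np.asarray(w_neg, dtype=float).copy()
    row_sum = w_pos.sum(axis=1) + w_neg.sum(axis=1)
    scale = np.where(row_sum > 0, budget / np.where(row_sum > 0, row_sum, 1.0), 1.0)
    return w_pos * scale[:, None], w_neg * scale[:, None]


def _sample_edges(rng, sources, targets, count, taken, out_propensity):
    """Sample ``count`` distinct (target, source) pairs without self-loops.

    Sources are drawn with probability proportional to the template's
    out-degree propensity (hub regulators); targets uniformly.
    """
    pairs = []
    if count == 0 or len(sources) == 0 or len(targets) == 0:
        return pairs
    prop = np.array([out_propensity[s] for s in sources], dtype=float)
    prop = prop / prop.sum()
    max_possible = sum(len(targets) - (1 if s in targets else 0) for s in sources)
    count = min(count, max_possible - len(taken))
    tries = 0
    while len(pairs) < count and tries < 100 * count + 1000:
        s = rng.choice(sources, p=prop)
        t = rng.choice(targets)
        tries += 1
        if s == t or (t, s) in taken:
            continue
        taken.add((t, s))
        pairs.append((t, s))
    return pairs


def build_network(profile: GenerationProfile, seed: int,
                  template: TemplateAdjacency | None = None,
                  ) -> tuple[RegulatoryNetwork, KineticParams, PromoterModel]:
    """Draw a fully parameterized ground-truth network.

    Node classes are assigned at random, edge counts per type drawn Poisson
    around the profile means, sources chosen with propensity proportional to
    the template's out-degrees (hub regulators), and magnitudes uniform on
    [w_min, w_max] before per-target normalization of secondary rates.
    Every TF edge carries the sign of its source TF's mode of regulation;
    secondary-edge signs are ±1 with equal probability.  Secondary
    regulators that end up without an outgoing edge are relabeled as
    non-regulators, since no perturbation could ever implicate them.
    """
    rng = np.random.default_rng(seed)
    n = profile.n_nodes
    if template is None:
        template = scale_free_template(n, seed=int(rng.integers(2 ** 31)))
    if template.n < n:
        raise ValueError("template smaller than requested network")

    # map template nodes onto network nodes: highest-degree template nodes
    # become regulators so the degree structure carries over
    tmpl_out = template.out_degrees()[:n]
    order = np.argsort(-tmpl_out, kind="stable")
    names = [f"G{i:03d}" for i in range(n)]
    reg_slots = order[: profile.n_tf + profile.n_p]
    perm = rng.permutation(profile.n_tf + profile.n_p)
    p_slots = set(reg_slots[perm[: profile.n_p]].tolist())
    tf_slots = set(reg_slots[perm[profile.n_p:]].tolist())

    classes = {}
    p_nodes = sorted(p_slots)
    n_pk = int(round(profile.frac_pk * len(p_nodes)))
    for rank, i in enumerate(rng.permutation(p_nodes)):
        classes[names[i]] = "PK" if rank < n_pk else "PP"
    for i in tf_slots:
        classes[names[i]] = "TF"
    for i in range(n):
        if names[i] not in classes:
            classes[names[i]] = "O"
    nodes = NodeSets.from_classes(classes)
    idx = nodes.index()

    # canonical-order index lists per class
    def cls_idx(slots):
        return [idx[names[i]] for i in sorted(slots)]

    p_idx = cls_idx(p_slots)
    tf_idx = cls_idx(tf_slots)
    o_idx = [idx[names[i]] for i in range(n) if classes[names[i]] == "O"]

    propensity = {}
    for i in range(n):
        propensity[idx[names[i]]] = float(tmpl_out[i]) + 1.0

    counts = {
        "pt": rng.poisson(profile.mean_pt),
        "pp": rng.poisson(profile.mean_pp),
        "tp": rng.poisson(profile.mean_tp),
        "tt": rng.poisson(profile.mean_tt),
        "to": rng.poisson(profile.mean_to),
    }
    taken: set[tuple[int, int]] = set()
    edges = {
        "pt": _sample_edges(rng, p_idx, tf_idx, counts["pt"], taken, propensity),
        "pp": _sample_edges(rng, p_idx, p_idx, counts["pp"], taken, propensity),
        "tp": _sample_edges(rng, tf_idx, p_idx, counts["tp"], taken, propensity),
        "tt": _sample_edges(rng, tf_idx, tf_idx, counts["tt"], taken, propensity),
        "to": _sample_edges(rng, tf_idx, o_idx, counts["to"], taken, propensity),
    }

    # TF modes of regulation: each TF acts consistently on all its targets
    tf_mode = {j: (1 if rng.random() < profile.tf_activator_frac else -1)
               for j in tf_idx}

    W = np.zeros((n, n))
    for key in ("pt", "pp"):
        for (t, s) in edges[key]:
            mag = rng.uniform(profile.w_min, profile.w_max)
            W[t, s] = mag * (1 if rng.random() < 0.5 else -1)
    for key in ("tp", "tt", "to"):
        for (t, s) in edges[key]:
            mag = rng.uniform(profile.w_min, profile.w_max)
            W[t, s] = mag * tf_mode[s]

    # a P node with no outgoing edge is unidentifiable: give it one target,
    # then drop another same-type edge from a multi-edge source so the
    # ensemble edge-type counts still match the profile
    p_set = set(p_idx)
    for s in p_idx:
        if not np.any(W[:, s] != 0):
            choices = [t for t in (p_idx + tf_idx) if t != s and (t, s) not in taken]
            if not choices:
                continue
            t = int(rng.choice(choices))
            taken.add((t, s))
            mag = rng.uniform(profile.w_min, profile.w_max)
            W[t, s] = mag * (1 if rng.random() < 0.5 else -1)
            same_type = [(ti, si) for (ti, si) in zip(*np.nonzero(W))
                         if si in p_set and si != s
                         and ((ti in p_set) == (t in p_set))
                         and np.count_nonzero(W[:, si]) >= 2]
            if same_type:
                ti, si = same_type[int(rng.integers(len(same_type)))]
                W[ti, si] = 0.0

    # normalize secondary rates per target to the decay budget; the signed
    # ground-truth magnitudes are updated to match the simulated rates
    p_cols = np.zeros(n, bool)
    p_cols[p_idx] = True
    w_p_signed = W * p_cols[None, :]
    w_pos, w_neg = KineticParams.rates_from_weights(w_p_signed)
    w_pos, w_neg = normalize_weights_per_target(w_pos, w_neg, profile.lam_decay)
    W = np.where(p_cols[None, :], w_pos - w_neg, W)

    net = RegulatoryNetwork(nodes, W)
    kin, promoter = parameterize_network(
        net, seed=int(rng.integers(2 ** 31)), lam_decay=profile.lam_decay,
        k_log_spread=profile.k_log_spread,
        competition_prob=profile.competition_prob)
    return net, kin, promoter


def parameterize_network(net: RegulatoryNetwork, seed: int,
                         lam_decay: float = 0.8, rate_jitter: bool = True,
                         calibrate: bool = True, competition_prob: float = 0.0,
                         k_log_spread: float = 0.0,
                         ) -> tuple[KineticParams, PromoterModel]:
    """Kinetic parameters and promoter model for a given signed network.

    Max transcription/translation rates are near 1 (mild jitter), decay
    rates equal the shared decay scale, and passive activation/deactivation
    rates counterbalance the incoming secondary edges.  Each TF edge becomes
    a singleton promoter module with half-saturation at the regulator's
    wildtype activated-protein level, keeping every regulator responsive
    (mid-range) in the unperturbed strain and avoiding silent regulation.
    With ``calibrate`` the wildtype level is read off an actual wildtype
    steady-state simulation (one extra solve) rather than a closed-form
    estimate; a nonzero ``k_log_spread`` then scatters each dissociation
    constant log-uniformly around that operating point (±k_log_spread
    decades), leaving a realistic fraction of edges partially saturated
    (weakly observable) the way randomly parameterized kinetic models do.
    A gene with several TF inputs has them merged, with
    probability ``competition_prob``, into a single competitive module
    (the TFs compete for the same site), which mutes the gene's response
    to the loss of any one of them — the main source of hard-to-detect
    primary regulation in real promoters.
    """
    rng = np.random.default_rng(seed)
    n = net.nodes.n
    W = net.W
    p_cols = np.zeros(n, bool)
    p_cols[net.nodes.indices("P")] = True
    w_p_signed = W * net.M_P
    w_pos, w_neg = KineticParams.rates_from_weights(w_p_signed)

    lam = lam_decay
    if rate_jitter:
        m_rna = rng.uniform(0.8, 1.2, size=n)
        m_prot = rng.uniform(0.8, 1.2, size=n)
    else:
        m_rna = np.ones(n)
        m_prot = np.ones(n)
    lam_rna = np.full(n, lam)
    lam_prot = np.full(n, lam)
    lam_act = np.zeros(n)
    lam_deact = np.zeros(n)
    for i in range(n):
        npos = int(np.sum(w_pos[i] > 0))
        nneg = int(np.sum(w_neg[i] > 0))
        lam_act[i], lam_deact[i] = sample_passive_rates(npos, nneg, lam)
    kin = KineticParams(m_rna, m_prot, lam_rna, lam_prot, lam_act, lam_deact,
                        w_pos, w_neg)

    r_scale = m_rna / lam_rna
    p_scale = m_prot * r_scale / lam_prot
    denom = lam_act + lam_deact
    psi_scale = p_scale * np.where(denom > 0,
                                   lam_act / np.where(denom > 0, denom, 1), 0.5)
    psi_scale = np.maximum(psi_scale, 0.1 * p_scale)
    modules: list[list[PromoterModule]] = [[] for _ in range(n)]
    for (i, j) in zip(*np.nonzero(W * net.M_T)):
        k_half = psi_scale[j] * 0.5 * (rng.uniform(0.7, 1.3) if rate_jitter else 1.0)
        nu = rng.uniform(1.0, 3.0) if rate_jitter else 2.0
        # module effect strength = the edge magnitude, so the signed weight
        # matrix is the simulation's ground truth in strength, not just sign
        modules[i].append(PromoterModule(
            regulators=(int(j),), k=(float(k_half),), nu=(float(nu),),
            activating=bool(W[i, j] > 0), weight=float(min(abs(W[i, j]), 1.0))))
    for i, gene_mods in enumerate(modules):
        if len(gene_mods) >= 2 and rng.random() < competition_prob:
            modules[i] = [PromoterModule(
                regulators=tuple(m.regulators[0] for m in gene_mods),
                k=tuple(m.k[0] for m in gene_mods),
                nu=tuple(m.nu[0] for m in gene_mods),
                activating=any(m.activating for m in gene_mods),
                weight=max(m.weight for m in gene_mods),
                competitive=True,
                member_activating=tuple(m.activating for m in gene_mods))]
    promoter = PromoterModel(modules)
    if calibrate and any(modules):
        # pin half-saturation to the simulated wildtype activity level so no
        # regulator sits in a saturated (silent) part of its response curve
        from .simulate import simulate_steady_state
        wt = simulate_steady_state(net, kin, promoter)
        cal: list[list[PromoterModule]] = [[] for _ in range(n)]
        for i, gene_mods in enumerate(modules):
            for mod in gene_mods:
                k_cal = tuple(
                    float(max(wt.psi[j], 1e-3)
                          * 10 ** rng.uniform(-k_log_spread, k_log_spread))
                    for j in mod.regulators)
                cal[i].append(PromoterModule(
                    mod.regulators, k_cal, mod.nu, mod.activating, mod.weight,
                    mod.competitive, mod.member_activating))
        promoter = PromoterModel(cal)
    return kin, promoter
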