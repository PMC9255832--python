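"""Signed regulatory networks with two regulator classes.

Nodes are partitioned into protein kinases (PK), protein phosphatases (PP),
transcription factors (TF) and observed non-regulators (O).  The union
P = PK ∪ PP holds the secondary regulators, which act on the *activity* of
other regulators; TFs are primary regulators acting on mRNA production.

A network stores a single dense signed weight matrix ``W`` where ``W[i, j]``
is the effect of node ``j`` on node ``i``, together with two disjoint binary
masks: ``M_T`` marks allowed transcriptional edges (TF columns) and ``M_P``
marks allowed secondary edges (P columns, regulator rows).  The net linear
influence of every node on mRNA levels, through all pathways including
cycles, is the total-effects matrix

    B = W_T (I - W_P)^{-1},   W_T = W ⊙ M_T,  W_P = W ⊙ M_P.

The accumulated-effects matrix ``B*`` is the same construction on absolute
weights; it is nonnegative and immune to sign cancellation between parallel
cascades, which makes it the natural sparsity-regularization target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NodeSets",
    "RegulatoryNetwork",
    "split_weights",
    "total_effects",
    "accumulated_effects",
    "total_effect_from_knockout",
    "read_node_sets",
    "write_node_sets",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency",
    "write_adjacency",
]

#: condition-number ceiling for (I - W_P) solves; beyond this the secondary
#: cycle gain is treated as a modeling error rather than a numerics problem
COND_LIMIT = 1e8

_CLASS_NAMES = ("PK", "PP", "TF", "O")


class CycleGainError(np.linalg.LinAlgError):
    """(I - W_P) is singular or numerically unusable (cycle gain ≥ 1)."""


@dataclass(frozen=True)
class NodeSets:
    """Partition of node ids into regulator classes.

    Ordering is canonical: the P block (PK ∪ PP) first, then TF, then O,
    each sorted lexicographically.  All matrices in the package index nodes
    in this order.
    """

    pk: tuple[str, ...]
    pp: tuple[str, ...]
    tf: tuple[str, ...]
    other: tuple[str, ...]

    def __post_init__(self):
        groups = dict(pk=self.pk, pp=self.pp, tf=self.tf, other=self.other)
        for name, g in groups.items():
            object.__setattr__(self, name, tuple(g))
        all_ids = self.pk + self.pp + self.tf + self.other
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("node classes must be pairwise disjoint and ids unique")

    @classmethod
    def from_classes(cls, classes: dict[str, str]) -> "NodeSets":
        """Build from a node → class mapping with class in {PK, PP, TF, O}."""
        by = {c: [] for c in _CLASS_NAMES}
        for node, c in classes.items():
            if c not in by:
                raise ValueError(f"unknown node class {c!r} for node {node!r}")
            by[c].append(node)
        return cls(pk=tuple(sorted(by["PK"])), pp=tuple(sorted(by["PP"])),
                   tf=tuple(sorted(by["TF"])), other=tuple(sorted(by["O"])))

    # -- derived sets, canonical order ------------------------------------
    @property
    def p(self) -> tuple[str, ...]:
        """Secondary regulators P = PK ∪ PP (canonical order)."""
        return tuple(sorted(self.pk + self.pp))

    @property
    def regulators(self) -> tuple[str, ...]:
        """R = P ∪ TF."""
        return self.p + self.tf

    @property
    def all_nodes(self) -> tuple[str, ...]:
        """V = R ∪ O in canonical order; indexing order of every matrix."""
        return self.p + self.tf + self.other

    @property
    def n(self) -> int:
        return len(self.all_nodes)

    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.all_nodes)}

    def class_of(self, node: str) -> str:
        for name, cls_ in (("pk", "PK"), ("pp", "PP"), ("tf", "TF"), ("other", "O")):
            if node in getattr(self, name):
                return cls_
        raise KeyError(node)

    def indices(self, which: str) -> np.ndarray:
        """Integer indices of a class: PK, PP, TF, O, P, R or V."""
        idx = self.index()
        sets = {
            "PK": self.pk, "PP": self.pp, "TF": self.tf, "O": self.other,
            "P": self.p, "R": self.regulators, "V": self.all_nodes,
            "T": self.tf,
        }
        if which not in sets:
            raise KeyError(which)
        return np.array([idx[v] for v in sets[which]], dtype=int)


def _class_masks(nodes: NodeSets) -> tuple[np.ndarray, np.ndarray]:
    """Default full masks: M_T covers V×TF, M_P covers R×P, no diagonal."""
    n = nodes.n
    m_t = np.zeros((n, n), dtype=bool)
    m_p = np.zeros((n, n), dtype=bool)
    m_t[:, nodes.indices("TF")] = True
    m_p[np.ix_(nodes.indices("R"), nodes.indices("P"))] = True
    np.fill_diagonal(m_t, False)
    np.fill_diagonal(m_p, False)
    return m_t, m_p


@dataclass
class RegulatoryNetwork:
    """Node sets plus signed weight matrix and edge-permission masks."""

    nodes: NodeSets
    W: np.ndarray
    M_T: np.ndarray = None
    M_P: np.ndarray = None

    def __post_init__(self):
        n = self.nodes.n
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (n, n):
            raise ValueError(f"W must be {n}x{n}, got {self.W.shape}")
        if self.M_T is None or self.M_P is None:
            full_t, full_p = _class_masks(self.nodes)
            self.M_T = full_t if self.M_T is None else np.asarray(self.M_T, bool)
            self.M_P = full_p if self.M_P is None else np.asarray(self.M_P, bool)
        self.M_T = np.asarray(self.M_T, dtype=bool)
        self.M_P = np.asarray(self.M_P, dtype=bool)
        self.validate()

    def validate(self) -> None:
        n = self.nodes.n
        if np.any(np.diag(self.W) != 0):
            raise ValueError("self-loops are not allowed (diagonal of W must be 0)")
        if np.any(self.M_T & self.M_P):
            raise ValueError("M_T and M_P overlap")
        tf_cols = np.zeros(n, bool)
        tf_cols[self.nodes.indices("TF")] = True
        if np.any(self.M_T[:, ~tf_cols]):
            raise ValueError("M_T allows edges from non-TF sources")
        p_cols = np.zeros(n, bool)
        p_cols[self.nodes.indices("P")] = True
        r_rows = np.zeros(n, bool)
        r_rows[self.nodes.indices("R")] = True
        if np.any(self.M_P[:, ~p_cols]) or np.any(self.M_P[~r_rows, :]):
            raise ValueError("M_P allows edges outside P columns × R rows")
        if np.any(np.diag(self.M_T)) or np.any(np.diag(self.M_P)):
            raise ValueError("masks must not allow self-loops")
        outside = self.W * ~(self.M_T | self.M_P)
        if np.any(outside != 0):
            raise ValueError("W has weight mass outside the allowed masks")

    def copy_with(self, W: np.ndarray) -> "RegulatoryNetwork":
        return RegulatoryNetwork(self.nodes, W, self.M_T.copy(), self.M_P.copy())


def split_weights(network: RegulatoryNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Return (W_T, W_P) = (W ⊙ M_T, W ⊙ M_P)."""
    return network.W * network.M_T, network.W * network.M_P


def _implicated_cycle_nodes(nodes: NodeSets, w_p: np.ndarray) -> list[str]:
    """Node ids in non-trivial strongly connected components of the P graph."""
    import networkx as nx

    g = nx.from_numpy_array((w_p != 0).T.astype(int), create_using=nx.DiGraph)
    names = nodes.all_nodes
    out: list[str] = []
    for comp in nx.strongly_connected_components(g):
        if len(comp) > 1:
            out.extend(names[i] for i in sorted(comp))
    return out


def _solve_against(nodes: NodeSets, w_t: np.ndarray, w_p: np.ndarray) -> np.ndarray:
    """B = W_T (I - W_P)^{-1} via a linear solve on the transposed system."""
    n = w_p.shape[0]
    m = np.eye(n) - w_p
    cond = np.linalg.cond(m, 1)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        cyc = _implicated_cycle_nodes(nodes, w_p)
        raise CycleGainError(
            f"(I - W_P) is ill-conditioned (cond≈{cond:.2e}); secondary-regulation "
            f"cycle gain near or above 1. Implicated cycle nodes: {cyc or 'none found'}"
        )
    return np.linalg.solve(m.T, w_t.T).T


def total_effects(network: RegulatoryNetwork) -> np.ndarray:
    """Total-effects matrix B = W_T (I - W_P)^{-1}.

    Raises :class:`CycleGainError` when the secondary-regulation cycle gain
    makes (I - W_P) numerically singular.
    """
    w_t, w_p = split_weights(network)
    return _solve_against(network.nodes, w_t, w_p)


def accumulated_effects(network: RegulatoryNetwork) -> np.ndarray:
    """Accumulated effects B* = |W_T| (I - |W_P|)^{-1} (entrywise ≥ 0)."""
    w_t, w_p = split_weights(network)
    b_star = _solve_against(network.nodes, np.abs(w_t), np.abs(w_p))
    # ρ(|W_P|) < 1 guarantees nonnegativity; clip away solver round-off
    if b_star.min() < -1e-9:
        cyc = _implicated_cycle_nodes(network.nodes, w_p)
        raise CycleGainError(
            "accumulated effects came out negative; |W_P| cycle gain ≥ 1. "
            f"Implicated cycle nodes: {cyc or 'none found'}"
        )
    return np.clip(b_star, 0.0, None)


def total_effect_from_knockout(x_ko: np.ndarray, knocked: int, target: int) -> float:
    """Single-sample total effect t(knocked ⇝ target) = x_target / x_knocked.

    ``x_ko`` is the logFC vector of the experiment in which node ``knocked``
    was intervened on.
    """
    x_ko = np.asarray(x_ko, dtype=float)
    denom = x_ko[knocked]
    if denom == 0:
        raise ZeroDivisionError(
            "total effect undefined: the knocked-out node has zero logFC"
        )
    return float(x_ko[target] / denom)


# ---------------------------------------------------------------------------
# Text formats: node sets, edge lists, adjacency matrices
# ---------------------------------------------------------------------------

def write_node_sets(nodes: NodeSets, path) -> None:
    rows = [(v, nodes.class_of(v)) for v in nodes.all_nodes]
    pd.DataFrame(rows, columns=["node", "class"]).to_csv(path, sep="\t", index=False)


def read_node_sets(path) -> NodeSets:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df["node"].duplicated().any():
        raise ValueError("duplicate node ids in node-set file")
    return NodeSets.from_classes(dict(zip(df["node"].astype(str), df["class"])))


def write_edge_list(network: RegulatoryNetwork, path) -> None:
    """TSV edge list ``source target weight type`` with type in {T, P}."""
    names = network.nodes.all_nodes
    rows = []
    for i, j in zip(*np.nonzero(network.W)):
        etype = "T" if network.M_T[i, j] else "P"
        rows.append((names[j], names[i], network.W[i, j], etype))
    pd.DataFrame(rows, columns=["source", "target", "weight", "type"]).to_csv(
        path, sep="\t", index=False)


def read_edge_list(path, nodes: NodeSets,
                   masks: str = "full") -> RegulatoryNetwork:
    """Read a TSV edge list into a network.

    masks="full" allows every class-consistent edge (inference setting);
    masks="support" restricts the masks to exactly the listed edges.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    idx = nodes.index()
    n = nodes.n
    w = np.zeros((n, n))
    sup_t = np.zeros((n, n), bool)
    sup_p = np.zeros((n, n), bool)
    for _, row in df.iterrows():
        j, i = idx[str(row["source"])], idx[str(row["target"])]
        w[i, j] = float(row["weight"])
        (sup_t if row["type"] == "T" else sup_p)[i, j] = True
    if masks == "support":
        return RegulatoryNetwork(nodes, w, sup_t, sup_p)
    return RegulatoryNetwork(nodes, w)


def write_adjacency(network: RegulatoryNetwork, path) -> None:
    names = list(network.nodes.all_nodes)
    pd.DataFrame(network.W, index=names, columns=names).to_csv(path, sep="\t")


def read_adjacency(path, nodes: NodeSets) -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    order = list(nodes.all_nodes)
    w = df.loc[order, order].to_numpy(dtype=float)
    return RegulatoryNetwork(nodes, w)
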