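"""ODE simulation of transcription networks with phospho-regulation.

Each gene i carries three state variables: mRNA concentration r_i, total
protein p_i and activated protein ψ_i (0 ≤ ψ_i ≤ p_i):

    dr_i/dt = m_i^rna f_i(ψ) - λ_i^rna r_i
    dp_i/dt = m_i^prot r_i  - λ_i^prot p_i
    dψ_i/dt = (Σ_j w⁺_ij ψ_j + λ⁺_i)(p_i - ψ_i) - (Σ_j w⁻_ij ψ_j + λ⁻_i) ψ_i

Secondary regulators act through the nonnegative rate matrices w⁺/w⁻
(activation/deactivation of target proteins); transcription factors act
through the promoter function f_i(ψ) ∈ [0, 1], a combination of Hill terms
in the activated TF concentrations.  Perturbation strains are simulated to
steady state and compared against wildtype to produce log₂ fold-change
datasets for network-inference benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .networks import RegulatoryNetwork
from .inference import PerturbationDataset

__all__ = [
    "KineticParams",
    "PromoterModule",
    "PromoterModel",
    "Perturbation",
    "SimState",
    "hill_activator",
    "hill_repressor",
    "transcription_fraction",
    "ode_rhs",
    "simulate_steady_state",
    "generate_logfc_dataset",
    "SteadyStateError",
]

#: logFC assigned to genes whose steady-state mRNA is zero (true value -inf)
LOGFC_CLIP = 10.0


class SteadyStateError(RuntimeError):
    """Integration reached t_max without meeting the steady-state tolerance."""

    def __init__(self, msg, last_state=None):
        super().__init__(msg)
        self.last_state = last_state


def hill_activator(psi: float, k: float, nu: float) -> float:
    """Activating Hill term μ⁺(ψ) = ψ^ν / (k^ν + ψ^ν) ∈ [0, 1)."""
    psi, k, nu = float(psi), float(k), float(nu)
    if psi < 0 or k <= 0 or nu <= 0:
        raise ValueError("require psi >= 0, k > 0, nu > 0")
    rho = (psi / k) ** nu
    return rho / (1.0 + rho)


def hill_repressor(psi: float, k: float, nu: float) -> float:
    """Repressing Hill term μ⁻(ψ) = 1 / (1 + (ψ/k)^ν) = 1 - μ⁺(ψ)."""
    psi, k, nu = float(psi), float(k), float(nu)
    if psi < 0 or k <= 0 or nu <= 0:
        raise ValueError("require psi >= 0, k > 0, nu > 0")
    return 1.0 / (1.0 + (psi / k) ** nu)


@dataclass
class PromoterModule:
    """One cis-regulatory module: joint binding of its member regulators.

    A *cooperative* module (default) binds its members jointly: with
    saturation ratios ρ_j = (ψ_j/k_j)^ν_j the module activity is a
    generalized Hill term, a = Πρ/(1+Πρ) when activating and a = 1/(1+Πρ)
    when repressing.  A *competitive* module instead has its members
    competing for the same site: a = Σ_act ρ_j / (1 + Σ_all ρ_j), with the
    per-member ``member_activating`` flags deciding which bound states are
    productive.  A singleton module of either kind reduces exactly to the
    standard Hill activator or repressor.

    ``weight`` ∈ (0, 1] is the module's effect strength on the promoter:
    the module contributes a factor 1 − weight·(1 − a), i.e. at weight 1 it
    fully gates transcription and at small weight it only modulates it.
    """

    regulators: tuple[int, ...]       # node indices of the bound TFs
    k: tuple[float, ...]              # per-regulator dissociation constants
    nu: tuple[float, ...]             # per-regulator Hill coefficients
    activating: bool
    weight: float = 1.0
    competitive: bool = False
    member_activating: tuple[bool, ...] = None   # competitive modules only

    def __post_init__(self):
        if self.competitive and self.member_activating is None:
            object.__setattr__(self, "member_activating",
                               tuple([self.activating] * len(self.regulators)))

    def _rhos(self, psi: np.ndarray) -> np.ndarray:
        rho = np.empty(len(self.regulators))
        for m, (j, kj, nj) in enumerate(zip(self.regulators, self.k, self.nu)):
            x = psi[j]
            if x < 0:
                raise ValueError("negative regulator concentration")
            rho[m] = min((x / kj) ** nj, 1e30)
        return rho

    def activity(self, psi: np.ndarray) -> float:
        rho = self._rhos(psi)
        if self.competitive:
            act = np.array(self.member_activating, dtype=bool)
            return float(rho[act].sum() / (1.0 + rho.sum()))
        prod = float(np.prod(rho))
        mu_plus = prod / (1.0 + prod)
        return mu_plus if self.activating else 1.0 - mu_plus


@dataclass
class PromoterModel:
    """Per-gene lists of regulatory modules; empty list = unregulated (f ≡ 1)."""

    modules: list[list[PromoterModule]]

    def fraction(self, gene: int, psi: np.ndarray) -> float:
        """f_i = Π_m (1 - weight_m (1 - a_m)): independent partial gating.

        Modules act as independent partial gates on the promoter; a single
        full-weight module reduces exactly to its Hill term.
        """
        mods = self.modules[gene]
        if not mods:
            return 1.0
        f = 1.0
        for m in mods:
            f *= 1.0 - m.weight * (1.0 - m.activity(psi))
        return f

    def _flat(self):
        """Cached flat member/module arrays for vectorized evaluation."""
        cached = getattr(self, "_flat_cache", None)
        if cached is not None:
            return cached
        mod_id, reg_idx, ks, nus, m_act = [], [], [], [], []
        gene_idx, wts, comp, coop_act = [], [], [], []
        mid = 0
        for g, mods in enumerate(self.modules):
            for m in mods:
                members = m.member_activating if m.competitive \
                    else [m.activating] * len(m.regulators)
                for j, kj, nj, aj in zip(m.regulators, m.k, m.nu, members):
                    mod_id.append(mid)
                    reg_idx.append(j)
                    ks.append(kj)
                    nus.append(nj)
                    m_act.append(aj)
                gene_idx.append(g)
                wts.append(m.weight)
                comp.append(m.competitive)
                coop_act.append(m.activating)
                mid += 1
        flat = (np.array(mod_id, int), np.array(reg_idx, int), np.array(ks),
                np.array(nus), np.array(m_act, bool), np.array(gene_idx, int),
                np.array(wts), np.array(comp, bool), np.array(coop_act, bool))
        object.__setattr__(self, "_flat_cache", flat)
        return flat

    def fractions(self, psi: np.ndarray) -> np.ndarray:
        """Vector of f_i(ψ) for all genes at once."""
        n = len(self.modules)
        (mod_id, reg_idx, ks, nus, m_act, gene_idx, wts, comp,
         coop_act) = self._flat()
        out = np.ones(n)
        if gene_idx.size == 0:
            return out
        n_mod = gene_idx.size
        with np.errstate(over="ignore"):
            rho = np.minimum((psi[reg_idx] / ks) ** nus, 1e30)
        s_all = np.bincount(mod_id, weights=rho, minlength=n_mod)
        s_act = np.bincount(mod_id, weights=rho * m_act, minlength=n_mod)
        prod = np.ones(n_mod)
        np.multiply.at(prod, mod_id, rho)
        prod = np.minimum(prod, 1e30)
        mu_plus = prod / (1.0 + prod)
        a_coop = np.where(coop_act, mu_plus, 1.0 - mu_plus)
        a_comp = s_act / (1.0 + s_all)
        a = np.where(comp, a_comp, a_coop)
        np.multiply.at(out, gene_idx, 1.0 - wts * (1.0 - a))
        return out


def transcription_fraction(gene: int, psi: np.ndarray,
                           promoter: PromoterModel) -> float:
    """Proportion of maximal transcription f_i(ψ) ∈ [0, 1]."""
    psi = np.asarray(psi, dtype=float)
    if gene >= len(promoter.modules):
        raise KeyError(f"no promoter entry for gene index {gene}")
    return promoter.fraction(gene, psi)


@dataclass
class KineticParams:
    """All rate parameters of the ODE system (per-gene vectors, rate matrices)."""

    m_rna: np.ndarray
    m_prot: np.ndarray
    lam_rna: np.ndarray
    lam_prot: np.ndarray
    lam_act: np.ndarray     # λ⁺, passive activation
    lam_deact: np.ndarray   # λ⁻, passive deactivation
    w_pos: np.ndarray       # activating P-edge rates (nonnegative, n×n)
    w_neg: np.ndarray       # deactivating P-edge rates

    def __post_init__(self):
        for name in ("m_rna", "m_prot", "lam_rna", "lam_prot",
                     "lam_act", "lam_deact", "w_pos", "w_neg"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"{name} must be nonnegative")
            setattr(self, name, arr)

    @classmethod
    def rates_from_weights(cls, w_p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split a signed P-weight matrix into (w⁺, w⁻) rate matrices."""
        return np.where(w_p > 0, np.abs(w_p), 0.0), np.where(w_p < 0, np.abs(w_p), 0.0)


@dataclass
class Perturbation:
    """Genetic perturbation of one or more genes: KO or overexpression."""

    genes: tuple[int, ...] = ()
    kind: str = "KO"           # KO | OE
    oe_factor: float = 4.0     # transcription-rate multiplier for OE

    def apply(self, kin: KineticParams) -> KineticParams:
        m_rna = kin.m_rna.copy()
        for g in self.genes:
            m_rna[g] = 0.0 if self.kind == "KO" else m_rna[g] * self.oe_factor
        return KineticParams(m_rna, kin.m_prot, kin.lam_rna, kin.lam_prot,
                             kin.lam_act, kin.lam_deact, kin.w_pos, kin.w_neg)


@dataclass
class SimState:
    r: np.ndarray
    p: np.ndarray
    psi: np.ndarray

    def pack(self) -> np.ndarray:
        return np.concatenate([self.r, self.p, self.psi])

    @classmethod
    def unpack(cls, y: np.ndarray, n: int) -> "SimState":
        return cls(r=y[:n], p=y[n:2 * n], psi=y[2 * n:])


def ode_rhs(state: SimState, kin: KineticParams,
            promoter: PromoterModel) -> np.ndarray:
    """Time derivative of (r, p, ψ) under the mass-action/Hill dynamics."""
    r, p, psi = state.r, state.p, state.psi
    if np.any(~np.isfinite(r)) or np.any(~np.isfinite(p)) or np.any(~np.isfinite(psi)):
        raise FloatingPointError("non-finite state in ODE right-hand side")
    psi_c = np.clip(psi, 0.0, None)
    f = promoter.fractions(psi_c)
    dr = kin.m_rna * f - kin.lam_rna * r
    dp = kin.m_prot * r - kin.lam_prot * p
    act = kin.w_pos @ psi_c + kin.lam_act
    deact = kin.w_neg @ psi_c + kin.lam_deact
    dpsi = act * (p - psi) - deact * psi
    return np.concatenate([dr, dp, dpsi])


def _default_init(kin: KineticParams) -> SimState:
    lam_rna = np.where(kin.lam_rna > 0, kin.lam_rna, 1.0)
    lam_prot = np.where(kin.lam_prot > 0, kin.lam_prot, 1.0)
    r0 = 0.5 * kin.m_rna / lam_rna
    p0 = kin.m_prot * r0 / lam_prot
    denom = kin.lam_act + kin.lam_deact
    frac = np.where(denom > 0, kin.lam_act / np.where(denom > 0, denom, 1.0), 0.5)
    return SimState(r=r0, p=p0, psi=p0 * frac)


def simulate_steady_state(net: RegulatoryNetwork, kin: KineticParams,
                          promoter: PromoterModel,
                          perturbation: Perturbation | None = None,
                          tol: float = 1e-6, t_max: float = 5000.0,
                          init: SimState | None = None) -> SimState:
    """Integrate to steady state (relative derivative norm < tol).

    Integration proceeds in chunks with a stiff-capable adaptive method
    (LSODA); convergence is declared when max_i |dy_i/dt| / scale < tol,
    where scale is the larger of |y_i| and the system's typical
    concentration.  Raises :class:`SteadyStateError` carrying the last
    state if t_max is exhausted first.
    """
    kin_p = perturbation.apply(kin) if perturbation is not None else kin
    n = len(kin_p.m_rna)
    state = init if init is not None else _default_init(kin_p)
    y = np.clip(state.pack(), 0.0, None)

    def rhs(t, yv):
        return ode_rhs(SimState.unpack(np.clip(yv, 0.0, None), n), kin_p, promoter)

    scale_floor = max(float(np.max(kin_p.m_rna / np.where(kin_p.lam_rna > 0,
                                                          kin_p.lam_rna, 1.0)),),
                      1e-3)
    t, chunk = 0.0, 50.0
    while t < t_max:
        sol = solve_ivp(rhs, (t, min(t + chunk, t_max)), y, method="LSODA",
                        rtol=1e-8, atol=1e-10)
        if not sol.success:
            raise SteadyStateError(f"integrator failed: {sol.message}",
                                   SimState.unpack(y, n))
        y = np.clip(sol.y[:, -1], 0.0, None)
        t = sol.t[-1]
        dy = rhs(t, y)
        rel = np.max(np.abs(dy) / np.maximum(np.abs(y), scale_floor))
        if rel < tol:
            return SimState.unpack(y, n)
        chunk = min(chunk * 2, 400.0)
    raise SteadyStateError(
        f"no steady state by t_max={t_max} (residual {rel:.2e} > tol {tol:.2e})",
        SimState.unpack(y, n))


def generate_logfc_dataset(net: RegulatoryNetwork, kin: KineticParams,
                           promoter: PromoterModel,
                           experiments: list[Perturbation],
                           tol: float = 1e-6, t_max: float = 5000.0,
                           noise_sigma: float = 0.0,
                           rng: np.random.Generator | None = None,
                           ) -> tuple[PerturbationDataset, SimState]:
    """Steady-state log₂ fold-change dataset for a list of perturbations.

    X[i, k] = log₂(r_i^(k) / r_i^(wt)), clipped to ±LOGFC_CLIP (a knocked-out
    gene has r = 0, hence logFC -∞ in exact arithmetic).  Optional Gaussian
    measurement noise is added to passively observed entries only.
    """
    wt = simulate_steady_state(net, kin, promoter, None, tol=tol, t_max=t_max)
    if np.any(wt.r <= 0):
        bad = [net.nodes.all_nodes[i] for i in np.nonzero(wt.r <= 0)[0]]
        raise ValueError(f"wildtype steady state has zero mRNA for {bad}; "
                         "network is infeasible for logFC readout")
    n = net.nodes.n
    K = len(experiments)
    X = np.zeros((n, K))
    J: list[set[int]] = []
    for k, pert in enumerate(experiments):
        st = simulate_steady_state(net, kin, promoter, pert, tol=tol,
                                   t_max=t_max, init=wt)
        with np.errstate(divide="ignore"):
            lfc = np.log2(np.where(st.r > 0, st.r, np.nan) / wt.r)
        lfc = np.where(np.isnan(lfc), -LOGFC_CLIP, lfc)
        X[:, k] = np.clip(lfc, -LOGFC_CLIP, LOGFC_CLIP)
        J.append(set(pert.genes))
    if noise_sigma > 0:
        rng = rng if rng is not None else np.random.default_rng()
        noise = rng.normal(0.0, noise_sigma, size=X.shape)
        for k, jset in enumerate(J):
            noise[list(jset), k] = 0.0
        X = X + noise
    return PerturbationDataset.from_experiments(X, J), wt
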