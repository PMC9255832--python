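# Methods

## The inference model

`phostf` infers signed regulatory edges from steady-state log₂ fold-change
(logFC) expression profiles of knockout (KO) and overexpression (OE)
strains.  Nodes are genes, partitioned into secondary regulators P (protein
kinases PK and phosphatases PP), primary regulators T (transcription
factors), and observed non-regulators O; R = P ∪ T, V = R ∪ O.

Each node carries an observed mRNA logFC `x_i` and an unobserved relative
activity `y_i` (the phosphorylation-state contribution); the combined
activity is `a_i = x_i + y_i`.  The model is linear and may contain cycles:

    x = W_T a + e_x        (transcriptional regulation, TF sources only)
    y = W_P a + e_y        (activity regulation, P sources only)

where `w_ij` is the effect of node j on node i, `w_ii = 0`, and the two
weight classes live in one matrix `W` under disjoint binary masks:
`W_T = W ⊙ M_T` (columns of T) and `W_P = W ⊙ M_P` (columns of P, rows of
R).  At equilibrium the activity variable can be eliminated:

    x = B x + e,      B = W_T (I − W_P)⁻¹.

`B` is the **total-effects** matrix: the summed influence of every node on
every mRNA level through all pathways, including cycles (convergent when
the spectral radius of `W_P` is below one).  `B` equals `W_T` on TF
columns; on P columns it holds accumulated secondary effects.

### Interventions

In experiment k the intervened nodes J_k are fixed at constants `c_k`
(their adjusted logFC) and are no longer transcriptionally regulated:

    x_k = U_k B x_k + U_k e_k + c_k,

with `U_k` diagonal, zero at intervened nodes.  Missing measurements are
excluded from the loss through the same mechanism rather than imputed
(imputation would inject signal the model would then "explain").

### Objective

Weights are estimated by minimizing

    SSE + λ‖B*‖₁,   SSE = ‖(I − B) X ⊙ U‖₂²,   B* = |W_T| (I − |W_P|)⁻¹,

with λ = 0.1 by default.  Regularizing the **accumulated-effects** matrix
`B*` instead of `W` leaves direct TF edges penalized exactly once and
penalizes secondary edges by their accumulated downstream influence;
taking absolute weights prevents two parallel cascades of opposite sign
from cancelling each other out of the penalty.  A corollary, visible in
the redundant-pair example, is that an edge whose downstream pathway
weights are near zero is almost free: such "dangling" candidates are
identifiable only through the data, not the penalty.

### Optimization

The cost is minimized with AdamW implemented in numpy with an analytic
gradient.  For `A = (I − W_P)⁻¹` and upstream gradient `G = ∂L/∂B`:

    ∂L/∂W_T = G Aᵀ,      ∂L/∂W_P = Bᵀ G Aᵀ,

and the regularizer uses the same identities on `|W|` with subgradient
`sign(W)` (0 at 0).  The gradient is validated against central finite
differences (relative error ≤ 1e-5) in the test suite.

Defaults: learning rate 0.01, moment decays (0.9, 0.999), decoupled weight
decay 0 (the penalty is explicit in the cost, decay would double-count),
epochs 15000 for the simulated benchmark and a cosine-annealed learning
rate.  Annealing is our choice: with a constant step, AdamW's
sign-normalized updates leave every flat direction oscillating at the step
scale (~1e-2), which buries weak true edges; annealing lets them settle
about two orders of magnitude lower.  Training keeps the spectral radius
of `|W_P|` below 0.95 by rescaling the secondary block whenever a step
overshoots — beyond that point the pathway sum `(I − |W_P|)⁻¹` stops
converging and the cost is meaningless.  Public solves refuse
`(I − W_P)` systems with condition number above 1e8 and name the nodes in
the offending secondary cycles.

Initialization: trainable entries are N(0, σ² = 1e-4) draws; in the
compendium (genome-scale) configuration, allowed TF edges start at ±1
according to the TF's mode of regulation and may be frozen; secondary→TF
entries may be seeded from rank tests (below).

Edge presence is scored as |w_ij| and the sign of w_ij gives the mode of
regulation.  Fixed epoch budget, no early stopping; the per-epoch
(SSE, λ‖B*‖₁) trace is returned for auditing.

## The simulator

Benchmark data come from an ODE model of transcription with
phospho-regulation.  Gene i has mRNA `r_i`, protein `p_i` and activated
protein `ψ_i` (0 ≤ ψ_i ≤ p_i):

    dr_i/dt = m_i^rna f_i(ψ) − λ_i^rna r_i
    dp_i/dt = m_i^prot r_i − λ_i^prot p_i
    dψ_i/dt = (Σ_j w⁺_ij ψ_j + λ⁺_i)(p_i − ψ_i) − (Σ_j w⁻_ij ψ_j + λ⁻_i) ψ_i

`w⁺/w⁻` are the positive/negative parts of the secondary weights;
`λ⁺, λ⁻` are passive (de)activation rates.  The promoter function
`f_i(ψ) ∈ [0, 1]` is a product of module factors `1 − α_m (1 − a_m)`:
each cis-regulatory module gates transcription with effect strength
`α_m ∈ (0, 1]` and activity `a_m`, a generalized Hill term.  Cooperative
modules use `a = Πρ/(1+Πρ)` (activating) or `1/(1+Πρ)` (repressing) with
`ρ_j = (ψ_j/k_j)^ν_j`; competitive modules, where several TFs contend for
one site, use `a = Σ_act ρ_j / (1 + Σ_all ρ_j)`.  A singleton full-weight
module is exactly the standard Hill activator/repressor; unregulated genes
transcribe at the maximal rate (`f ≡ 1`).

Steady states are found by chunked LSODA integration until the relative
derivative norm falls below 1e-6 (checked to be initial-condition
independent on stable systems).  A knockout sets the gene's transcription
rate to zero; overexpression multiplies it by 4 (matching a +1 logFC
adjustment convention, ~4× wildtype).  Readout is
`X[i,k] = log₂(r_i^(k)/r_i^(wt))`; the KO gene itself has logFC −∞, which
is clipped to −10 so data files stay finite, and that clipped value serves
as the intervention constant c.  Optional Gaussian noise can be added to
passively observed entries; the benchmark default is noiseless.

## Random network generation

The benchmark profile targets, per 100-node network: 20 TFs, 20 kinases/
phosphatases (3:1 PK:PP, as in the curated yeast sets), and mean edge
counts 13 P→T, 13 P→P, 25 T→P, 21 T→T, 102 T→O; actual counts are Poisson
around the means.  A scale-free template grown by preferential attachment
(or a user-supplied adjacency) supplies degree structure: sources are
drawn proportional to template out-degree, targets proportional to
in-degree, so both regulator hubs and co-regulated target hubs occur.
Each TF has a single mode (activator with probability 0.75, matching the
curated 191:65 activator:repressor split) stamped on all its outgoing
edges; secondary-edge signs are ±1 with equal probability.  Magnitudes
are uniform on [0.2, 1] and the incoming secondary rates of each target
are then normalized to sum to the decay scale — keeping edges sharing a
target individually weaker, which limits silent regulation by saturation.

Passive rates per protein follow the counterbalancing rule: with no
secondary input both equal λ_decay = 0.8; otherwise λ⁺ is λ_decay scaled
by the fraction of deactivating inputs and λ⁻ by the fraction of
activating inputs.  Checked by the closed-form fixed point
ψ/p = λ⁺/(λ⁺+λ⁻).

Promoter kinetics: Hill coefficients uniform on [1, 3]; dissociation
constants are first calibrated to each regulator's simulated wildtype
activity (so the operating point is responsive) and then scattered
log-uniformly over ±1 decade, leaving a realistic fraction of edges
partially saturated and hence weakly observable.  Multi-input promoters
are merged into a single competitive module with probability 0.5.  Module
effect strength equals the edge magnitude, so the signed weight matrix is
the ground truth in strength, not just sign.

This generator is a surrogate: it targets the published summary statistics
of the benchmark networks, not their exact construction (which we do not
have).  Hand-built demonstration networks (the four-motif and
redundant-pair examples) use clean operating-point kinetics with no
saturation scatter or competition, so their recovery behavior is crisp.

## Compendium-style priors

For genome-scale data the package implements the standard
network-construction steps, all data-source agnostic (plain TSV records):

- **Perturbed-node enhancement.** Measured logFC of a KO gene gets −4
  added (microarray cross-hybridization biases deleted genes toward zero;
  −4 ≈ 100-fold below wildtype), OE genes +1 (≈ 4× wildtype).  Additive,
  not replacement.
- **TF-edge mask.** Binding-evidence p-values are combined per edge with
  Fisher's method (dataset-level p substitutes for missing per-edge p;
  records without any p-value get the conventional 0.05) and filtered by
  Benjamini–Hochberg at q < 0.2.
- **TF mode of regulation.** Priority cascade: curated GO classification;
  then per-interaction mode evidence (Fisher-combined activating vs
  repressing p-values); then mean regulon logFC under TF deletion
  (targets drop when an activator is lost); then sign of TF–target logFC
  correlation.  A pure function of its inputs.
- **Secondary→TF initialization.** For each P with KO data and each TF,
  absolute logFC of the regulon is compared with the remaining genes by a
  one-sided rank-sum test; the initial magnitude is σ·Φ⁻¹ of (1−p) on the
  half-normal — the quantile-pinned version of an |N(0, σ²)| draw, so
  smaller p means larger |w| and the magnitude is monotone in p.  The
  sign is −sgn(T_i)·sgn(M̂), with M̂ the Hodges–Lehmann median difference
  of the signed regulon logFC versus the rest.  σ defaults to the
  training initialization scale (0.01); the magnitudes are not otherwise
  capped beyond the quantile floor at p → 0.
- **FDR filtering of trained edges.** q-values for |w| are not defined by
  the model, so the null is empirical: retraining on experiment-label-
  permuted data (default 20 permutations) and pooling trainable-edge
  scores, then per-family (P→T, P→P) BH at q < 0.05.  The filter refuses
  a null smaller than 10/q draws.  This null is conservative — permuted
  compendia are internally contradictory and the fit inflates weights on
  them — so on weak instances the filter may keep nothing.

## Evaluation

Signed ROC: candidates are mask-allowed, class-matching, off-diagonal
entries (structurally untrainable entries would deflate the false-positive
rate); prediction at threshold θ is w > θ for d(·,·,+), w < −θ for
d(·,·,−), |w| > θ otherwise; curves pool the merged candidate list across
networks with raw weights and AUC is trapezoidal.  Enrichment against
known edge sets uses one-sided Fisher's exact tests on the 2×2 over a
declared candidate universe.  Annotation-sharing odds ratios (shared-term
count ≥ threshold, inferred vs uninferred pairs) carry Woolf 95% CIs with
a flagged Haldane–Anscombe correction for empty cells.  The sign-vs-mode
χ² uses expected counts from the independence product rule (algebraically
the standard 2×2 contingency expectation) with 1 df.  Top-pathway
selection takes, for each shared-term threshold 1..6, the two most
positive and two most negative edge weights and returns the deduplicated
union.

## Benchmark problem sizes and what the tests show

The packaged benchmark runs 5 networks of 100 nodes with every regulator
knocked out once and 15000 training epochs per network (a few minutes on
one CPU); the pooled AUCs for secondary→TF regulation are stable at this
scale.  The synthetic compendium check uses four 30-node instances with
two noisy replicates per knockout (σ = 0.2 logFC).

Passing tests demonstrate recovery under the simulator's assumptions:
steady-state readout, single-gene interventions, edge effects large
enough to be observed, and no measurement artifacts beyond optional
Gaussian noise.  They do not establish performance on real compendia,
where unmodeled confounders (condition-specific silent regulation,
batch structure, protein-level measurements mixed with mRNA) dominate.

## Known limitations

- The generator reproduces summary statistics of the benchmark networks,
  not their exact topology-extraction procedure; primary-regulation
  recovery on our surrogate runs somewhat easier than the reference
  values for it, while secondary-regulation recovery matches.
- Relay ambiguity is inherent: a secondary regulator whose entire effect
  routes through one other regulator cannot be distinguished from a
  direct edge (the redundant-pair example); the regularizer bounds but
  does not remove the resulting extra edges.
- Deactivating-edge knockouts produce intrinsically weaker responses than
  activating ones (activity can only rise to its passive ceiling), so
  their recovered magnitudes are compressed.
- No uncertainty quantification; a single point estimate per run.
- Steady-state only; time-resolved data are out of scope.
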