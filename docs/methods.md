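# Methods

## Model

The package ranks proteins by combining two evidence channels:

1. **Network diffusion.** Proteins and their Pfam-style domains form one
   heterogeneous graph whose weighted adjacency is the symmetric block
   matrix `M_PD = [[W_PP, W_PD], [W_PDᵀ, W_DD]]` (protein nodes first, then
   domain nodes; each block built as described in the README). A random
   walk with restart is solved from every node twice — once over the intact
   node set (IS) and once with the walking vector masked after every hop to
   the node's key target convergence set (KTCS) — and the two stationary
   vectors are averaged (`R^ANS`).
2. **Annotation priors.** A subcellular-localization score (relative
   occupancy of the protein's most populated compartment) and an orthology
   score (conservation normalized by the cohort maximum), averaged into
   `Initial_Score ∈ [0, 1]`.

The final score of protein `p` is the mean of its prior and its stationary
walk mass on the domain block:

    Final_Score(p) = (Σ_{j ∈ domain nodes} R^ANS_{p,j}(∞) + Initial_Score(p)) / 2.

### Why the domain-block sum

The walk contribution could in principle sum the whole stationary vector
rather than its domain columns (`score_block="all"`, available as a config
variant). We made the cross-type block the default on mathematical grounds:
the unmasked stationary vector of a non-dangling node is a probability
distribution, so its whole-row sum is identically 1 and carries no
information; the whole-row variant therefore reduces to the masked walk's
retained-mass term alone. That term measures how much of a node's
transition mass survives projection onto its convergence set — on synthetic
data it mostly reflects the protein-vs-domain split of the node's edge
weights (a hub artifact) rather than essentiality, and in the planted-signal
study it degrades the ranking severely (top-10% accuracy 0.32 whole-row
vs 0.99 cross-block, against a 0.51 degree-centrality baseline). The
cross-block sum `K2`-style result matrix is also the quantity the model is
designed to predict essentiality from. Domain nodes are not assigned final
scores (they have no priors).

### Assumptions

- The PPI network is treated as a simple undirected binary graph:
  self-loops and duplicate/reciprocal records are dropped at parse time,
  because the interaction-profile kernel presupposes a symmetric 0/1
  adjacency.
- Proteins appearing in the domain/annotation tables but absent from the
  PPI network are dropped (logged; `restrict_to_graph=False` disables
  this). Proteins missing an annotation receive component score 0 rather
  than being excluded, so every network protein is scored.
- Essentiality correlates with network centrality and with annotation
  richness — the premises the method inherits from the
  centrality–lethality literature.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| `alpha` | 0.3 | restart weight of the walk; the stationary vector interpolates between the restart row (α→1) and pure diffusion (α→0). 0.3 is the operating point at which the model performs best and the ranking is insensitive to moderate changes (the test suite checks adjacent-α top-decile stability). |
| `tol` | 1e−6 | L1 stopping threshold between consecutive walk iterates. |
| `max_iter` | 10⁴ | hop budget; the map contracts by (1−α) per hop, so ~40 hops suffice at α=0.3 and hitting the budget signals a configuration error. |
| `ktcs_size` | 200 | convergence-set size per node. Meaningful only when smaller than the counterpart pool; on small synthetic networks choose a value that is a few percent to ~20% of the pool, otherwise the mask degenerates to the whole counterpart set and only removes same-type mass. |
| `gamma_prime` | 1 | bandwidth multiplier of the interaction-profile kernel. |
| `gip_mean_norm` | false | bandwidth denominator is the *sum* of squared profile norms (literal form); `true` uses the mean, the common convention elsewhere. |
| `ppi_overlap` | plain | shared-neighbour term divided by `(|N_i|+1)(|N_j|+1)`; `sqrt` divides by the square root of that product. |
| `ktcs_inf_policy` | exclude | candidates unreachable from part of a seed set average over the finite distances only; `strict` makes any infinite distance rank the candidate last. |
| `score_block` | cross | walk mass summed over domain columns; `all` sums the whole row (see above). |

## Numerical choices

- **Transitions and dangling nodes.** `W` row-normalizes `M_PD`; all-zero
  rows are left zero and recorded. A dangling node has a zero restart
  vector, zero walk mass, and final score `Initial_Score/2` — graceful and
  monotone. (With the default dense kernel weighting, dangling nodes do not
  arise; they can with degenerate inputs.)
- **Masking.** The KTCS mask is applied after every full update, so the
  masked map `R ↦ M[(1−α)WᵀR + αR(0)]` remains a (1−α)-contraction in L1:
  the fixed point exists, is unique, and is independent of the starting
  iterate. Nodes with an empty seed set (no domain annotation) skip masking
  and reuse their unmasked vector.
- **Batching.** All per-node walks are solved as one dense batched
  iteration (each column an independent restart problem — identical
  arithmetic to the per-node loop, which is kept as `propagate` and
  cross-checked in tests). A dense linear solve
  `α(I−(1−α)MWᵀ)⁻¹MR(0)` serves as the verification oracle on networks up
  to 500 nodes.
- **Ties and determinism.** KTCS candidates tie-break by ascending node
  index (stable argsort; infinite means sort last); rankings tie-break by
  ascending protein ID; top-k% cutoffs use `ceil(p/100·N)`, which
  reproduces the standard published cutoff counts for an 1,855-protein
  benchmark at 1/5/15/20/25%. ROC/PR sweeps group tied scores at one
  threshold and use trapezoidal areas, making AUROC equal the
  Mann–Whitney pair-counting statistic with half credit for ties.
- **Degenerate inputs.** An edgeless adjacency has an undefined kernel
  bandwidth and is rejected; empty domains are rejected at weighting time
  (they are already dropped at parse time); negative orthology scores and
  malformed table lines raise errors naming the line.

## Synthetic data

The generator emulates the structure of the yeast-style benchmark inputs:
a preferential-attachment (scale-free) PPI backbone; domain memberships
drawn from a power-law domain-popularity distribution with
Poisson-distributed counts per protein; compartment labels from a
geometric popularity distribution; orthology scores as uniform noise; and
an exact-count essential set. Four independent nonnegative biases plant
the signal and are all signal-free at zero: `degree_bias` (essentials
sampled ∝ degree^bias), `domain_bias` (essentials draw (1+bias)× more
domains), `subcell_bias` (essentials favor high-occupancy compartments)
and `hom_bias` (essentials' orthology scores shifted up by the bias). All
randomness flows from one seed through one generator, so outputs are
byte-reproducible.

What it does **not** emulate: the empirical degree distribution of
DIP/Gavin networks, correlated noise between annotation channels, false
positive/negative interactions, multi-database ID inconsistencies, or the
actual biology linking domains to essentiality. Passing the
planted-signal tests therefore shows that the pipeline recovers signal of
the assumed form at realistic sizes — not that it attains any particular
accuracy on real PPI data.

The planted-signal study (and the acceptance script) uses 500 proteins,
100 domains, 20% essential, unit biases and ten replicates — large enough
for stable rank statistics while the full study (two pipeline runs per
replicate plus baselines) completes in seconds.

## Known limitations

- Dense `float64` matrices throughout: memory grows as `(N_P+N_D)²`, which
  is comfortable to a few thousand nodes but would need a sparse or
  blocked walk engine at proteome scale with rich domain vocabularies.
- The kernel's logistic sharpening leaves a weight floor of 1e−4 between
  every protein pair, so the heterogeneous network is complete; distances
  of ∞ (and the `ktcs_inf_policy` distinction) only matter for degenerate
  inputs or user-supplied weight matrices.
- No ID reconciliation across naming systems; inputs must share one
  identifier vocabulary.
- Competing published predictors beyond the DC/NC/LAC centralities are not
  reimplemented; external rankings can be compared through
  `ktcspm evaluate --other`.
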