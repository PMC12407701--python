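# Methods

## The inference problem

Three genes — *eud-1* (a sulfatase), *sult-1* (a sulfotransferase) and
*nhr-40* (a nuclear hormone receptor) — form the core of the regulatory
network controlling the mouth-form decision (predatory vs. bacterivorous) in
the nematode *Pristionchus pacificus*. Bulk RNA-seq time courses measure the
three mRNAs at six developmental time points in three conditions (wild type,
*eud-1* knock-out, *sult-1* knock-out), but which protein regulates which
gene, and with which sign, is unknown. The package treats that structural
uncertainty head-on: it enumerates *every* admissible regulatory structure,
fits each one to the data, and asks which structures the data can actually
reject — the remainder forming a *model set* of practically indistinguishable
structures.

## Model family

Each modelled gene g contributes an observed mRNA M_g and a hidden protein
P_g:

    dM_g/dt = α_g + k_tx,g · F_g(P; K) − k_m · M_g
    dP̂_g/dt = M_g − k_p · P̂_g

with shared degradation rates k_m (mRNA) and k_p (protein). F_g is a product
of one or two Hill factors — activation P/(K+P) or repression K/(K+P) — in
the regulator proteins, with an optional square of a single factor
(cooperativity). With regulators {E, N, S} there are 24 admissible terms per
gene (12 single/squared + 12 two-factor products), hence 24³ = 13,824
wild-type structures; a knock-out removes the gene's equations and every
Hill factor in its protein, leaving 12 terms per remaining gene and
12² = 144 structures.

The untransformed model with explicit translation rate k_t carries a scaling
symmetry: (P, K, k_t) → (ξP, ξK, ξk_t) leaves the mRNA observables invariant
for any ξ > 0, so those parameters are not structurally identifiable.
Setting ξ = 1/k_t removes the symmetry; the package fits in these reduced
coordinates (proteins and half-max constants carry the translation rate
implicitly). `apply_scaling_symmetry` exposes the transformation on the
unreduced model so invariance is verified numerically rather than assumed —
a property test integrates 20 random parameter draws under ξ ∈ {0.01, 1,
100} and checks the observables agree to < 1e-6 sup-norm.

Half-max bookkeeping: the gene at wild-type position i ∈ {1,2,3} uses K_i
for its (first) Hill factor and K_{i+3} for the second factor of a
two-factor term, in all families.

Terms are enumerated in a fixed documented order (singles by regulator
E, N, S with activation before repression, then squared singles, then pairs
(E,N), (E,S), (N,S) with sign order aa, ar, ra, rr) and structures are
indexed by the 0-based mixed-radix integer over (eud-1, nhr-40, sult-1)
digits. Reference structures are exposed by name (`named_models()`):
`model_11574` (the synthetic-study ground truth), `unified` (the structure
found in the intersection of all three experiments' model sets), a
structurally similar candidate `near_11574`, and two structurally disjoint
candidates `distant_rich`/`distant_minimal` that share none of the truth's
21 binary features.

## Error model and likelihood

Observation noise is multiplicative: y = x·(1 + cv·Z) with Z standard
normal, matching the signal-proportional scatter of normalized RNA-seq
values. The negative log-likelihood for predictions x_i(θ) is

    −l(θ, σ) = n log σ + Σ_i log x_i + (1/2σ²) Σ_i ((y_i − x_i)/x_i)².

σ is a nuisance parameter with the exact profile σ̂² = max(σ_floor²,
(1/n) Σ ((y_i−x_i)/x_i)²); fits minimise the profiled objective over the
kinetic parameters only (joint optimisation would add one dimension for no
benefit). σ_floor = 1e-6. One global σ is shared across genes and
replicates. Any non-positive or non-finite prediction, or an integration
failure, evaluates to a large finite penalty (1e10) so that infeasible
parameter regions are cheap to traverse; a fit whose best value is the
penalty is flagged failed.

## Optimisation

Bounds: unscaled kinetic parameters (α's, k_tx's, k_m, k_p, mRNA initial
conditions) in [1e-5, 1e4+1]; translation-rate-scaled parameters (half-max
constants, scaled protein initial condition) in [1e-9, 1e8+1]. Starting
points are Latin-hypercube samples mapped log-uniformly over the interior
ranges [1e-4, 1e4] and [1e-8, 1e8]. Optimisation runs L-BFGS-B in log10
coordinates — the boxes span 9–17 decades, so log coordinates are the only
reasonably conditioned choice — with gradient tolerance 1e-8 and up to
1,000 iterations.

Free parameters per structure: the rates, shared degradations and mRNA
initial conditions; only the half-max constants its term actually uses; and
the scaled NHR-40 initial condition P̂_N(0) when N appears in at least one
production term (it is identifiable exactly then). The EUD-1 and SULT-1
protein initial conditions are fixed to a low preset (1e-3 scaled units,
configurable): expression of those genes is low in all experiments, and the
extra degrees of freedom are not identifiable in structures that never read
them.

Multi-start protocol: the default runs every start to convergence
(1,000 starts per structure at full scale). For budgeted triage the package
provides a screen-and-polish option (`FitOptions.race_budget`): every start
first runs under a small evaluation cap, then the `polish_top` best
finishing points (default 12) are warm-restarted and optimised to full
precision. Use it with care: on these sloppy landscapes the deepest optimum
of a well-specified structure is often a single basin in fifty whose depth
is invisible after a cheap screen (instrumented rank 19th-45th of 50 after
120 evaluations), so screened runs are suitable for coarse family-wide
triage but not for close comparisons between near-equivalent structures —
those use the full protocol. Per-start nll values are retained, so
nested-subset monotonicity (more starts never worsen the reported optimum)
is checkable directly.

## Numerics

Trajectory reporting (`simulate`) integrates with adaptive LSODA at
rtol 1e-8 / atol 1e-10 (configurable); negative excursions beyond −1e-9 and
solver failures raise `IntegrationFailure` rather than being clipped, so
parameter pathologies surface during fitting instead of being masked. The
optimisation hot path drives the same LSODA algorithm through the
lower-overhead `odeint` entry point (the numba-compiled right-hand side is
called with no Python wrapper) at rtol 1e-6 / atol 1e-9 with a 3,000-step
cap, returning a penalty instead of raising; the two paths agree to ~1e-6
on bounded trajectories. Ties on the cost curve are broken by model index;
ranking is a stable sort.

## Synthetic data

The generator emulates the study design: times (0, 12, 24, 48, 60, 72) h
post-synchronization, 4 replicates for wild type and 2 per knock-out, and
max-scaling of each experiment's values to [0, 1]. The default scaling scope
is one maximum per experiment (preserving the large expression differences
between genes, notably *nhr-40* ≫ *eud-1*, *sult-1*); per-gene scaling is
available as an option. Noise is applied to the true model trajectory;
draws below 1e-6 are truncated to that floor rather than resampled
(truncation is vanishingly rare for cv ≤ 0.3 on trajectories bounded away
from zero). The default experimental-regime noise level is cv = 0.2, a
realistic coefficient of variation for replicate-level bulk RNA-seq
expression values; it is configurable everywhere it appears.

The default ground-truth kinetic parameters (`default_true_params`) were
chosen so trajectories are positive, dynamic across the 72 h window, of
order 0.1–1 in scaled units, and actually traverse the Hill half-max
constants so each regulatory edge matters. What synthetic tests do *not*
emulate: count-level sequencing noise, library-size effects, temporal
asynchrony between replicates ("x-direction" error), or any stochasticity
of the underlying dynamics; passing them shows the pipeline's inferential
machinery works under its own assumptions, not that those assumptions hold
for a particular real dataset.

## Sweeps, thresholds and model sets

The misspecification sweep generates one seeded dataset per (sampling
count × cv) cell — matching a single heat-map value per cell — and refits
the true and several misspecified structures; repetitions are available for
stochastic statements. The default grid is counts {4, 6, 9, 13, 25, 73}
(equally spaced over [0, 72] h; the flagged "approximate experimental
regime" cell uses the uneven design times) by cv ∈ {0.02, 0.05, 0.1, 0.2,
0.35, 0.5}. Heat values are the best nll per cell; per-observation
normalisation is available since cells differ in n.

Acceptability on a cost curve is drawn either at a fixed rank (the
wild-type convention: the 1,000 lowest-cost structures of 13,824 ≈ the
plateau edge; null accuracy of labelling everything unacceptable is then
92.8%) or at the largest consecutive nll jump (the knock-out curves show a
single discrete gap). The 21 binary structural features (this package's
documented schema: per gene, regulated-by-E/N/S (9); any activation (3);
any repression (3); autoregulation (3); cooperativity (3)) feed a depth-5
decision tree (Gini, stratified 5-fold CV, seeded; entropy and a depth
sweep over 1–10 available; minority upsampling off by default as it
overfits). Model sets from different experiments are intersected by
projecting each wild-type structure through its knock-out reductions and
re-indexing in the knock-out family; a reduction whose term collapsed to
basal-only production has no knock-out-family counterpart and drops out.

## Problem sizes in the shipped tests and acceptance script

The full study scale (13,824 structures × 1,000 starts × 3 experiments) is
cluster work. The shipped test suite and `scripts/acceptance.py` exercise
the identical code paths at desk scale, as this package's own choice of
problem size: structure recovery fits 4 candidate structures with 50 starts
each, every start optimised to convergence (fitting tolerances rtol 1e-5 /
atol 1e-8 for these runs), over 1 seeded repetition of the dense low-noise
cell (73 hourly points, cv = 0.02) in the test suite — the acceptance
script repeats it over 2 seeded repetitions at 30 starts — and 2 seeded
repetitions of the experimental-regime cell, compared on per-candidate
medians: the single-draw nll margins in the experimental regime fluctuate
by several units, so replication, not a looser margin, is the right
control. The
screened multi-start protocol is *not* used for these comparisons:
instrumented runs showed the deepest optimum of the structured models is
typically one basin in fifty whose screen-stage rank is uninformative
(19th-45th after 120 evaluations), so capped protocols systematically
misrank the candidates. The acceptance script uses 40 starts with the same
design. The end-to-end pipeline smoke test
runs a 144-structure two-gene family on an index subset. All seeds derive
from a master seed via SHA-256 of (seed, stage, unit), so every number is
reproducible.

## Known limitations

* The acceptability threshold for the wild-type family is a fixed rank, not
  a statistical test; it inherits the arbitrariness of "the plateau".
* The decision tree explains acceptability in terms of the 21-feature
  schema only; structures misclassified near the threshold are expected
  (the cost-curve plateau is rounded).
* The screened multi-start can in principle leave the eventual-best basin
  outside the polish pool; the default protocol (every start to
  convergence) does not.
* The multiplicative error model is assumed, not estimated; weighted least
  squares or count-level error models are out of scope.
* At the experimental regime (six time points, cv = 0.2), a complex
  feature-disjoint structure — three two-factor all-repression terms,
  carrying more free parameters than the generating model — fits the
  synthetic data to within a few nll units of the true structure; only the
  minimal disjoint structure is clearly rejected there. Practical
  indistinguishability at that data quality extends further across the
  structure family than a feature-overlap notion of "similarity" suggests,
  and the corresponding check in the test suite records this as an expected
  failure of the strict separation margin (the test is left failing by
  design, not marked or skipped).
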