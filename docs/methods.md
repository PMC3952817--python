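# Methods

This note records the package's models, numerical choices, and the design
decisions taken where the design was genuinely open. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Optimal Scaling fitness

An ordinal observation places each observed cell in a rank r ∈ {1..N}. The
fitness of a model output y is the minimal relative error achievable by
surrogate data s confined to rank-ordered intervals:

- per cell e_i = ((y_i − s_i)/(ν + ε))², with ν the total variation of y
  **over the full germline geometry** (not just the observed cells) and
  ε = `epsilon_fraction`·S. ν penalizes flat outputs, the common trivial
  compromise; ε keeps the error finite when ν = 0.
- the observation error is sqrt(Σ_domains mean_{i∈domain} e_i), with one
  domain per observed region (GSC, CB, Cyst, Posterior), so a 7-cell region
  weighs the same as a single-cell region.
- a category objective is sqrt(Σ_observations Σ_domains mean e): the square
  root is taken per observation for reporting and once per category for
  optimization, i.e. category values aggregate the pre-root inner sums.
  (The per-observation-then-category root-sum convention is fixed here;
  aggregating after the root would weight observations differently.)

**Interval constraints.** With model scale S = max(y) − min(y) (falling
back to max|y|, then 1), the minimum interval range and inter-interval gap
are

    Δ_min = (2b/3)·S/N,     g_min = (b/3)·S/max(N−1, 1),

with budget b = `min_range_fraction_budget` = 0.75, so the N minimum
ranges consume b·2/3 of the scale and the N−1 minimum gaps b·1/3, and
N·Δ_min + (N−1)·g_min = b·S exactly for every N ≥ 2 — at most 75% of the
model scale is accounted for by the minimum allocation. The 2:1 split
between ranges and gaps mirrors the intuition that detecting *membership*
of a level needs more resolution than separating adjacent levels. For
N = 1 there is no gap and Δ_min = (2b/3)·S. Whether ε is absolute or
scale-relative was an open choice; it is scale-relative here (ε = 1e-6·S)
so the whole error is invariant under rescaling y.

**Solver.** Because the optimal surrogate for fixed intervals is y clipped
into its rank's interval, only the 2N boundaries are free. They are
parameterized by non-negative slacks (offset of the first lower bound
above the floor, extra widths, extra gaps), making all ordering/width/gap
constraints simple box bounds. The solver first runs a greedy leftmost
placement that decides exact-fit feasibility in closed form (and returns
the smallest-span, lexicographically smallest zero-error intervals — the
deterministic tie-break); otherwise it scans a coarse grid over the slacks
(dimension ≤ 6 only) and polishes the grid optimum plus deterministic
quantile-based seeds with L-BFGS-B. The problem is solved in units of S,
making the result exactly scale-invariant. Interval upper bounds are
capped at max(y) + Δ_min: unbounded intervals add no expressive power
under the clipping rule.

## Germarium model family

One-dimensional chain of 18 ODE compartments: the somatic cap cell (CC,
compartment 0) and 17 germline cells — GSC (cell 1), CB (2), Cyst (3–9),
Posterior (10–17). States: extracellular Dpp per compartment, bound
Dpp–receptor complex per germline cell (no receptors in the CC), and one
state per intracellular regulator per germline cell.

- **Ligand field:** dD/dt = D_c·(D_{i+1} − 2D_i + D_{i−1})/Δx² +
  secretion·[i=0] − k_on·D·R_free + k_off·C − δ_D·D, with ghost-node
  no-flux ends. R_free = R_tot − C; complexes internalize at first order.
  The full receptor/transducer equations of the original supplementary
  material are not public; the package uses the minimal standard
  ligand–receptor–transducer scheme behind one module boundary.
- **Regulators:** dX/dt = φ_X·Π_j h_j − δ_X·X, one Hill factor per
  incoming edge, h = K²/(K² + R²) for repression and R²/(K² + R²) for
  activation, cooperativity 2 throughout. pMad production carries an
  additional saturating factor C²/(k_signal² + C²) in the bound complex.
- **Conditions:** null/heterozygous/doubled scale the target's production
  (secretion for Dpp, receptor level for Rec, pMad production for Mad) by
  0/0.5/2; overexpression adds uniform ectopic production at
  `overexpression_rate` (a config parameter, not fitted — the real
  increase in Gal4-UAS-style overexpression is highly uncertain). The
  "null + overexpress" pair on one species encodes ectopic expression in a
  null background.
- **Protocols:** steady state is the state after 24 h of integration from
  a null (all-zero) state — deliberately *not* a root-finder solution, so
  slow transients count as such. The dynamic protocol approximates a cell
  cycle and displacement by setting each zone to the mean of its anterior
  neighbor zone (GSC keeps its own mean; extracellular states untouched)
  and integrating 12 h further. The phenotype output (fusome vs
  spectrosome) is the per-cell mean Brat over the trailing 6 h.
- **dMyc:** the growth regulator is present in all networks (it is
  perturbable in experiment design); the Core default wires it as
  Brat ⊣ dMyc with dMyc activating pMad production. Both edges live in
  the topology JSON, so alternative couplings are configuration, not code.
- **Numerics:** LSODA, rtol 1e-6, atol 1e-9, 15-minute output grid. A
  guard aborts an integration whose derivative goes non-finite or exceeds
  a 200 k-evaluation budget; failures are flagged and penalized with
  infinite objectives rather than raised, so global screens survive bad
  parameter corners.

## Search and Pareto front

All searching is in log10 parameter space with strict box bounds.

- **Screen:** a Smolyak sparse grid on nested Chebyshev–Gauss–Lobatto
  nodes takes at most 75% of the evaluation budget (the level is chosen
  automatically; if even level 1 = 2d+1 points exceeds that share the grid
  is skipped), and a seeded Latin hypercube (scipy.stats.qmc) takes the
  remainder. Desk-scale default: 2,000 samples, 8 local starts; the
  cluster-scale settings of the original study (500 k samples, 64 starts)
  are reachable through configuration.
- **Local refinement:** L-BFGS-B with numerical gradients from the best
  distinct screened samples. A bound-respecting quasi-Newton method plays
  the role an interior-point solver played in the original MATLAB
  workflow; results are clamped so a refined solution is never reported
  worse than its starting sample.
- **Anchors and NNC:** one anchor per category objective (multistart on
  that component; one shared screen serves all anchors). Anchor values
  define an affine normalization; the Utopian plane is the simplex of the
  normalized anchors, covered by an even barycentric lattice (default 5
  points per edge, 3 for the desk-scale recovery harness). For each plane
  point the solver minimizes displacement along the inward plane normal
  with a quadratic penalty (weight 1e4) on the squared distance from the
  constraint line — equality constraints on nonconvex objectives are
  fragile, a penalty is the "slight modification" adopted here. Searches
  are seeded from the sparse-grid polynomial interpolant of the screen at
  the plane point and at inward fractions {0.25, 0.5, 0.75} of the
  constraint vector (the original fractions are not printed; several
  inward offsets guard against local minima). Solutions plus anchors are
  deduplicated (parameter distance < 1e-6 log units) and Pareto-filtered
  (weak dominance, first duplicate kept).

## Sensitivity analysis

Forward finite differences with relative step h = 0.01 (forward, not
central, halves the simulation cost):
S = ((y(θ(1+h)) − y(θ))/(h·θ))·(θ/max(y, floor)), floor = 1e-12 × output
scale. Computed at steady state under Wild Type unless a condition is
given; failed perturbed simulations yield NaN entries that downstream
aggregation excludes.

## Network screening

Alternative wirings are subsets of the 12 non-self repression edges among
{pMad, Bam, Nos, Brat} over the fixed signaling backbone (4,096 without a
cap). The inhibitory screen is an exhaustive lattice: each edge's K at
{0.1, 10} × the regulator's reference level φ/δ (strong/weak; the original
levels are unstated). The signed screen replaces the lattice with a small
seeded global search over edge strengths. Acceptance is best Wild-Type
error ≤ 0.05 (configurable; the original threshold is unstated), and the
parsimony filter keeps accepted wirings containing no strictly smaller
accepted edge set. The package documents its own enumeration count (2^12)
rather than targeting the original study's ~65 k figure, which is not
reconstructible from the published description.

## Experiment design

Candidates are single and unordered pairwise perturbations from
{null, heterozygous, doubled} on {Dpp, Rec, Mad, Bam, Nos, Brat, dMyc}
(21 + 189 = 210 conditions) × a measured species.

Qualitative designs discretize each simulated output to binary region
calls by evaluating the Optimal Scaling error of all 2⁴ labelings against
*fixed canonical intervals* — the lowest interval hugging the output
minimum, intervals of width Δ_min spread so the highest ends at the output
maximum (gaps ≥ g_min). Anchoring the intervals is essential: free
(optimized) intervals make the all-low labeling vacuously exact, so
labeling must be judged against the output's own scale. Ties break toward
fewer "high" regions, then lexicographically.

Objectives (all per-cell quantities aggregate region-mean-then-sum so the
four regions weigh equally; variances are population variances because
representative counts differ between models):

- **Expected-prediction variance** (discriminate): variance over models of
  the per-region median prediction (ties → low).
- **Jaccard dissimilarity** (discriminate): Σ_{j<k} (1 − J_jk) with
  J_jk = 2|S_j ∩ S_k|/(|S_j| + |S_k|) over the models' *sets* of unique
  prediction vectors — set semantics, so duplicated representatives cannot
  change the score; zero means identical prediction sets, the number of
  model pairs means mutually exclusive ones.
- **Prediction variance** (refine): Σ_models of the per-region variance
  among that model's representatives.
- **Quantitative designs:** from sensitivity tables, variance over models
  of the representative-mean sensitivity (discriminate) or Σ_models of the
  variance among representatives (refine).

Design tables are min–max normalized per objective and ranked descending.

## Synthetic data

The generator simulates a known model under a list of (condition, dynamic)
pairs and discretizes region means into ranks by quantile thresholds of
the Wild-Type output of the same species and protocol. A region is
recorded only when every cell of the region falls in the same threshold
bin as the region mean, and marginal regions are dropped (smallest
threshold margin first) until the remaining cells admit an exact
rank-consistent interval assignment. This masking emulates a curator who
records only regions with a clear signal, and it guarantees the generator's
contract: with zero rank noise the generating parameters score exactly
(0, 0, 0) — an absolute acceptance floor for the pipeline. Rank noise
mirror-flips a region's rank (r → N+1−r) with the given probability,
deterministically under the seed.

The default study is a two-regulator repression chain (signal ⊣ A ⊣ B)
in the full 17-cell geometry with a sharpened ligand gradient
(diffusion 0.5 cell²/h, ligand decay 1/h) so regions are internally
near-homogeneous; it has 9 observations across all three categories and 4
free parameters, and desk-scale budgets recover it in minutes. What the
generator does *not* emulate: inter-experiment scale differences beyond
what per-observation scaling absorbs, curation ambiguity, image noise, or
conflicting observations — so passing recovery tests shows the machinery
is correct, not that real compiled data are this benign.

The packaged 25-row compiled dataset encodes published qualitative
interpretations; the per-region ranks are an editorial encoding (the
original work prints only example interpretations), each row carrying a
provenance note, with regions under unmodeled regulation (posterior Bam
repression by RBP9, late-cyst Nos re-expression) masked.

## Known limitations

- Ordinal data leave parameters heavily under-determined; zero-error
  Representatives can lie far from generating parameters (the recovery
  report's parameter distance is meaningful only for identifiable
  parameters).
- The receptor/transducer scheme and the dMyc coupling stand in for
  unpublished supplementary equations; both are isolated behind the
  topology/parameter configuration surface.
- The extended hypothetical mechanisms (endocytosis feedback, regulated
  diffusivity, miRNA intermediaries) are expressible as topology files
  plus the activation-edge form but are not part of the tested surface.
- Desk-scale budgets trade front density for runtime; fronts on the
  compiled dataset need cluster-scale budgets to be dense enough for
  model comparison.
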