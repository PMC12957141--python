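# Methods

This note documents the statistical machinery, the choices made where the
design was genuinely open, and what the synthetic data do and do not
establish.

## Niche-breadth statistics

**Tree-slicing phylogenetic diversity D_P.**  For an ultrametric host tree
of height T with distinct node ages 0 = t_0 < t_1 < … < t_m = T, each
interval [t_{k−1}, t_k] is an evolutionary period.  D_k counts the distinct
lineages ancestral to the parasite's hosts that cross the period — lineage
richness, treating all lineages as equally and maximally distinct.  D_P is
the period-duration-weighted mean of the D_k.  Numerical choices:

- Lineages are counted at period midpoints, which avoids tie-breaking at
  node ages (edges span half-open age intervals; ties occur on a set of
  measure zero).
- Node ages closer than 1e-9 · T are merged into one cut, so zero-length
  branches (e.g. from polytomy resolution) collapse naturally.
- An unweighted mean over periods is available (`weighting="equal"`), but
  duration weighting is the default: a lineage count that persists for nine
  tenths of the tree's history should dominate one that holds for a sliver.
- **Depth convention.**  When D_P is computed for an assemblage drawn from a
  larger host pool, the tree is pruned to the pool with the *original root
  retained* (`trees.prune` collapses unary nodes but never re-roots).  Both
  conventions — full-tree depth vs assemblage-MRCA depth — are defensible;
  full-tree depth is the default here because host specificity must
  distinguish a parasite of two congeners from a parasite of two distantly
  related hosts, and re-rooting at the assemblage MRCA erases exactly that
  contrast (both would span their subtree's full depth).

**Rao's quadratic diversity Q.**  With presence/absence data all S hosts get
weight 1/S, so Q = (1/S²) Σ_ij d_ij and Q = 0 for S = 1.  Abundance
weighting is deliberately out of scope: occurrence records are far more
reliable than abundance estimates in parasite surveys.

**Gower dissimilarity.**  d_ij = Σ_k w_k δ_ijk s_ijk / Σ_k w_k δ_ijk, with
s_ijk the range-normalised absolute difference for quantitative traits and
a 0/1 mismatch for categorical and binary traits; δ_ijk = 1 only when both
values are observed and the trait is informative.  Choices:

- Ordinal traits are compared on their integer ranks scaled by rank range
  (classic Gower); `ordinal_mode="categorical"` switches to pure mismatch.
- Missing values use pairwise deletion with denominator renormalisation;
  a species pair with no jointly observed trait is an error (the caller
  must impute or drop), because silently returning 0 or 1 would bias Q.
- Constant traits (range 0, or one observed level) are excluded with a
  warning rather than erroring, since subsetting a trait table to a host
  pool routinely produces them.
- Binary traits are symmetric: neither level is privileged (hibernation
  yes/no has no natural "presence" state).

## Tree preparation

- Newick branch lengths default to 1 when absent — the convention for
  topologies assembled from taxonomic literature without rate information.
- `force_ultrametric_extend` lengthens each terminal branch to the maximal
  root-to-tip depth, leaving internal branches untouched; it is idempotent.
- `resolve_polytomies` inserts zero-length internal branches in a seeded
  random order, so the cophenetic matrix is preserved exactly — the only
  property downstream statistics depend on.
- `consensus_with_edges` is a majority-rule (>50%) clade consensus whose
  retained edges carry the mean length over the trees containing that
  clade.  It is an approximation to edge-length-aware consensus methods for
  posterior tree samples: topologically standard, with a simple and
  transparent length summary.
- `taxonomy_to_tree` builds the four-level (family → subfamily → genus →
  species) unit-branch-length tree from a rank table; single-child rank
  nodes are retained so the result is exactly ultrametric with height 4 and
  rank-based cophenetic distances {2, 4, 6, 8}.

## Repeatability (ICC)

One-way Gaussian random-intercept model y_ij = μ + a_i + e_ij with
a_i ~ N(0, σ²_b), e_ij ~ N(0, σ²_w); R = σ²_b/(σ²_b + σ²_w).  The REML
criterion is profiled analytically: for a fixed variance ratio
θ = σ²_b/σ²_w, the GLS mean and σ²_w have closed forms, leaving a
one-dimensional maximisation in θ ≥ 0 (coarse log-grid plus bounded
refinement; the θ = 0 boundary is always evaluated).  Unbalanced group
sizes are handled natively — no subsampling or balancing.  This direct
implementation makes a parametric bootstrap of 1000 refits cost well under
two seconds.

- CIs are percentile (2.5%, 97.5%) intervals over parametric-bootstrap
  refits; SE is the bootstrap standard deviation.
- The test of σ²_b = 0 is a likelihood-ratio test on ML fits of both
  models against the 50:50 mixture χ²₀/χ²₁ (the null puts the parameter on
  the boundary).  Its empirical size at α = 0.05 sits near 0.03–0.05 —
  slightly conservative, as expected for the mixture approximation at
  moderate group counts.
- ICC is computed on raw metric values by default (`log_metrics` switches
  to logs); R is invariant under any affine transform of the values, so
  the choice matters only through distributional shape.
- If every observation is identical, both components are zero and R is
  reported as 0 with a warning.

## PGLS

The Brownian covariance V_ij is the shared root-to-MRCA path length.
Pagel transforms are composed κ → δ → λ (the convention of the comparative
methods this mirrors): κ powers each branch length (0^0 := 0) before V is
rebuilt; δ powers V element-wise and rescales so the maximal diagonal entry
is preserved (requires an ultrametric tree); λ scales off-diagonals.  An
alternative node-height formulation of δ exists; the element-wise form was
fixed here and is flagged wherever δ is reported.

- Estimation is GLS via Cholesky whitening (no explicit inverse);
  σ̂² = r'V⁻¹r/(n−p); coefficient tests are t-tests on n−p df.
- R² and F are computed in whitened space against the GLS intercept-only
  null, for both with-intercept and through-origin models (so the two
  variants are comparable); F = ((TSS−RSS)/q)/(RSS/(n−p)) with q the
  number of non-intercept predictors.
- Transform parameters are optimised by profile *maximum likelihood* (not
  REML), by L-BFGS-B from five starts (both bounds, midpoint, two seeded
  random points); bounds default to λ ∈ [0,1], κ, δ ∈ [1e-6, 3].
  Near-boundary optima are flagged in `fit.boundary`.  By default only λ
  is free with κ = δ = 1: joint three-parameter ML is weakly identified at
  comparative sample sizes, so freeing κ or δ is an explicit caller choice.
- **Intercept reporting rule.**  When the fitted intercept has p ≥ 0.05 the
  model is refitted through the origin and that variant reported (the
  discarded fit is kept in `alternative`).  This mirrors a common reporting
  convention in the comparative host-specificity literature, where
  through-origin equations appear whenever the intercept is indistinguishable
  from zero; α = 0.05 is a package choice.

## Analysis pipeline

- Filtering: commensal ubiquitous hosts (*Rattus rattus*, *R. norvegicus*,
  *Mus musculus*) and their characteristic ubiquitous fleas (*Xenopsylla
  cheopis*, *Nosopsyllus fasciatus*) are removed first; then any parasite
  with fewer than 3 hosts is dropped — within each region for regional
  matrices and on the pooled matrix for the continental matrix,
  *independently* (a parasite can be analysable continentally yet absent
  from a sparse region).  Filtering is idempotent.
- Characteristic abundance: per host, abundances are averaged within
  regions first, then across regions; the principal host is the argmax
  (ties break lexicographically, logged).  Species body size is the median
  of the average male and average female sizes — for two values, their
  mean — the convention for taxa with female-biased size dimorphism.
- Regression suites run in natural-log space (abundance and body-size
  suites), with the parasite tree pruned to the species present.  Regional
  models run only in regions with ≥ 8 parasite species; regions with fewer
  than 4 matched taxa after trait/tree matching are skipped and logged.
  The scale-comparison suite (mean regional vs continental breadth, species
  in ≥ 2 regions) runs on raw metric values.
- Host-pool regressions (species in ≥ 8 regions; log regional breadth on
  log regional host-pool diversity) are within-species across-region fits,
  so ordinary least squares is used: there is no cross-species phylogenetic
  covariance to model among conspecific observations.  A user-supplied
  covariance hook would slot into `gls_fit` directly if a correlation
  structure across regions were ever wanted.
- Significance tallies use α = 0.05 per model with no multiple-testing
  correction, matching the per-region starring convention of comparative
  survey analyses; the full p-values are always in the output tables.

## Synthetic data

The generator emulates a mid-sized multi-region ectoparasite survey.
Defaults (all overridable): 40 hosts, 60 parasites, 15 regions; pure-birth
trees (birth rate 1) rescaled to height 1, with terminal branches extended
by one waiting time so the youngest cherry is not degenerate; 7
quantitative traits by unit-rate Brownian motion, 1 ordinal trait (a
Brownian trait cut into 5 quantile ranks), 3 categorical and 2 binary
traits by rate-1 Markov switching — mirroring the 13-trait mix of real
host-trait compilations.

Incidence structure: each parasite has a focal host; per occupied region
its hosts are drawn without replacement with weight ∝ exp(−θ·d) in
patristic distance d to the focal host (θ = 3 by default; θ = 0 is a
uniform generalist, large θ a strict phylogenetic specialist).  Region
occupancy is beta-distributed per parasite (mean 0.3, concentration 2), so
most species occur in few regions and a minority are widespread, giving
regional species counts (~10–20) and widespread-species counts like those
of real surveys.  Host-set sizes vary log-normally between parasites and
between regions within a parasite.

Within-species repeatability is calibrated by pilot simulation: the
realized ICC of regional log D_P decreases monotonically in the probability
that a parasite's focal host is regionally redrawn from the pool
(principal-host shifts, a documented phenomenon in these taxa), so pilot
passes at shift ∈ {0, 0.3, 0.6, 0.9} trace that curve and the target ICC
(default 0.12, the weak-repeatability regime) is hit by interpolation.  The
calibration is approximate — realized ICCs scatter around the target — and
no closed form exists for the mapping.

Responses: log CA = a + b_CA · log D_P(continental) + ε with b_CA = 0.3 and
ε multivariate normal under a λ-transformed Brownian covariance on the
parasite tree (λ = 0.5, sd 0.15 — chosen so the continental
abundance–breadth effect has the moderate strength, R² ≈ 0.2–0.5 at n = 60,
that a detectable continental signal implies); log body size is generated
from log D_P with slope −0.5 (sd 0.2), the continental-scale negative
size–breadth regime.  Record-level abundances are rescaled so that each
parasite's region-mean abundance peaks on its focal host at the simulated
characteristic abundance, making the principal-host derivation and the
response table mutually consistent.

**What the synthetic data do not show.**  Trees are pure-birth (no
extinction), traits are evolutionarily independent of each other and of the
incidence process (real host traits are correlated and co-drive
parasitism), regions have no spatial arrangement, and sampling effort is
uniform.  Passing tests therefore demonstrate that the estimators recover
known structure of the assumed forms — not that real survey data satisfy
those forms.

## Problem sizes in the checks

The verification suite uses 200 simulated datasets of 100 taxa for PGLS
recovery, 1000 replicates of a 50-species × 4-region design for ICC bias,
2000 null datasets for LRT size, and the default 60-parasite/15-region
bundle for the end-to-end run — sizes at which the Monte-Carlo error of
each summary is well inside its assertion band.

## Known limitations

- The consensus is clade-based majority rule; it does not reproduce any
  specific posterior-summary tool's tie-breaking or compatibility handling.
- The δ transform operates on the covariance matrix, not on node heights;
  the two differ for non-ultrametric trees (where δ is disabled anyway).
- ML (not REML) transform optimisation gives slightly downward-biased σ̂²
  at small n, as is standard for comparative ML fits.
- The hierarchical-clustering route from a taxonomy to a dendrogram is
  collapsed into the direct rank-tree construction; the net object (an
  ultrametric rank tree) is identical, intermediate objects are not built.
- `pgls_ml` with all three transforms free can sit on ridge-shaped
  likelihoods; the multi-start reports the best optimum and flags bounds,
  but users should inspect `boundary` before interpreting κ or δ.
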