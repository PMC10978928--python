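# Methods

## Phylogenetic diversity and phylobetadiversity

A `Phylogeny` is a rooted tree with non-negative branch lengths; tips carry
unique labels.  Ultrametric input is expected for the biological questions
here but is not enforced (`Phylogeny.is_ultrametric` checks it).

An assemblage's **branch set** is the union of edges on the root-to-tip
paths of its species.  We use the *rooted* convention — paths run to the
tree root, not to the assemblage's most recent common ancestor — so that
Faith's PD of the complete species pool equals the total tree length, and
pβ between assemblages on disjoint subtrees is maximal.  This matches the
behaviour of the standard branch-length beta-diversity implementations in
the R ecosystem.  The MRCA convention is the main alternative; it changes
PD by the depth of the subtree root and is deliberately not offered, to
keep one unambiguous definition.  Zero-length edges are legal and carried
by identity (set membership is by edge id, never by length).

Pairwise dissimilarity uses the Sørensen-family partition on branch
lengths: with `a` shared length and `b`, `c` unique lengths,

    sim = min(b, c) / (a + min(b, c))     # turnover
    sor = (b + c) / (2a + b + c)          # total
    nes = sor − sim                       # nestedness-resultant

`sor = sim + nes` holds to machine precision by construction.  If every
relevant edge has zero length the pair is returned as all-zero with a
warning.  The matrix builder computes one boolean cells × edges indicator
and evaluates all pairs with weighted matrix products; empty cells are
rejected, or dropped with a warning when `drop_empty=True` (regressions
downstream need complete rows).

## Functional space

Mixed-type traits are combined with Gower dissimilarity: continuous
columns optionally log- or sqrt-transformed then range-scaled, percentage
columns divided by 100 and treated as continuous, categorical columns by
0/1 simple matching; per-column weights default to 1 (diet-style blocks
are *not* down-weighted; block weighting can be expressed through the
per-column weights if desired).  Zero-range columns are dropped with a
warning rather than poisoning the denominator.

PCoA double-centers −½D² and keeps the first `m` positive-eigenvalue axes
scaled by √λ.  Negative eigenvalues (Gower matrices are generally
non-Euclidean) are truncated and counted, not corrected — no
Cailliez/Lingoes constant — because truncation is reproducible and the
retained-axis geometry is what the hull volumes are computed in.  `m`
defaults to 4 axes, with 3 appropriate for smaller pools (the
reduced bat-like configuration).  Axis signs are fixed deterministically
(largest-magnitude coordinate positive).

Functional richness of an assemblage is its convex-hull volume divided by
the pool hull volume (Qhull).  Cells with fewer than `m + 1` species, or
with point sets that do not span an `m`-volume, yield a missing value with
a reason code (`too_few_species` / `degenerate`) and are excluded from
both focal and partner roles downstream, with the exclusions reported.

Functional beta diversity needs the **exact** intersection volume of two
hulls: the half-space representations are stacked, an interior point found
as the Chebyshev center by linear programming (empty or flat intersections
return volume 0), and the intersection polytope's vertices enumerated with
Qhull.  A seeded rejection-sampling estimator exists in the test suite as
an independent oracle only.  The turnover/nestedness partition mirrors the
branch-length one with volumes in place of lengths; turnover is 0 when one
hull nests inside the other and 1 when they are disjoint.

## Ordination

NMDS minimizes Kruskal stress-1 over unordered pairs,

    stress = sqrt( Σ (d − d̂)² / Σ d² ),

where d̂ are least-squares monotone fits of configuration distances on the
dissimilarity order (pool-adjacent-violators; tied dissimilarities are
averaged within blocks before the PAV pass).  Each start alternates the
monotone fit with a Guttman/SMACOF update; disparities are renormalized to
a fixed norm (Σd̂² = number of pairs) before each update — without this the
configuration scale decays geometrically toward zero while stress-1, being
scale-free, looks healthy, and downstream quadratic terms underflow.
A start terminates when the stress improvement falls below `tol` (1e-7) or
when an update would raise stress (the previous configuration is kept), so
the recorded trace is non-increasing.  Defaults: 500 iterations, 20 starts
(start 1 is the classical metric scaling of the input; the rest are seeded
random configurations).  The best solution is centered, rotated to
principal axes, and sign-fixed, making "axis 1/2/3" labels deterministic.

## Regression and variance partitioning

The environment design is PC1–PC4 of the climate correlation matrix (skewed
precipitation-like variables sqrt-transformed first, signs fixed by largest
loading) plus their squares, mean elevation and its square, elevational
range, and log landmass area — 12 predictors.  The isolation design is the
second-order trend surface over the NMDS axes (3 linear + 3 quadratic + 3
interaction terms for k = 3; a generalized surface with a warning
otherwise).  Because NMDS axis values carry no intrinsic meaning, only the
surface over them does, which is also the only spatial-autocorrelation
handling used.  The discrete alternative replaces the surface with realm
dummy variables (alphabetically first level as reference).

OLS is solved by least squares with an explicit rank check on
column-normalized predictors (predictors span ~10 orders of magnitude, so
an unnormalized rank test silently passes or fails by scale); collinear
columns are named in the error.  Adjusted R² uses
`1 − (1 − R²)(n − 1)/(n − p − 1)`.  The partition reports
`unique_iso`, `unique_env` and `shared` exactly as adjusted-R²
differences; slightly negative fractions are a known property of this
partition and are reported unmodified.  The candidate-variable screen
(`delta_adjr2`) compares nested fits with a configurable threshold
(default 0.01).  Residual-difference maps are per-cell
`|resid_env| − |resid_global|`; positive means isolation improved the fit
for that cell.  Prediction summaries report medians and ranges of
predictions vs observations over a named cell subset and their percent
difference.

## Phylogenetic signal

Blomberg's K follows the variance–covariance formulation (C from shared
root-to-MRCA path lengths; observed MSE₀/MSE against its Brownian
expectation); K ≈ 1 under Brownian motion, → 0 without signal.

Fritz–Purvis D scores a binary trait by the sum over internal nodes of
absolute sister differences in nodal values obtained by averaging states
down the tree, located between two seeded reference ensembles (1000
simulations each by default): tip shuffles (D = 1) and Brownian traits
thresholded to the observed prevalence (D = 0).  A trait whose presence is
exactly one clade is *more* clumped than Brownian and scores well below 0;
that is a property of the statistic, not an error.  Because K and D run in
opposite directions, D is also reported rescaled as 1 − D so that larger
always means stronger signal; this matches orientation, not range, and is
the package's choice where no canonical rescaling exists.  Multi-state
categorical traits are scored one-vs-rest per state.

## Synthetic worlds

The generator emulates the study design at desk scale, with ground truth
recorded for every run (`truth.json` is sufficient to regenerate a world
bit-identically).

* **Phylogeny** — one birth–death clade per realm (endemics) plus one
  cosmopolitan clade holding a `mixing` fraction of the pool, each
  simulated forward (Gillespie), pruned of extinct lineages, normalized to
  depth 1 and grafted onto a common root with 0.5 stems; ultrametric by
  construction.
* **Traits** — continuous traits by Brownian motion (body mass on the log
  scale), a diet-style percentage block by softmax of Brownian deviates
  (rows sum to 100), a categorical foraging stratum by a continuous-time
  Markov chain.
* **Environment** — six climate variables following a pseudo-latitudinal
  gradient with per-cell noise; the precipitation-like ones are generated
  skewed (squared), so the pipeline's sqrt de-skew is the appropriate
  inverse.  Elevation and landmass area are independent nuisance columns.
* **Occupancy** — range-map style: each species has a Gaussian climatic
  niche on the *dominant climate axis of the realized environment table*
  (PC1, min–max rescaled) and occupies every cell of its realm whose
  position falls inside its tolerance window.  Presence is deterministic
  given the species-level draws, mirroring presence defined by gridded
  range polygons; there is no per-cell sampling noise.  Niche optima
  follow a linear density (denser at the productive end), sampled on a
  domain padded by the maximum tolerance width with flat extensions, so
  expected richness is linear along the gradient with no boundary droop.
* **Isolation** — each species independently fails to establish in the
  designated realm with probability 1 − ρ (whole-range exclusion), so the
  realm's expected richness is ρ times its environmental potential while
  its composition becomes distinctive — both signatures of deep isolation.

Two modelling choices deserve emphasis, because they were forced by
validity requirements of the null condition (ρ = 1, mixing = 1, where the
pipeline must find *no* unique isolation signal):

1. *Per-cell Bernoulli occupancy is not used.*  Independent per-cell draws
   couple a cell's random richness excess to its position in pβ_sim space
   (a richer cell shares more branch length with everyone), which the
   trend surface reads as isolation structure.  Range-map determinism
   removes that coupling — and is closer to how real gridded range data
   behave.
2. *The richness–environment relationship is kept expressible by the
   environment design.*  The niche axis is climate PC1 itself, and the
   expected richness profile is linear by construction; curvature the
   12-term environment design cannot represent would otherwise be mopped
   up by the 9-term NMDS surface and booked as isolation.  The recovery
   worlds also use a large pool (2000 species over a 10 × 20 grid, 4
   realms), since finite-pool roughness in richness along the gradient
   projects onto low-order polynomials with share ∝ 1/S.

What the generator does **not** emulate: spatially contiguous 2-D range
shapes (ranges are climate-band intervals), dispersal kinetics, trait-
dependent occupancy, observational error, and richness-dependent trait
filtering.  Passing recovery tests therefore shows the *inference
machinery* attributes variance correctly under a clean data-generating
process; it does not certify behaviour under real range-map artifacts.

## Problem sizes and tolerances

Worked fixtures are exact (1e-12 where float arithmetic is involved).
Oracle comparisons: 200 random tree/assemblage pairs at 1e-12;
hull-intersection volumes within 1% of a seeded 10⁶-point rejection
sampler (generated pairs keep intersection fractions large enough that the
Monte-Carlo standard error is well below that).  Recovery experiments use
the 200-cell worlds with 8 NMDS starts (the engine default stays 20; at
this matrix size eight starts reach the same basin, and start 1 is the
deterministic metric-scaling seed).  D uses 1000-simulation ensembles; the
K calibration uses 500 Brownian replicates on a 64-tip tree.  The
demonstration world is 30 cells / 3 realms / 120 species so the complete
pipeline, including all pairwise 4-D hull intersections, runs in seconds.
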