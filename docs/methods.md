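# Methods

This note records the scientific and numerical choices behind
`psishent`: what is computed, under which conventions, and what the
synthetic tests do and do not establish.

## Data model

**Compositional grids.**  The primary input is a rectangular lattice of
cells, each carrying, per time step, a fraction of occupation for every
category of a categorical variable *C*.  Fractions are non-negative and
sum to at most 1 per (cell, time); a deficit is treated as
unclassified ground and is *not* renormalised away by default
(`CompositionGrid.renormalised()` is explicit, because renormalising
after excluding categories changes every entropy downstream and the
right choice depends on whether the excluded mass is meaningful).
Cells are addressed by 0-based (row, col); time indices are 0-based;
all interval-like bins are closed-open unless a class label says ">".

**Observations.**  `to_observations` converts a grid to point records
either by the dominant category per (cell, time) (weight = its
fraction; exact ties broken deterministically by lowest category index
and logged) or by one record per (cell, time, category) above a
threshold (weight = fraction).  Dominant ties are rare in continuous
data but the tie-break must be fixed for reproducibility.

## Patches and descriptors

A **spatial patch** is a connected component of cells with
fraction(*c*) strictly greater than the threshold (default 0.15) at one
time; connectivity defaults to 4-neighbour (8 available; the patch
count under 8 is never larger).  Patches of different categories are
computed independently and may overlap — a cell belonging to several
patches contributes once per patch in cell-based counting; no overlap
resolution is applied by default (use the dominant rule in
`to_observations` when a separation is wanted).  A **temporal patch**
is a maximal run of consecutive above-threshold time steps at one cell.

**Size classes.**  `SizeClassing` maps every positive integer to
exactly one ordered class given by lower bounds.  The shipped defaults
are the classings of the reference land-cover study: spatial
1, 2, >2, >7, >25, >50, >100 (so ">25" covers 26–50) and temporal
1, 2, >2, >4, >7, >20, >30, >60.  The temporal grouping has no stated
rationale in the source study; it is user-replaceable.

**Shape features** (spatial patches only): area = cell count;
perimeter = number of exposed unit cell edges (4·area − 2·adjacencies);
compactness = 4π·area/perimeter², clipped to (0, 1]; elongation = the
square root of the ratio of the principal-axis eigenvalues of the
member-cell layout.  Raw coordinate covariance is singular for single
cells and straight lines, so each cell is given its unit-square extent
(adding 1/12 to each diagonal term): a single cell then has elongation
exactly 1 and a 1×N line a large finite value.  `classify_shapes` runs
seeded k-means on standardised features; zero-variance features are
left unscaled, and degenerate inputs (all patches identical) collapse
into one effective class.

**Ordinal motifs.**  A window (x_t, x_{t+τ}, …, x_{t+(l−1)τ}) is
labelled by the 1-based positions of its values in increasing order
(e.g. values (1, 3, 2) → "132"); a series of length N yields
N − (l−1)τ windows.  Differences smaller than the minimum meaningful
difference δ (default 0) count as ties and are resolved by stable time
order (earlier index first), with a tie counter reported; chains of
pairwise-near values are ordered by the same insertion rule, which is
the documented behaviour for δ > 0.  The refined l = 3 split appends
"t" when the first gap of the sorted values is ≥ the second ("the
larger change first" for an increasing triple) and "b" otherwise.  The
direction of this inequality is stated ambiguously in the literature
the split comes from, so the convention is explicit and flippable
(`tb_first_gap_large=False`).

## Multiway tables

`MultiwayTable` is a named-mode non-negative tensor with total mass N,
joint probability p = values/N and one-mode margins.  Three statistics
fill it:

- **Occurrences** (`occurrence_table`, `patch_size_table`): unit
  weights accumulated per label combination.  `count_unit="cell"`
  counts grid-cell patch memberships (large patches therefore dominate
  — a deliberate topological forcing); `count_unit="patch"` counts each
  spatial patch once, cancelling that baseline; the patch's temporal
  class is then the modal class over its member cells (ties to the
  smaller class).
- **k-co-occurrences** (`cooccurrence_table`): unordered k-subsets
  (counting ordered tuples would inflate everything by k!) whose
  pairwise distances satisfy the collocation rule.  The asymmetric form
  works within spatial snapshots with a common category; the symmetric
  form applies the per-dimension distance-rule (dS ≤ dεS, dT ≤ dεT,
  dC ≤ dεC, the category dissimilarity defaulting to the 0/1
  indicator) — no composite S×T×C metric is offered because mixing the
  scales is not well defined.  Categorisation of a symmetric
  co-occurrence is strict (all labels common), majority (per-dimension
  vote, lowest-label tie-break, ties counted) or fuzzy (a dimension
  whose pairwise distances all fall within the tighter radius
  contributes every member label, one count per valid combination).
  Border overlap: with d_border > 0 (recommended < dεS, e.g. dεS/2) a
  subset may include same-time observations from a neighbouring
  stratum within d_border of an inside member; cross-border subsets
  can be counted in more than one stratum and are intentionally not
  deduplicated (a small documented over-count, preferable to the
  under-count at borders).
- **Distance-ratio weights** (`distance_ratio_table`): mean
  within-category pair distance over mean between-category pair
  distance per (s, t, c); small values mean clustering, and an
  inverted variant is available since the entropy machinery expects
  "large = frequent".  W uses distinct unordered within-category pairs
  (ordered pairs would include zero-distance self-pairs).  The
  symmetric variant follows the neighbourhood rule as printed in its
  source — W: both observations within the radius of *some* member of
  the cell's observation set; B: one within the radius of some member,
  the other at distance ≥ the radius from *all* members — the
  asymmetric quantifier mix is implemented as stated and flagged here
  for review.  Cells with empty W or B are undefined, excluded from
  normalisation and reported.

## Entropy decomposition

Plug-in Shannon entropy in natural log, 0·log 0 = 0; no bias-corrected
estimators (the framework is descriptive, not inferential).  Normalised
entropy Hu = H/log(n) is base-invariant; a 1-label mode returns Hu = 1
(degenerate-uniform convention) with a warning.  `decompose` computes a
conditioning chain H(X1) + H(X2|X1) + …, its normalised counterpart
with log-cardinality weights, and the multiway mutual information, and
*asserts* the chain rule, the weighted-sum identity and the
H − ΣH_mode + MI identity at 1e-9 absolute, reporting the largest
residual.  Empty conditioning strata contribute zero.  The
conditional-entropy ratio p_s·H(C|S=s)/H(C|S) is identical on raw and
normalised scales (the normalisation cancels); it is NaN when the
conditional entropy is zero.  `map_statistic` restricts the ratio to
the conditioning labels occurring at each cell (the classes of the
patches covering it) and reports a percentage of the global conditional
entropy; cells with no patches are missing values, read as local
uniformity by absence.

## Multiway correspondence analysis

The ratio tensor z = p/(p_S ⊗ p_T ⊗ p_C) is decomposed greedily:
component 0 is the exact independence term (σ0 = 1, all-ones vectors),
and each further component maximises the margin-weighted projection of
the residual onto a rank-one tensor.  Numerically the weighted problem
is transformed to a plain one (multiply z by √ of the margin product;
weighted unit norms become Euclidean), solved by higher-order power
iteration with an HOSVD-style initialisation plus seeded random
restarts (default 8; the objective is non-convex and the restart with
the largest σ wins), and every mode vector is Gram–Schmidt-projected
against the same mode's vectors of all previous components.  Sign
indeterminacy is fixed by making the largest-magnitude entry of the
last (category) mode positive.  Convergence: relative σ change below
1e-12 or 500 iterations, non-convergence flagged per component.

Consequences of this design, chosen over the full nested
principal-tensor hierarchy because only the leading rank-one terms and
their CTRs are interpreted downstream:

- for two-mode tables the procedure reproduces classical
  correspondence analysis (SVD of standardised residuals) to 1e-8, and
  a full decomposition satisfies Σσr² = 1 + χ²/N;
- for three or more modes the per-mode orthogonality bounds the number
  of extractable components by the smallest mode cardinality and the
  greedy expansion is not complete in general, so variability shares
  σr²/(1 + χ²/N) always use the χ² identity denominator computed
  directly from the table, never a truncated sum.

Empty labels are dropped before analysis (zero margins break the ratio
tensor) and reported.

**CTR summaries.**  Per component, the CTR vectors p·v² each sum to 1;
the CTR-tensor is their outer product; signed per-label percentages
100·p·v²·sign(v) give the familiar contribution tables.  The combined
CTR entropy is the log-cardinality-weighted mean of the per-mode Hu
values, which equals the joint Hu of the product tensor exactly.

**Positive split.**  A signed rank-one term with factors u = p·v is
expanded over the 2^k sign patterns of (u⁺, u⁻); even-parity patterns
form the positive part, odd the negative, each with at most 2^(k−1)
terms (4 for three modes), all pairwise orthogonal by disjoint
supports, reconstructing the term exactly (tested to 1e-12).  Each
non-negative term is renormalised into latent per-mode distributions
with scaling μ = Π(Σ factor), on which `entropy_ratios` reports each
mode's share of the additive joint entropy (NaN when the joint entropy
is zero).

**Map scores.**  `signed_scores` assigns each cell the k-th root of the
product of its labels' CTR weights, signed by the category-mode vector
entry — a spatial intensity of the component's pattern.

## Synthetic generator

`simulate_composition` draws, per category, a unit-variance spatially
smoothed Gaussian field (correlation length in cells, default 3) scaled
by a patch-intensity amplitude (default 2), adds a linear logit trend
per step and an independent smoothed space-time noise field (default
0.15 logit units), and applies a softmax across categories.  This
guarantees exact compositions, spatially contiguous dominant-category
patches whose typical size grows with the correlation length, and
smooth monotone prevalence trends — the qualitative features of a
multi-decadal land-cover forecast at coarse resolution.  It does *not*
emulate climate forcing, abrupt regime shifts, spatially varying trend
fields, or inter-category dynamics; passing tests therefore establish
the correctness of the machinery on realistic-looking compositional
data, not any claim about a particular earth-system simulation.
Defaults used in tests and the CLI (12×12 cells, 40 steps, 6
categories; 10×10×30 with 11 categories for the study-shaped checks)
are desk-scale choices keeping full runs in seconds while leaving all
seven spatial and eight temporal size classes reachable.

`make_rank_structured_table` builds p = W·(1 + σ*·v1⊗v2⊗v3) with
random Dirichlet margins and per-mode vectors of zero weighted mean and
unit weighted norm, so the margins of p equal the construction margins
and σ* is the exact first singular value — the oracle for recovery
tests.  Perturbations large enough to create negative cells are
rejected with a hint.

`worked_example_fixtures` ships the printed values of the reference
boreal land-cover analysis (entropy decomposition per year, weights
0.4479736/0.5520264 for cardinalities 7 and 11, per-component CTR
entropies and signed CTR tables, size classings); the running text and
the printed table disagree on one value (0.595 vs 0.596 for the
independence tensor's temporal entropy), so both are kept and
comparisons against the combined value use ±0.001.

## Known limitations

- Co-occurrence and distance-ratio enumeration is brute force per
  stratum; fine for desk-scale point sets (hundreds of observations),
  not for millions.
- The greedy rank-one extraction can in principle return a local
  maximum despite restarts; σ sequences are reported as extracted, and
  a non-increasing sequence is evidence, not a guarantee, of global
  optima.
- Shape classing is a plain k-means on four features; no composite
  two-category motifs or fuzzy 2D+1/1D+1 shape profiles.
- Entropies are plug-in values with no sampling-error quantification.
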