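# Methods

This note records the models implemented, the conventions and tolerances
chosen where the methods literature leaves them open, what the synthetic
data emulate, and the limits of both.

## Superimposition

Full Procrustes superimposition with unit-centroid-size scaling: every
configuration is centered, divided by its centroid size, and rotated to the
consensus by the determinant-corrected orthogonal (Kabsch) solution —
reflections are never used, since all mandibles are digitized in the same
buccal orientation and a reflected match would be an error worth seeing,
not silently fixing. The consensus is the arithmetic mean of the rotated
configurations, re-scaled to unit centroid size each iteration. The first
specimen seeds the initial reference; iteration stops when the consensus
moves less than 1e-10 in Procrustes distance or after 100 iterations
(non-convergence warns and flags the dataset rather than raising).

Two conventions deserve note:

- **Orientation.** After convergence the consensus is rotated to its
  principal axes, with the 180° ambiguity resolved by the sign of a fixed
  generic linear functional of the coordinates. This makes GPA output
  *invariant* (not merely equivariant) under a common rigid motion or
  rescaling of all inputs, and deterministic across platforms. The
  consequence is that the aligned frame generally differs from the raw
  digitizing frame by a rotation; comparisons against externally defined
  shapes must superimpose frames first (the test suite does this
  explicitly).
- **Tangent space.** Tangent coordinates are the orthogonal projection of
  the aligned pre-shape at the consensus, stored as full coordinates near
  the consensus (consensus + projected deviation) so that averages of
  tangent rows are themselves displayable shapes. Orthogonal rather than
  stereographic projection was chosen; for the small shape variation these
  methods assume (Procrustes distances ≲ 0.2) the two differ negligibly,
  and the suite verifies tangent distances track Procrustes distances
  within 1% for perturbations below 0.05.

Procrustes distance is the full Procrustes distance
d = √(1 − cos²ρ) between unit-size, optimally rotated configurations; it is
symmetric and satisfies the triangle inequality (checked numerically).
Near-zero distances carry ~1e-8 floating noise because of the square root,
which is why exactness assertions on coincident shapes use 1e-6..1e-9
depending on the path.

## Evolutionary allometry

Taxon means (not individual specimens) are the regression units. Each
tangent coordinate is regressed on centroid size (raw CS by default;
log CS available); the reported quantity is the percent of total tangent
sum of squares predicted by the fit, with a Goodall-style F that pools all
shape dimensions into (1, n−2) degrees of freedom, and a permutation p that
shuffles CS across taxa, p = (1 + #{permuted %predicted ≥ observed})/(1 +
n_perm). Permutation counts default to 9,999 in the fit API and are set
explicitly (999) in the pipeline; a seed is always required.

Clade homogeneity is tested on one-dimensional regression scores — the
projections onto the pooled (within-group common) allometric axis — rather
than by a full MANCOVA: with p ≫ n shape dimensions a multivariate ANCOVA
is ill-posed, and single-F reporting implies a univariate reduction anyway.
The scores then go through standard nested-model ANCOVA: group×CS
interaction F (df g−1, n−2g) for slopes; under a common slope, a group F
(df g−1, n−g−1) for intercepts. Parametric p-values are accompanied by
residual-permutation p-values (permuting residuals of the reduced model).
Groups with fewer than 3 taxa are excluded with a warning.

Size-corrected shapes are the regression residuals re-expressed about the
consensus; their covariance is what the ordination consumes, which makes
every principal component uncorrelated with CS by construction (verified to
|r| < 1e-8).

## Ordination

PCA eigendecomposes the covariance (not correlation) matrix of tangent
coordinates across taxon means. Superimposition removes four degrees of
freedom (two translation, one scale, one rotation), so at most
min(n−1, 2k−4) axes are non-null; axes with eigenvalue below 1e-12 × trace
are dropped. Each eigenvector's largest-magnitude entry is made positive —
an arbitrary but deterministic sign convention. Shapes along an axis are
center + score·eigenvector folded back to k×2; the phylogeny is projected
into the ordination by applying the same centering/projection to
reconstructed ancestral shapes.

## Phylogenetic signal and homoplasy

The tree is used as topology only: all branch lengths are overwritten with
1 at import, with no option to keep them. Squared-change parsimony then
minimizes Σ_edges ‖x_parent − x_child‖²; the minimizer solves the sparse
linear system in which each internal node equals the mean of its tree
neighbors, per coordinate — unique on a connected tree, and verified
against direct numerical minimization. Polytomies are handled naturally by
the linear system.

**Rooted versus unrooted convention.** Reconstruction and the signal test
use the tree exactly as given: a degree-2 root (the usual artifact of a
rooted newick) contributes a reconstructed node of its own, which is the
convention of rooted squared-change parsimony and of the four-tip
worked example (internal states 1, 5, 3 and length 12 for tips 0,0,6,6).
Tree length is invariant to re-rooting at any existing node (the edge set
is unchanged); placing a *new* root on an edge halves that edge's
contribution and is not length-preserving, which is why the homoplasy
indices drop degree-2 nodes: their Steiner enumeration runs over unrooted
binary topologies, and the observed length must live on the same footing
for min ≤ observed ≤ max to hold.

The signal test permutes the tip-to-shape assignment (full Fisher–Yates,
one seeded generator per invocation) and counts permuted lengths ≤
observed; p never reports zero because numerator and denominator both add
1. The test is conservative and sensitive to signal confined to single
clades, which is why the pipeline also runs it per user-defined clade.

SCI = L_min/L_obs and SRI = (L_max − L_obs)/(L_max − L_min). L_max is the
star-tree length Σ‖tip − mean‖², which exhaustive checking (n ≤ 7) confirms
bounds every binary topology's optimized length from above. L_min is found
by enumerating all (2n−5)!! unrooted binary topologies and optimizing each;
the exhaustive path is gated at a configurable cap (API default 11,
pipeline default 8 — enumeration at 8 taxa is 10,395 topologies and runs in
seconds, each additional taxon multiplies the count by ~2n). Above the cap
a nearest-neighbor-interchange descent from the observed topology is
available and its result is labeled approximate. When all tips coincide
(L_max = L_min) the indices are undefined and flagged rather than forced.

## Classification

CVA uses individual specimens as units; ungrouped specimens and singleton
groups never enter the fit. Because Procrustes data are rank-deficient, the
grouped data are first reduced to the PCA subspace of non-null variance
(cutoff 1e-12 × trace) capped at N − g dimensions so the pooled
within-group covariance is invertible; the cap is configurable. The
between/within generalized eigenproblem is solved there, and eigh's
v′Wv = 1 normalization gives canonical scores unit pooled within-group
variance. At most g−1 axes are non-null; signs follow the same
largest-entry convention as the PCA.

Assignment minimizes the Mahalanobis distance to each group mean in the
reduced subspace, with equal priors — group sizes reflect sampling effort,
not prevalence — and posteriors ∝ exp(−D²/2), computed after subtracting
the row minimum for numerical stability. Exact distance ties resolve to the
lowest group index (deterministic). Leave-one-out cross-validation refits
the entire CVA per fold, with no shortcut formulas: correctness over speed
at this scale (hundreds of specimens, ~milliseconds per refit). Folds that
would leave a group too small are skipped with a warning. Canonical-axis
shape reconstructions use the within-covariance image of the eigenvector —
the expected shape displacement per unit canonical score — mapped back to
landmark space.

Between-group distance tests compare group mean shapes by full Procrustes
distance, with p from shuffling the two groups' specimens (same +1
convention).

## Biomechanics

Moment arms are point-to-point distances from the pivot — the midpoint
between the two condylar landmarks — to the landmark standing for each
muscle insertion's extreme point; this operational definition (rather than
perpendicular distance to a muscle action line) is what the lever-arm
ratios of the comparative literature use. The resistance arm runs to the
antero-dorsal border of the incisor alveolus (landmark 1), not the worn
incisor tip. Default insertions: MT2′ → landmark 5 (coronoid tip), MT →
landmark 4 (coronoid base, the surrogate usable on reconstructed shapes
where the calliper-measured insertion is invisible), MSM8′ → 11, MSM9′ →
10, MADM → 14. The MSM/MT2′ assignments are anatomically motivated defaults
and fully overridable, because different nomenclatures disagree on the
exact points. A mechanical advantage above 1 warns rather than errors: real
mandibles have RI longer than every moment arm, arbitrary shapes need not.

## Synthetic data

The generator emulates the data model the analyses assume: per-taxon mean
shape = template + Brownian walk along the (Yule or user-supplied) tree
(independent per coordinate, variance × branch length) + the taxon's
dietary-group offset + allometric vector × (CS − mid-range CS); specimens
add isotropic landmark noise, and raw coordinates are randomly rotated,
translated, and scaled to the specimen's centroid size so the
superimposition is genuinely exercised. All randomness flows from a single
seed; bundles are byte-reproducible.

Default parameters are the study conditions, chosen once for realism at
this clade scale: 44 taxa × 7 specimens (~300 mandibles), 14 landmarks,
centroid size log-uniform over 50–800 mm (pygmy squirrel to marmot), BM
step SD 0.01 per coordinate per unit branch, dietary offsets of norm 0.05,
an allometric shift of 0.2 Procrustes units across the size range (≈ 15–20%
of among-taxon variance, a weak but significant effect), specimen noise SD
0.01 per coordinate, and one taxon left ungrouped as the fossil analog. All
shape effects stay within the small-variation regime (total spread ≲ 0.2)
where the tangent-space linear methods are valid.

What the generator does *not* emulate: correlated (non-isotropic)
digitizing error, within-taxon allometry distinct from the evolutionary
trend, selective regimes (Ornstein–Uhlenbeck), locomotion-specific shape
effects (locomotor labels are assigned independently of shape, so locomotor
classification succeeds only through phylogenetic and dietary covariance —
usefully mimicking the confounding argued for real data), or landmark-wise
variance heterogeneity. Passing tests therefore demonstrate correctness and
calibration of the machinery under the stated model, not robustness to
those violations.

## Numerical conventions, in one place

- GPA: convergence 1e-10 (Procrustes shift of the consensus), cap 100
  iterations, first specimen as initial reference, principal-axis
  orientation standardization.
- Null-axis cutoff: eigenvalue < 1e-12 × trace (PCA and CVA reduction).
- Permutation p-values: (1 + exceedances)/(1 + n_perm), one seeded
  generator per call; warnings below 99 permutations.
- Tree import: branch lengths forced to 1; taxon matching is
  case-sensitive after whitespace trimming; reconciliation failures list
  both unmatched sides.
- Steiner enumeration cap: 11 in the API (hard combinatorial wall: the
  count is (2n−5)!!), 8 in the pipeline configuration; NNI descent beyond,
  flagged approximate.
- Assignment ties: lowest group index. Eigenvector signs: largest-magnitude
  entry positive.
- Pipeline reports round floats to 12 significant digits for byte-stable
  JSON across reruns.

## Known limitations

- Exact SCI/SRI is limited to small clades by the Steiner enumeration; the
  NNI heuristic can stick in local optima.
- The ANCOVA reduction to regression scores tests heterogeneity only along
  the pooled allometric axis; slope differences orthogonal to it are
  invisible to this test (as they are to any single-F summary).
- Orthogonal tangent projection, like any linearization, degrades for
  shape spreads approaching the curvature scale (Procrustes distances
  ≳ 0.3); the generator keeps well inside this regime, and real datasets
  with larger spreads should be examined for projection distortion.
- Leave-one-out refits make cross-validation O(N) full CVA fits; fine for
  hundreds of specimens, slow for tens of thousands.
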