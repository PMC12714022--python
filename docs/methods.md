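# Methods

## Plasticity score

The score treats a cell's state as "plastic" when it is both moving fast in
expression space and acting as a net donor of probability mass in the
velocity transition graph.

For cell *c*, speed is the L2 norm of its velocity vector in the 2-D
visualization embedding, min-max scaled across cells. The embedding is
fixed at two dimensions; higher-dimensional velocity input is rejected
rather than silently normed, because the score is defined on the projected
field. Net flow is `mean(nonzero row c of T) − mean(nonzero column c of T)`
over the directed transition matrix *T*: zero entries are excluded from
both means so that sparsely connected cells are not dragged toward zero,
and a cell with no nonzero entries on one side gets mean 0 for that side.
Diagonal (self-transition) entries carry no state-transition information
and are ignored. Negative entries are rejected: a signed velocity graph
must be split or thresholded upstream. Net flow is min-max scaled, the
per-cell score is the product of the two scaled quantities, per-type scores
are type means min-max scaled once more, and spot scores multiply the type
score by the type's deconvolved proportion in the spot. The per-spot sum
over a type subset (e.g. fibroblast subtypes) is *not* renormalized over
the subset: a spot only 40% covered by fibroblasts can reach at most 0.4.

Degenerate min-max scaling (all values equal) maps to all zeros at every
level: no variation is no evidence of differential plasticity. Together
with exclusion of zero entries this makes symmetric transition matrices
score identically zero.

## Spot QC and smoothing

Smears are low-count off-tissue bead signal. A spot is removed iff its
total counts fall below 100 **and** it has at most 15 neighbors within a
100 µm radius; any spot failing either part of the conjunction is kept, so
deep spots and spots inside dense tissue always survive. (The opposite
polarity — retain only low-count well-neighbored spots — is selectable via
a flag for sensitivity analysis, but discards essentially all tissue and is
not a sensible default.) Neighbor counting uses a k-d tree, excludes the
spot itself, and never materializes a dense pairwise distance matrix.

Gaussian smoothing uses kernel sd 46.37 µm truncated at 3 sd (the source
tool states no truncation; 3 sd retains > 98% of kernel mass). A spot is
smoothed only when at least 10 spots — including itself — fall under the
truncated kernel; under-covered spots are excluded from the smoothed output
and listed, treating the minimum as a coverage requirement. Weights are
normalized to sum to 1, so smoothing is a convex combination: it preserves
nonnegativity and cannot exceed the neighborhood's value range. The
smoother is applied to depth-normalized expression; raw counts are kept
alongside for methods that need them (deconvolution, for example, consumes
raw counts).

Single-cell QC removes a cell when any of these triggers: doublet score
> 0.25, fewer than 300 or more than 10,000 detected genes, or mitochondrial
fraction > 10%. Cells with a missing metric are flagged and removed, never
silently kept.

## Proportions and dominant types

Proportions are the row-normalized deconvolution abundances. Spots with
zero total abundance are a deconvolution failure, not biology, and are
dropped rather than assigned uniform proportions. The dominant type is the
argmax proportion; ties break to the lexicographically smallest type name
(deterministic and seed-free; with continuous abundances ties have
probability zero, so the rule is a documented convention rather than an
inference). Spots dominated by an excluded population — erythrocytes by
default, i.e. residual blood — are flagged and omitted downstream.

## Layer position

Boundaries are inputs (single spot layers on the inner, outer, upper and
bottom edges of an annotated wall), mirroring manual annotation; the
synthetic generator derives them analytically for its shapes. The layer
position of a spot is d_outer/(d_outer + d_inner) with nearest-boundary
Euclidean distances, 0 on the outer and 1 on the inner boundary; the axial
position is the analogous upper→bottom coordinate. Positions depend only on
pairwise distances, hence are invariant to rigid motions of the section.
Boundary spots are kept as members in the binning.

Profiles bin the layer position into 10 equal-width bins ([a, b) except the
last, closed at 1) within 5 axial segments. Per non-empty (segment, bin)
cell the fractions of dominant types sum to 1. The per-bin summary is the
unweighted mean of per-segment fractions (segments are equal analysis
units, not pooled counts) and a 95% CI from the 2.5th/97.5th percentiles
across segments using linear interpolation between order statistics; empty
bins contribute nothing to that bin's mean or CI. Both the percentile
method and the empty-bin rule are conventions of this package and are kept
where a config choice matters.

## Valve sub-domains

Spatial-domain labels and the ARI stability values of candidate cluster
numbers are inputs: the package implements the selection rule only, since
domain finding itself (graph-based contrastive clustering) is external. The
rule takes the first maximal run of ≥ window consecutive candidates with
ARI > 0.65 (window 5 for whole-tissue clustering, 4 for the sub-domain
round) and chooses the k with maximal ARI inside the run, ties toward the
smallest k — a deterministic stand-in for visual refinement. Candidates
after the first qualifying run cannot change the outcome.

Regional plasticity of a sub-domain is the mean fibroblast summed spot
score over its spots; sub-domains are ranked 1..K from most plastic to most
stable and relabeled by rank so labels are comparable across samples. Score
ties break by original sub-domain id.

Neighborhood composition keeps the dominant-type fractions of a sub-domain
sorted descending, drops types below 5% (eligibility is applied *before*
accumulation; the alternative order is selectable), and accumulates
eligible types until the included mass first reaches 90%, including the
crossing type. A type is a sample-level candidate neighbor when included in
≥ 2 sub-domains, and a condition-level neighbor when a candidate on ≥ 2
distinct days of that condition ("shared across time points" is read
within-condition, since per-day compositions are compared within each
condition; the per-sample reading of the two-sub-domain rule is used).

## Synthetic data

The generators emulate the statistical structure the analysis assumes, not
gene-level biology:

- **Geometry.** A jittered square lattice (default pitch 20 µm, matching a
  10 µm-bead array's effective spot density at desk scale) fills an annulus
  (ventricular wall; an angular-extent field makes half-annular walls with
  meaningful upper/bottom ends) or a wedge (valve leaflet, tip to base).
  True transmural (0 = outer, 1 = inner) and axial (0 = upper/tip,
  1 = bottom/base) fractions are recorded per spot.
- **Depth.** Bead totals are negative binomial with mean 500 and dispersion
  2.0 — deliberately overdispersed relative to Poisson, as bead counts are;
  both knobs are exposed because real bead-depth distributions vary by
  platform and tissue. Totals are spread over pseudo-genes by a fixed
  Dirichlet weight vector.
- **Smears.** Binomial(n_tissue, smear_fraction) off-tissue spots with
  uniform counts in [1, 50], placed in a halo 4–12 lattice spacings outside
  the footprint. The halo starts at 4 spacings because the QC radius
  (100 µm) spans 5 spacings at the default pitch: smears planted within
  ~2 spacings of tissue inherit > 15 tissue neighbors and are by
  construction indistinguishable from tissue under the count-and-neighbor
  rule, whereas real smears lie off the section. Boundary rings are the
  spots within one spacing of the exact geometric boundary (inner and outer
  rings are kept disjoint).
- **Composition.** Per-type logistic profiles over the true transmural
  fraction give noise-free abundances; truncated-at-zero Gaussian noise is
  added after the ground-truth proportions are stored.
- **State chain.** Cells of stage i place mass forward_p (default 0.8)
  uniformly on up to 3 random cells of stage i+1 and mass noise_p on random
  other cells; terminal cells have zero outflow. Velocities point at the
  next stage's centroid with magnitude 1 − stage_fraction, so the source
  stage is fastest and the sink stationary. With noise off, the source
  stage provably attains type score 1 and the sink 0.

All generators are pure functions of (parameters, seed) via a single
seeded NumPy generator per call; the seed is echoed in output metadata.

What the simulations do **not** capture: marker-gene structure and
gene–gene correlation, segmentation errors and partial-volume mixing at
single-cell scale, platform-specific spatial artifacts beyond isotropic
smears, and condition-dependent composition shifts. Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
structure, not biological validity on real sections.

## Problem sizes and numerics

The bundled analyses use a half-annulus of ~1,100 spots, a ~320-spot
leaflet and a 600-cell chain — small enough to run in seconds yet dense
enough that the bead lattice exceeds the QC neighbor threshold everywhere
in tissue. Distances are Euclidean in µm throughout; coordinates are
assumed already in µm. Net-flow equality against the brute-force reference
is exact (same floating-point operations up to summation order on grids of
quarter fractions); statistical recovery checks use Spearman correlations
with thresholds stated in the tests.

## Known limitations

- The package consumes velocity fields, transition graphs, deconvolution
  abundances, domain labels and ARI sweeps; it does not infer any of them.
- Smear filtering assumes smears are *isolated* and low-count; smear signal
  adjacent to tissue (within the QC radius) is not separable by this rule.
- The two-round domain-finding orchestration is a thin driver around a
  user-supplied clustering callback; no clustering is bundled.
- Layer position is purely geometric; walls with strongly non-convex
  boundaries can map distinct anatomical depths to the same position.
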