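# Methods

## Data model and filtering

Each data dimension is an unweighted bipartite edge list linking disease
identifiers to feature identifiers in one namespace (gene, pathway,
chemical, or symptom). Edges are deduplicated on load; any weight column is
ignored with a warning. Diseases are converted to binary incidence vectors
over the union of the dimension's features, with rows and columns ordered
lexicographically so every downstream tie-break is deterministic.

Two filters precede any distance computation. First, within each dimension,
diseases whose feature count falls **strictly below the first quartile** of
the count distribution are removed; Q1 uses linear interpolation (quantile
type 7), and ties exactly at Q1 are retained. The rationale is that sparsely
annotated diseases produce unreliable similarity estimates. Coverage
statistics (Q1, median, mean, Q3) are reported on the pre-filter counts; the
pipeline additionally writes the post-filter statistics so both views are
available. Second, the disease sets of all dimensions are intersected, so
every disease in the map has data everywhere; diseases can optionally be
dropped when no display name is available for them (an empty name table is a
documented pass-through).

## Distance metrics

Six metrics are computed per dimension on each disease pair's feature sets A
and B: Jaccard (1 − |A∩B|/|A∪B|), Sørensen–Dice (1 − 2|A∩B|/(|A|+|B|)),
overlap (1 − |A∩B|/min(|A|,|B|)), cosine on binary vectors (1 −
|A∩B|/√(|A||B|), i.e. one minus the Ochiai coefficient), Hamming (|A△B|),
and Euclidean (√|A△B|). Hamming and Euclidean are normalized **per matrix**
by division by the maximum entry, so all six matrices live on [0, 1]; a
matrix of identical diseases yields all zeros rather than 0/0. Because
overlap ≥ Dice ≥ Jaccard as similarities, the distances obey the reverse
inequalities elementwise, which the suite property-tests. Filtering
guarantees non-empty feature sets, so the similarity metrics are always
defined.

## Ipsen–Mikhailov distance and calibration

Matrices are compared as weighted graphs via the Laplacian L =
diag(rowsum) − W. With eigenvalues 0 = λ₁ ≤ … ≤ λₙ and vibrational
frequencies ωᵢ = √λᵢ (only the trivial zero is dropped; extra zero modes of
disconnected graphs are kept), the Lorentzian density

ρ(ω) = K Σᵢ₌₂ⁿ γ/((ω − ωᵢ)² + γ²)

is normalized exactly by the closed form ∫₀^∞ γ/((ω−ωᵢ)²+γ²) dω = π/2 +
atan(ωᵢ/γ). The distance is the L2 norm of the density difference,
integrated by adaptive quadrature on [0, max ω + 10γ] with absolute
tolerance 1e-8, the spectral peaks passed as quadrature break points; if the
adaptive routine cannot reach the tolerance it falls back to a 20,001-point
trapezoid rule on the same interval. γ is calibrated once per matrix size n
by root-finding (bracketing plus Brent) so that d(empty graph, complete
graph) = 1 within 1e-6; the objective is strictly decreasing in γ, so the
root is unique. Calibrated values are cached per n and shared across a
family's pairwise computations.

A distance matrix is passed to the IM machinery **verbatim** as a weighted
adjacency matrix by default (interpretation `"distance"`), which reproduces
what feeding a distance matrix to a generic network-distance routine does; a
`"similarity"` interpretation (W = 1 − D off-diagonal) is available and all
structural properties hold under either. The choice is recorded in run
manifests.

One consequence worth stating explicitly: the IM distance depends only on
the Laplacian spectrum and is therefore invariant under relabeling of the
diseases. Comparisons against, e.g., an ICD-derived matrix are sensitive to
the *partition structure* of the codes (block sizes), not to which disease
carries which code; the test suite asserts this invariance rather than
pretending otherwise.

## Hierarchical consensus

To fuse a family of matrices (six metric matrices within a dimension; six
dimension matrices for the final map), the pairwise IM distances are
clustered by ward.D2 and the matrices are averaged stepwise along the
dendrogram: each internal node's matrix is the **unweighted arithmetic
mean** of its two children. The alternative — weighting branches by leaf
count, which would reduce to the plain mean of all inputs — was rejected
because stepwise branch averaging is the literal reading of "arithmetic mean
at each branching point", and it is what gives the construction its point:
redundant matrices merge early and share one branch's weight, so no single
data modality dominates by multiplicity. The induced effective leaf weights
(products of 1/2 along root-to-leaf paths, summing to 1) are surfaced in the
output provenance, and the consensus is exactly the convex combination of
the inputs with those weights (property-tested to 1e-12).

ward.D2 is implemented as vectorized Lance–Williams updates on squared
distances — d²(k, i∪j) = ((nᵢ+nₖ)d²ₖᵢ + (nⱼ+nₖ)d²ₖⱼ − nₖd²ᵢⱼ)/(nᵢ+nⱼ+nₖ) —
with merge heights equal to the unsquared cluster distance and ties broken
by the smallest (left, right) node-id pair. The suite cross-checks heights
and cut partitions against an independent library implementation of the
same criterion on tie-free data.

## Clustering, model selection, MDS

The consensus map is clustered with the same ward.D2 routine. The Dunn index
(minimum between-cluster distance divided by maximum within-cluster
diameter; +inf with a warning when all clusters are singletons or
duplicates) is scanned over cuts k = 2..k_max (default 250, clamped to
n−1). Local maxima are plateau-aware: a maximal run of equal values strictly
above both neighbors. Because the index typically increases with k, the
selected k is the first k of the flagged run with the highest Dunn value
(ties: smallest k), falling back to the global argmax when no interior
maximum exists — and it is always user-overridable, since the choice within
a plateau is a judgment call rather than an algorithm. Cluster ids are
assigned in order of first member appearance over the lexicographic disease
order.

Classical MDS double-centers the squared distances (B = −½ J D² J), takes
the top eigenpairs, clips negative eigenvalues (non-Euclidean input) to zero
with a warning, and fixes each coordinate column's sign deterministically.
Coordinates of a disease subset are sliced from the full embedding, never
re-fit on the subset.

## Enrichment statistics

For feature f and cluster c the 2×2 table counts (associated, in c),
(associated, outside), (not associated, in), (not associated, outside) over
the final disease set. One-sided p-values are upper hypergeometric tails
(over-representation); two-sided p-values sum the probabilities of all
tables with the same margins no more probable than the observed one (with a
1+1e-7 relative guard against floating-point ties). Nominal p-values are
Bonferroni-multiplied by (number of clusters) × (number of features
surviving filtering in the dimension), capped at 1, with significance
declared below 0.05. Pairwise cluster comparisons report nominal p-values as
the primary readout (adjusted values are included as well). Odds ratios are
the sample ad/bc, with a Haldane 0.5 correction applied and flagged only
when a zero cell occurs. Feature frequency tables rank features by the
number of linked diseases with lexicographic tie order, and Spearman
correlations (average-rank ties, large-sample p) relate association degrees
to external counts such as publication numbers.

## ICD-10 comparison

ICD-10 codes are validated as letter + two digits with an optional
subcategory. The default similarity is a three-level hierarchy rule:
identical codes 1, shared three-character category 2/3, shared chapter
letter 1/3, else 0. The published formula this stands in for is cited in the
upstream literature but not reproduced there, so the rule is isolated behind
a strategy argument and can be replaced without touching the comparison
code. The ICD matrix (1 − similarity) joins the dimension matrices and the
consensus in an IM family comparison, restricted to the mapped diseases
(≥ 3 required).

## Synthetic data generator

The generator emulates the statistical shape the analysis assumes, not any
real nosology. K planted clusters assign each disease a cluster; per
namespace, each cluster owns a disjoint signature feature pool (size about
m/2K, at least 4), linked by members with probability p_in; all other
features are linked with probability p_out scaled by power-law popularity
weights (rank^−α, mean-normalized, assigned in shuffled order, capped at
0.8), producing hub features linked to large fractions of diseases. Each
dimension observes an independent uniformly random coverage fraction of the
diseases, drawn from a per-dimension child generator spawned from one root
seed, so runs are reproducible and dimensions overlap only partially. The
pathway layer is a deterministic function of the gene layer: genes are
partitioned into consecutive pathways of `genes_per_pathway` members
(default 5) and a disease links a pathway iff it links any member gene.
Defaults: 60 diseases, 3 clusters, p_in = 0.9, p_out = 0.05, coverage
= 0.9, α = 1, and 150/60/80/100/120 features for the gene, drug, symptom,
targeting-chemical and associated-chemical namespaces — a desk-scale cohort
with strong but noisy multi-view structure.

Synthetic publication counts are drawn through a Gaussian copula: the
latent score mixes normal scores of the degree ranks with independent noise
at a requested strength s, then maps monotonically to heavy-tailed positive
integers. s = 1 reproduces the degree ranking exactly; intermediate s yields
a Spearman correlation close to s (with the usual copula attenuation, about
0.68 recovered at s = 0.7).

What the generator does **not** emulate: real identifier vocabularies,
calibrated degree distributions of any deposited dataset, directionality or
sign of chemical associations, and correlated (rather than independent)
coverage across dimensions. Passing tests therefore demonstrate the
correctness and discriminative behavior of the machinery on data with
planted truth, not biological conclusions about real diseases.

## Problem sizes and analysis choices

The recovery analyses (tests and the acceptance script) run the fusion
chain — metrics → metric consensus → dimension consensus → ward.D2 → cut at
the scan-selected k — on the intersected disease set of 60-disease cohorts
with 90% per-dimension coverage, five independent seeds. The quartile filter
is exercised on its own and inside the full pipeline, but the recovery
chain is run without it: stacking an independent 25% coverage filter on top
of 10% dropout in all six dimensions shrinks a 60-disease six-way
intersection to a handful of diseases, which is a statement about small
cohorts rather than about the method. On real-scale data (hundreds of
diseases surviving intersection) the filter is the default and first stage
of `run_pipeline`.

## Known limitations

* The stepwise-average consensus depends on the dendrogram topology; near
  ties in the family IM distances can flip merge order and hence leaf
  weights (tie-breaking is deterministic, so runs are reproducible).
* The Dunn index is a global min/max statistic and is sensitive to single
  outlier pairs; the plateau rule mitigates but does not remove this.
* IM comparisons are alignment-free (spectral); they measure structural,
  not disease-by-disease, agreement between maps.
* Fisher tests treat diseases as independent observations; shared ancestry
  between disease terms is not modeled.
* The default ICD similarity is a stand-in hierarchy rule; block-level
  chapter membership is approximated by the chapter letter.
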