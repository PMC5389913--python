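# Methods

This note documents the models, parameters, numerical choices and known
limitations of the package. Empirical figures quoted here (recovery
rates, rho values) are the ones the test suite and example scripts
compute; nothing is reported that the code does not itself produce.

## Canonical geometry models

Eighteen canonical coordination geometries are defined by ideal
unit-vector ligand positions: seven majors (tetrahedral Tet; trigonal
bipyramidal Tbp; octahedral Oct; trigonal prismatic Tpr; pentagonal
bipyramidal Pbp; hexagonal bipyramidal Hbp; square antiprismatic Sqa) and
eleven minors obtained by deleting fixed vertex indices from a major
(e.g. square pyramidal Spy = Oct minus one axial vertex; the deleted
indices are recorded on each model). The prism and antiprism both use
ring radius √(2/3) and half-height 1/√3, which reproduce the ideal angle
multisets 70.5/90/131.8 and 70.5/82/109.5/143.6 to better than 0.1°.
Bipyramids place the axial pair first, then the equatorial ring; minors
delete vertex 1 (second axial) for "vacancy axial" and vertex 2 (first
equatorial) for "vacancy planar" variants.

## The 6-angle reduction

A shell of n ligands has C(n,2) pairwise ligand–metal–ligand angles. The
reduction keeps the largest angle (ties broken by the lexicographically
smallest ligand-index pair), the smallest *opposite* angle (minimum over
angles sharing no ligand with the largest), and four order statistics of
the remaining middle angles sorted ascending: positions 0,
round(0.33·(m−1)), round(0.66·(m−1)), m−1 (nearest rank, half rounds
up). Anchoring the vector ends at the largest/smallest-opposite pair and
sorting the middles avoids any all-to-all ligand mapping and makes
shells of different coordination numbers comparable.

Degeneracies are intrinsic and documented rather than patched: Spy
reduces to the same vector as Oct, Pvp to the same as Pbp, and Hva to
the same as Hbp. Within a fixed coordination number the reduced vectors
are distinct; across coordination numbers these pairs are separated only
by the ligand count. Benchmarks that test cluster separability therefore
use classes with distinct reduced vectors.

## Ligand detection

Constants (all exposed in `DetectionConfig`, shipped per-metal values in
`data/metal_params.yaml`):

| parameter | default | meaning |
|---|---|---|
| shell lower cutoff | 1.3 Å | below this nothing is a ligand |
| initial upper cutoff | 3.20–3.65 Å | atomic-radius based, per metal |
| triangular factor | 1.5 | second-shell exclusion ratio |
| element whitelist threshold | >5% occurrence | rare elements dropped; carbon always |
| acceptance z | 2.5 | retains ≈98.76% of true ligands under the normal model |
| misassignment cutoff | 0.91 | average mode-normalized deviation |
| resolution fit cap / bin size | 3.5 Å, >30 points | slope-fit data quality |
| sd floor | 0.01 Å | avoids division blow-ups at extrapolated resolutions |
| metal-cluster distance | 3.0 Å | two metals closer than this are excluded |

The updated cutoff is (mean + sd + carbon mode)/2 of the most abundant
element versus the fictional metal–carbon distance mode. The carbon mode
is estimated from the *shell* carbons of round one (all carbons within
the initial cutoff after the triangular rule), not only from carbons that
happen to enter a best-fit subset: the calibration's purpose is to locate
where accidental alignments begin, and clean subsets rarely contain
carbon at all. When too few shell carbons exist for a mode (<30), the
shipped per-metal calibration value is used instead.

Mode detection uses a Gaussian KDE with Silverman bandwidth on a 512-point
grid, peaks with prominence ≥5% of the maximum density, sorted by height;
a near-constant sample (range <1e-9) short-circuits to its value.

The resolution slope m pools all metal–element series after centring each
by its n-weighted mean sd, keeping bins with resolution ≤3.5 Å and >30
points, and fits ordinary least squares. With a single resolution in the
data (as in synthetic fixtures) the fit is impossible and the slope falls
back to 0, i.e. the unadjusted sd.

**Misassignment filtering order.** The average mode-normalized deviation
is evaluated on the whitelisted cutoff shell *before* the per-ligand
2.5-sd test, and the element statistics feeding it are re-estimated from
the currently unflagged sites until the flag set stabilises (≤10
rounds). Both choices were forced by measurement: the z test censors
exactly the inflated long bonds the deviation filter needs to see
(capping recall near 60% on 20%-contaminated cohorts), and statistics
estimated from the contaminated cohort inflate the scale toward the
misassigned sites. With both in place the planted-misassignment
benchmark reaches ≈100% recall at 0% false flags (6-ligand Fe sites,
20% contamination). On 4-ligand sites with generation noise equal to the
detector's estimated sd, the site-average deviation has sd ≈0.5–0.6, so
a few percent of honest sites exceed 0.91; this is a property of the
filter at low coordination numbers, visible in the synthetic conditions
because there the per-site scatter equals the population scatter.

## Chi-square classification

The observed vector is the full ordered angle vector (largest, ascending
middles, smallest opposite), optionally extended with per-ligand bond
lengths as independent z² terms using per-element means and
resolution-adjusted sds; dof is the total vector length and the score is
the upper-tail χ² probability. The prism/antiprism family (Tpr, Tpv,
Sqa, Sav, Hbp, Hva, Hvp) uses the independence form with a 1.5 variance
multiplier; other models use the Mahalanobis form once a class has ≥3·dim
members, falling back to independent terms (without the multiplier) on
singular covariances.

**Combination preference.** Ligand combinations are searched over the
atoms within the updated cutoff; combinations containing an angle below
the per-metal small-angle cutoff, or failing the site-level quality
filters, are discarded. Among viable combinations the *largest* size is
preferred, then the highest probability, then the alphabetically first
model code. Probability-first selection across sizes is structurally
biased: every minor CG is an exact vertex subset of its parent major, so
under any noise a lower-dof subset fit would out-score the full-shell
fit (measured: 82% of noisy octahedral shells re-assigned to their own
subsets). The coordination number is fixed by detection; dropping atoms
is justified only when a combination fails a filter.

**Iterative refinement.** Classify-all / re-estimate alternates until the
largest angle-mean change is <0.1° (bond statistics are held at their
detection values), the assignment state repeats (limit cycles of
borderline sites occur and cannot move the statistics further), or 50
iterations elapse. Two stabilisers keep refinement honest: a class whose
estimated mean drifts >10° from its ideal geometry reverts to the prior
(a CG class is defined by its polyhedron; without the anchor a
zero-member minor class adopts another geometry's outliers and snowballs
— observed as a 195/197 takeover of tetrahedral sites by Bva), and
estimated covariance eigenvalues are floored at 0.25 deg² because ordered
angle vectors carry near-deterministic linear relations whose tiny
eigenvalues dominate the Mahalanobis distance. Ideal-model priors use a
5° angle sd.

Cluster-level characterization averages each model's χ² probability over
cluster members (in the 6-angle space, where the clusters live) and
reports the argmax with the full table; aberrant compressed-angle
clusters score <0.2 against every canonical model.

## Compressed-angle labeling and clustering

Training labels come from per-metal bands on the smallest angle (e.g.
Zn 60/70°: below = compressed, above = normal); in-band sites are
predicted by a 500-tree random forest on three feature groups — the
smallest angle, the element pair composing it (bag-of-elements counts),
and the bidentation flag (both atoms from one residue). Element symbols
(not residue names) identify the ligands.

k-means runs on raw degree-valued 6-angle vectors (Euclidean metric, 10
restarts, seeded). Stability across repeated runs is summarised by
greedy maximum-Jaccard cluster matching — the greedy matching agrees
with exhaustive permutation matching on the benchmarks tested — giving
the mean matched Jaccard and the (negated) sum of matched-center
distances. k is chosen by rank-sum: of all four measures (adding
structure–function ρ and −log₁₀ p, requiring p < 0.01) when ≥600 sites
are available, of the two stability measures otherwise; ties go to the
smaller k. The 600-site rule reflects the subsampling behaviour of ρ
(`subsample_rho_curve` reproduces the rising-then-plateau shape on
planted data).

## Structure–function analysis

Functional distance between clusters is 1 − cosine similarity of their
annotation-frequency vectors; structural distance is Euclidean between
6-angle cluster centers. ρ is the Spearman correlation over corresponding
off-diagonal pairs. Its p-value uses the asymptotic t approximation; an
exact cluster-relabelling permutation distribution is available
(`p_method="permutation"`) but its granularity is 2/k!, which cannot
reach 0.01 for k ≤ 5, so it serves as a cross-check rather than the
default. Average-linkage dendrograms of both matrices are emitted in
Newick format.

Enrichment is the upper-tail hypergeometric probability per term, BH
adjusted within each group; significance requires ≥2 annotated group
sites and raw p ≤ 0.05. Enriched terms are grouped by walktrap (4-step
random walks) on a graph whose edge weights are |shared annotated
sites|/|union| — a normalized overlap chosen so that the 0.8 removal
threshold is scale-free. Consistency checking flags a term whose
combined-stratum significance is contradicted (significant in the
*opposite* group) by any sub-stratum, and reports each term's maximum
per-metal usage fraction with a <0.5 filter.

## Synthetic data

The generator is the package's study-condition definition, not a test
dial. Defaults: 3° angle noise (per-ligand rotation about a random
tangent axis), 0.05 Å bond noise, compressed angles Normal(56°, 3.5°),
carbon decoys at the per-metal characteristic carbon-mode distance
(Normal(mode, 0.15 Å)) covalently anchored 1.42–1.48 Å to a true ligand
and pointing away from the metal, misassignment inflation of 1.5× the
element's *characteristic* bond-length sd (the crystallographic-scatter
scale, e.g. 0.134 Å for Fe–N — a wrong-ion radial error, not a
perturbation of the generation noise). Ligand atoms are wrapped in
minimal residue scaffolds (Cys SG+CB, Asp OD1/OD2+CG, His NE2+CD2,
water O); bidentation uses carboxylate geometry (C–O 1.25 Å, oxygens
placed symmetrically about the bisector of the smallest-ideal-angle
vertex pair). Written PDB entries carry a far-away 20-residue
poly-alanine chain so they pass the minimum-protein-size filter.

Planted structure–function annotations share each class's annotation
with other classes at probability exp(−d/τ) of their 6-angle distance d
(τ = half the median inter-class distance) plus 5% label noise. A single
label per class would make all cluster profiles uniformly dissimilar —
cosine distances then carry no rank information against structural
distances and ρ is near zero by construction; the graded overlap is what
a real structure–function association looks like at the annotation
level.

What the generator does **not** emulate: full protein environments
(second shells beyond the planted decoys, backbone sterics), B-factors
and occupancy disorder, crystallographic symmetry, resolution-dependent
coordinate error (all fixtures share one nominal resolution, so the
resolution-slope fit is exercised on constructed series rather than
end-to-end), and sequence redundancy. Passing benchmarks therefore
demonstrate the pipeline's statistical machinery under controlled
conditions, not its behaviour on the full heterogeneity of deposited
structures.

## Benchmark problem sizes

The shipped benchmarks use 200 sites per geometry class for detection,
decoy-removal, misassignment and recovery tests, 500 sites for the
compressed/normal classifier, and 900 sites (6 classes × 150) for the
structure–function correlation; these sizes put every rate estimate's
sampling error well inside the asserted margins while keeping the full
suite around a minute of CPU.

## Known limitations

* The 6-angle degeneracies above (Spy/Oct, Pvp/Pbp, Hva/Hbp) are
  irreducible in the reduced space.
* Low-population geometries (e.g. square planar) may not receive their
  own k-means cluster at practical k; unequal cluster densities are a
  fundamental clustering limitation, not solved here.
* The error-rate estimator assumes a uniform per-ligand error
  probability and is a lower bound on the true false-positive rate.
* Symmetry-copy filtering acts on explicitly marked copies; the package
  does not expand crystallographic symmetry itself.
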