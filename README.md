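# metalcg

Structural and functional characterization of metal binding sites in
proteins: statistically calibrated first-shell ligand detection,
coordination-geometry (CG) classification against 18 canonical models,
detection of *aberrant* compressed-angle geometries caused by bidentate
ligands, clustering in a reduced 6-angle space, and correlation of
structural clusters with functional annotations.

It is written for structural bioinformaticians who work with PDB/mmCIF
structures of metalloproteins (Zn, Mg, Ca, Fe, Na are configured out of
the box) and want a reproducible, filterable alternative to eyeballing
coordination shells — including the cases canonical-geometry matching
silently gets wrong.

## The method

**Ligand detection.** For each metal ion M, candidate shell atoms within
an atomic-radius-based cutoff are pruned by the *triangular rule* (atom
*a* is second-shell if some atom *b* satisfies d(M,a) ≥ 1.5·d(M,b) and
d(M,a) ≥ 1.5·d(a,b)) and bootstrap-fitted to the four common canonical
CGs. The resulting per-element bond-length statistics recalibrate the
shell cutoff as the midpoint between (mean + 1 sd) of the most abundant
ligand element and the main mode of the *fictional* metal–carbon
distances — carbon, almost never a true ligand, estimates where
accidentally aligned second-shell atoms begin. A bond length r is finally
accepted when |r − μ| ≤ 2.5·sd_x, with the resolution-adjusted scale

    sd_x = m · (R_x − R_avg) + sd_avg

(m: pooled slope of bond-length sd versus crystallographic resolution;
R_x: the entry's resolution). Sites whose bonds are *systematically*
inflated — average mode-normalized deviation (1/n)·Σ (r_i − mode_i)/sd_i
above 0.91 — are flagged as likely metal misassignments and removed.

**Classification.** A shell's angles are arranged as an ordered vector
(largest, ascending middles, smallest angle sharing no ligand with the
largest) and scored against each canonical model by χ² =
(x−μ)ᵀ Σ⁻¹ (x−μ) with per-model estimated angle covariance (an
independence form with a 1.5 variance multiplier for the ill-conditioned
prism/antiprism family); the model with the highest upper-tail χ²
probability wins, and model statistics are refined iteratively.

**Aberrant CGs and clustering.** The smallest ligand–M–ligand angle
separates *normal* sites from *compressed* ones (typically ≈56°, almost
always a bidentate Asp/Glu carboxylate) via per-metal training bands plus
a random forest for the in-between band. Sites of any coordination
number are clustered by k-means in the 6-angle space (largest,
smallest/33rd-quantile/66th-quantile/largest middle, smallest-opposite
angle); k is chosen by rank-sum of matched-Jaccard stability, center
stability, and — when ≥600 sites are available — the structure–function
Spearman ρ between cluster distances in angle space and cosine distances
between cluster annotation profiles, with hypergeometric term enrichment
(Benjamini–Hochberg adjusted, ≥2 sites and p ≤ 0.05) contrasting the
normal and compressed groups.

A synthetic-data module generates PDB fixtures with known ground truth
for every phenomenon above: noisy ideal geometries, bidentate
compressed-angle sites, second-shell carbon decoys, and
misassigned-metal sites with inflated bonds.

## Worked example

Detection on 150 noisy tetrahedral Zn sites, each with two planted
second-shell carbon decoys (`python examples/02_detect_ligands.py`):

```
input sites          : 150
surviving sites      : 140
updated upper cutoff : 2.749 A (carbon mode 3.109 A)
Zn-S bond length   : 2.337 +/- 0.043 A (mode 2.341, n=544)
decoy carbons planted: 300, surviving in shells: 0 (100.0% removed)
```

The cutoff recalibrates itself from the data (2.749 Å here, against the
3.20 Å atomic-radius starting point): every planted decoy is excluded
while the recovered Zn–S bond statistics match the generating values.
Classification on a Tet/Oct mixture (`python examples/03_classify_geometries.py`)
recovers 160/160 sites, and the planted structure–function benchmark
(`python examples/05_structure_function.py`) prints

```
n = 900 sites, k = 6
structure-function Spearman rho = 0.929 (p = 5.87e-07)
terms enriched in the normal group: ['NT0', 'NT1', 'NT2', 'NT3']
terms enriched in the compressed group: ['CT4', 'CT5']
```

— structurally close clusters carry similar annotations, and the
enriched terms of normal versus compressed coordination are disjoint.

The `metalcg` command wraps the same library:
`metalcg generate`, `metalcg run-all`, `metalcg report`.

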