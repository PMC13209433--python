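# shapedock

Small-molecule **target prediction** by alignment-free 3D shape screening and
native-ligand-normalized reverse docking.

Given a query molecule in 3D, shapedock answers: *which proteins is this
molecule likely to bind?* It works in two stages:

1. **Shape pre-screen.** The query is compared against a library of native
   co-crystallized ligands (one per candidate protein target, in their
   experimental bioactive poses) using a 10-component 3D shape descriptor
   vector computed on the voxelized van der Waals solid — no superposition or
   alignment is ever performed. The top-ranked targets form the shortlist.
2. **Reverse docking with DetScore.** The query is docked into each
   shortlisted pocket and scored by the differential

   *DetScore* = *ScoreA* − *ScoreB*,

   where *ScoreA* is the query's docking score and *ScoreB* is the stored
   score of the pocket's own native ligand redocked under identical settings.
   Raw docking scores are not comparable across targets (native redocks alone
   span tens of kcal/mol between systems); the differential normalizes out
   the target-specific bias. Targets are reported with both the similarity
   rank and the comprehensive (ascending-DetScore) rank.

## The descriptor vector

A molecule is realized as the union of atom-centered vdW spheres (Bondi radii
by default), sampled on a cubic grid of spacing *h* (default 0.3 Å): a voxel
is occupied iff its center lies inside the solid. The ordered 10-vector is

| # | symbol | meaning |
|---|--------|---------|
| 1–4 | τ₁…τ₄ | 3D Hu moment invariants of the solid: τ₁ = μ₂₀₀+μ₀₂₀+μ₀₀₂, τ₂ and τ₃ the second/third symmetric functions of the second-moment tensor, τ₄ the weighted sum of squared third-order central moments — all invariant to rotation and translation |
| 5 | κ | moment compactness 3^(5/3)/(5(4π)^(2/3)) · V^(5/3)/τ₁, = 1 for a ball |
| 6 | κst | isoperimetric ratio 36π·V²/S³, = 1 for a ball |
| 7 | κfit | Jaccard volume overlap with the equal-volume ball at the centroid |
| 8–10 | S, V, R | surface area (Å²), volume (Å³), and R = S/V (Å⁻¹) |

Moments are volume integrals realized as sums over occupied voxel centers;
V is exact voxel counting and S is a marching-cubes triangulation of the
signed-distance field of the sphere union. Similarity between vectors A and B
is the mean componentwise min/max ratio, in [0, 1], equal to 1 only for
identical vectors.

## Worked example

Generate a fully synthetic demo workspace (50 targets), then predict targets
for the demo query with the mock engine:

```bash
shapedock fixtures --outdir demo --n-targets 50 --seed 13
shapedock run --query demo/query.sdf --library demo/library.tsv \
              --engine mock --seed 13 --out ranking.tsv
head -4 ranking.tsv | cut -f1,5,6,9,10
```

```
entry_id        similarity      similarity_rank det_score       comprehensive_rank
T0026   0.584412        40      -9.2588 1
T0006   0.771396        10      -7.7962 2
T0047   0.660042        23      -7.3402 3
```

Reading the second row: the query's descriptor vector is 0.771 similar to
target T0006's native ligand (the 10th most shape-similar entry of 50), and
docking predicts the query binds 7.8 kcal/mol *better* than T0006's own
native ligand. Negative DetScore means better-than-native predicted binding;
the two ranks together are the method's dual sorting of candidate targets.

A query's conformational flexibility is handled before screening: molecules
with ≥ 5 rotatable bonds keep their input conformation; more rigid queries
may be expanded into an ensemble (delegated to Open Babel), filtered to
conformers with ≥ 0.5% Boltzmann population at 298.15 K, capped at 100.

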