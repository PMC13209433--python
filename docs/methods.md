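# Methods

## Molecular solid and voxelization

Every shape quantity is defined on the *molecular solid*: the union of
atom-centered van der Waals spheres. Radii default to Bondi's set (C 1.70,
N 1.55, O 1.52, H 1.20 Å, …); a custom `element,radius` CSV can be supplied,
and the radius-set label travels with every descriptor so query and library
vectors are never mixed across conventions. Hydrogens are retained whenever
the input file carries them, and this choice is recorded in the descriptor
metadata, because adding or dropping hydrogens changes V, S and all moments.

The solid is sampled on a cubic grid of spacing *h* (default **0.3 Å**):
a voxel is occupied iff its center lies within some atom's radius — the
center predicate is an unbiased volume estimator and the simplest convention
that makes `V = h³ × occupied count` exact. The grid box covers all spheres
with a margin of (max radius + 2h) per face so the boundary surface closes.

Two numerical choices matter here:

* **Lattice anchoring.** The lattice is anchored to the centroid of the atom
  coordinates with a quarter-voxel offset per axis. Anchoring to the molecule
  makes translations exact no-ops (the grid moves rigidly with the atoms);
  the offset desynchronizes sphere boundaries from lattice planes, which
  damps the coherent voxel-count oscillations familiar from lattice-point
  counting in balls. With this choice the single-atom V, S and τ₁ errors
  shrink monotonically through h = 0.4 → 0.2 → 0.1 and are ≲ 1% at 0.2 Å.
* **Surface area.** S is measured by marching-cubes triangulation of the
  signed distance field φ(x) = minᵢ(|x−cᵢ| − rᵢ), whose zero level set is the
  exact boundary of the sphere union. Counting exposed voxel faces instead
  would overestimate a sphere's area by ~50% systematically and destroy the
  isoperimetric compactness, whose ball limit must be 1. Grids injected
  directly as occupancy masks (a test hook with no underlying spheres)
  denote unions of voxel cubes; for those the exposed-face area *is* the
  exact boundary area and is used as such.

## Descriptors

Geometric moments are volume integrals over the solid, realized as sums over
occupied voxel centers times h³ — not sums over atom positions. Central
moments are taken about the centroid (m₁₀₀, m₀₁₀, m₀₀₁)/m₀₀₀. From orders
≤ 3 the four 3D Hu invariants are formed: τ₁ the trace of the second-moment
tensor, τ₂/τ₃ its second and third elementary symmetric functions written in
moment form, τ₄ the 1/3/6-weighted sum of squared third-order moments. All
four are invariant to rigid motion; on the raw (dimensionful) central moments
they are *not* scale invariant — a scale-normalized variant
(μ/m₀₀₀^(1+(p+q+r)/3)) is available behind a config flag and recorded in
metadata. The second invariant's final squared term is μ₀₁₁² by default; a
"printed" variant with μ₀₀₁² (identically zero for central moments, so the
term vanishes) is kept selectable for comparison with the formula as it has
circulated in print.

Compactness comes in three flavors, each dimensionless with the ball as the
unique maximizer at 1: κ = 3^(5/3)/(5(4π)^(2/3)) · V^(5/3)/τ₁ (the constant
is fixed by requiring κ(ball) = 1), κst = 36πV²/S³, and κfit, the Jaccard
overlap between the solid and the equal-volume ball centered at its centroid,
evaluated on the same grid. Because V and S are estimated by different
routes, discretization can push κ or κst a fraction of a percent above the
analytic supremum; both are clamped at 1.0. κ is always computed from the raw
(dimensionful) τ₁ regardless of the invariant variant, since its prefactor is
what makes it dimensionless. A single-voxel solid has τ₁ = 0 and is rejected
as degenerate.

The full vector is [τ₁, τ₂, τ₃, τ₄, κ, κst, κfit, S, V, R] with R = S/V.
τ₄'s units are heterogeneous across its terms as defined; the min/max ratio
in the similarity score compares each component against its counterpart only,
so the mixed scale cancels out of the comparison.

## Similarity and search

sim(A, B) = (1/10) Σᵢ min(αᵢ, βᵢ)/max(αᵢ, βᵢ). Edge conventions: both
components zero → the term is 1 (indiscernible); exactly one zero → 0;
opposite signs (τ₃ can be negative) → 0, since a magnitude ratio across a
sign change would count genuinely different shapes as similar. These keep
the score in [0, 1], symmetric, and 1 iff the vectors are equal.

Library entries hold the native ligand's experimental pose (no conformer
search on the library side); a query may be an ensemble, aggregated by the
max over conformers (best-match), with the best conformer index reported.
Ties in ranking break by entry id so output is reproducible. The library is
persisted as a TSV with a `# key=value` metadata header — diffable text, no
binary database — and search refuses vectors whose metadata (spacing, radius
set, variant) differs from the library's.

## Conformer workflow

The rotatable-bond count gates ensemble generation: ≥ 5 rotatable bonds skips
generation (combinatorial explosion; the input pose is used), < 5 generates.
A rotatable bond is a non-ring single bond between two heavy atoms each
bearing at least one further heavy neighbor, with amide C–N excluded
(standard convention); ring bonds are detected as non-bridge edges of the
bond graph. Generation itself — Monte Carlo (≤ 500 conformers) or systematic
enumeration (50 kcal/mol window, RMSD deduplication), followed by
MMFF94-class minimization (3000 steps) — is delegated to an adapter; the
shipped real adapter shells out to the Open Babel CLI and a deterministic
mock serves tests. Boltzmann populations at 298.15 K (R = 0.0019872041
kcal/mol/K, energies zeroed at the ensemble minimum for numerical stability)
filter the result: retain p ≥ 0.5%, cap at the 100 lowest-energy conformers.
When many near-degenerate conformers dilute every population below the
threshold, the cap lowest-energy conformers are retained instead — a
screening ensemble must never be empty.

## Docking and ranking

The docking box is derived from the native ligand: center at its bounding-box
midpoint, edges = extent + 2 × 8 Å margin, floored at 16 Å — a concrete,
configurable protocol. Engines sit behind a two-method adapter; the shipped
adapter speaks the AutoDock Vina 1.1.2 command/output dialect (fixed seed and
exhaustiveness recorded, since scores vary with both), and ligand PDBQT
preparation is delegated to Open Babel. Entries without a stored native
redock score are refused at dock time: without ScoreB the differential score
is meaningless, and silently reporting raw scores would reintroduce exactly
the cross-target bias DetScore exists to remove. The comprehensive ranking
sorts ascending DetScore, ties to higher similarity, then entry id; the
report carries both ranks per target.

## Evaluation metrics

ROC AUC is computed as the Mann–Whitney rank statistic (ties count ½), which
pins the tie convention exactly and is invariant under monotone score
transforms. EF at fraction f takes the top ⌈fN⌉ items (cutoff ties resolved
by score then item id) and divides the actives rate inside by the overall
rate; EF(f=1) = 1 identically and chance level is 1. Recall@K counts queries
whose true target's comprehensive rank is ≤ K and errors out if a true
target is missing from the supplied ranking.

## Synthetic data: what it models and what it does not

The fixtures module generates every input class deterministically from a
seed: single atoms, chains (1.5 Å heavy-atom spacing), rings, random clouds
(≥ 1.2 Å separation inside a box), and perturbed copies (Gaussian coordinate
noise). Benchmark screens model the actives/decoys construction
geometrically: actives are shape-perturbed copies of a base molecule
(σ = 0.1 Å default) — shape-similar regardless of chemistry, which is the
regime a pure shape descriptor addresses — and decoys are independent random
clouds matched in atom count *and* packing density (sampled in the base's own
bounding box), so screens are not separable by volume alone. Synthetic
libraries pair random-cloud "native ligands" with placeholder receptor files;
the mock engine scores deterministically in [−12, −1] kcal/mol as a pure
function of (receptor identity, query heavy-atom count, seed), so a native
self-dock reproduces its stored ScoreB exactly and DetScore = 0.

What passing these tests shows: the descriptor mathematics, invariances,
retrieval, normalization and ranking machinery behave exactly as specified.
What they do not show: performance on real chemistry — synthetic clouds have
no bonded structure, no property-matched decoys in the DUDE sense, and the
mock engine has no binding physics. Real-data benchmarks (e.g. DEKOIS 2.0 or
DUDE-Z sets) can be run offline through the same metrics module when the
user supplies the files.

## Problem sizes and defaults

Defaults were chosen once as realistic desk-scale study conditions: grid
spacing 0.3 Å (sphere errors < 2%), rigid-motion checks with 5 asymmetric
molecules × 20 motions (asymmetric shapes keep all third-order invariants
well away from zero, where relative comparisons are ill-conditioned),
synthetic libraries of 50 targets, screens of 20 actives / 200 decoys over
10 seeds, EF null expectation over 1000 random screens, similarity shortlist
top-k = 200. All randomness flows from explicit integer seeds; repeated runs
are byte-identical.

## Known limitations

* Descriptors see only the vdW solid: no electrostatics, pharmacophores or
  chirality (the sign convention treats opposite-sign τ₃ as dissimilar, but
  enantiomers largely share even-order moments).
* The Hu set on raw moments is size-sensitive by construction; the ratio
  similarity absorbs overall scale but mixed-size comparisons lean on S, V, R.
* Surface area from marching cubes converges from below on smooth solids;
  κst inherits a small positive bias that the clamp bounds at 1.
* The isoperimetric κst is sensitive to surface noise (S is cubed); it is
  the least rigid-motion-stable component (~2.5% at h = 0.3 Å vs < 1% for V).
* Receptor preparation (protonation, charges, PDBQT) is out of scope; the
  library stores prepared receptor paths.
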