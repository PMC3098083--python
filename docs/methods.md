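# Methods

`cmclust` clusters a set of molecular objects (protein structures, binding
subsites, sequences, ligand shapes) from nothing but a symmetric matrix of
pairwise similarities or distances. This note records the model, the
numerical conventions, and the design choices that were genuinely open.

## Similarity front-ends

**Hodgkin electrostatic similarity.** Two electrostatic potentials
M_i, M_j sampled on a common regular grid are compared with the Hodgkin
index

    SI_ij = 2 (M_i, M_j) / (‖M_i‖² + ‖M_j‖²),

where (·,·) is the scalar product over the compared grid points. SI = 1
for identical potentials, 0 for orthogonal ones, −1 for anti-correlated
ones; the bound |SI| ≤ 1 follows from the AM–GM inequality. The index is
scale-sensitive by design: SI(M, cM) = 2c/(1+c²), so a potential twice as
strong scores 0.8, not 1. Comparisons are restricted to a "skin" — grid
points whose distance to the structure's van der Waals surface lies in the
closed interval [3 Å, 7 Å] (offset 3 Å, thickness 4 Å) — and each pair is
compared over the **intersection** of the two skins. The surface distance
of a grid point is approximated as min over atoms of (distance to the atom
centre − atom vdW radius); radii come from a built-in Bondi-style table,
with unknown elements defaulting to 1.7 Å under a logged warning. Note
that the skin's grid-point count is not monotone in the offset in general:
a free spherical shell of fixed thickness grows with its inner radius, and
only shrinks once the outward-moving shell is clipped by the grid
boundary.

Grids default to 65×65×65 points at 1.5 Å spacing centred on the
structures' common centre of mass, the standard configuration for
whole-domain protein comparisons. Production potentials come from a
Poisson–Boltzmann solver (the OpenDX reader consumes APBS output
directly); the built-in generator is an unscreened Coulomb sum
V(p) = Σ_k q_k / max(|p − r_k|, ε) with ε = half the smallest grid
spacing. The clamp only bounds values near charge centres; it is a
fixture-generation convenience, not a solvent model.

**Sequence similarity.** Pairwise optimal Smith–Waterman local alignments
under PAM250 with affine gaps: a gap of length L costs
gap_open + gap_extend·(L−1), defaults 10.0 and 0.5 (the EMBOSS `water`
convention; some tools charge open+extend on the first position). The
PAM250 matrix is vendored as a checksummed text file; the ambiguous
residue X scores 0 against every letter, itself included. Two similarity
definitions are available, since percent identity and normalized score
weight divergence differently: `identity` = identical residues / aligned
columns (gapped columns count in the denominator — a single substitution
in a 167-residue sequence gives 166/167 ≈ 0.994), and `normalized_score` =
score_ij / √(score_ii · score_jj) ∈ (0, 1].

**Conversion.** Any similarity matrix with entries ≤ 1 becomes a distance
matrix via D_ij = √(2 (1 − SI_ij)): D(1) = 0, D(0) = √2, D(−1) = 2,
strictly decreasing in SI. The inverse SI = 1 − D²/2 round-trips exactly.
The summary statistic C_SIM is the mean similarity over the N(N−1)/2
unordered pairs (strict upper triangle, so self-similarities never enter).

## Chaotic map clustering

Each item i carries a map variable x_i ∈ [−1, 1] evolving synchronously as

    x_i(t+1) = (1/C_i) Σ_{j≠i} J_ij f(x_j(t)),     f(x) = 1 − 2x²,

with couplings J_ij = exp(−D_ij²/2a²), normalizers C_i = Σ_{j≠i} J_ij, and
local scale a = the mean over items of the mean distance to each item's K
nearest neighbours. Initial states are drawn uniformly from [−1, 1] with
the run's seed. f maps [−1, 1] into itself and each update is a convex
combination of f values, so trajectories never leave [−1, 1]. After a
burn-in, each map is reduced to the bit sequence S_i(t) = [x_i(t) ≥ 0] and
pairwise synchronization is scored by the empirical mutual information
I_ij = H_i + H_j − H_ij (natural log, 0·ln 0 := 0, clipped to [0, ln 2]).
Thresholding I_ij > ϑ (strict) and taking connected components yields a
partition at every ϑ in [0, ln 2]; since raising ϑ only removes edges,
partitions refine monotonically and the cluster entropy
S(ϑ) = −Σ (N_i/N) ln(N_i/N) is non-decreasing. The selected solution is
the partition held over the longest run of consecutive ϑ bins — identical
partitions imply an exactly flat entropy plateau, so "flattest plateau" is
operationalised as run length rather than a numeric |dS/dϑ| test — with
ties broken to the lowest ϑ and the run's midpoint reported. A fixed
`theta_override` bypasses selection when a documented threshold is wanted.

**Defaults and parameters.** n_iter = 10000 total updates with a
transient of 1000 discarded before bits are recorded (the burn-in length
is exposed; synchronization is typically reached within a few hundred
steps at these problem sizes). ϑ sweep bin width 0.01. Presets bundle
the (K, ϑ) pairs used for the analyses the toolkit was built around:
whole-structure electrostatics (K=16, ϑ=0.06), subsite/sequence analyses
(K=10, ϑ=0.08), ligand shapes (K=2, ϑ=0.08).

**Dense versus sparsified couplings.** By default every pair is coupled:
the Gaussian decay already makes couplings negligible beyond a few local
scales, and fully coupled groups synchronize reliably. An optional
`sparsify` mode restricts J to the symmetrized K-nearest-neighbour graph
(K = N−1 recovers the dense variant exactly). The sparse variant is kept
because it is a common formulation, but it is not the default: on planted
benchmarks, K-NN-sparsified lattices were observed to leave true clusters
only partially synchronized (intra-cluster MI near 0 for some members),
splitting them spuriously.

**Small clusters do not synchronize.** Under the update rule above, a
pair of mutually coupled maps exchanges orbits — each map receives f of
the *other* map's state — so two (or three) co-located items never reach
I ≈ ln 2 and surface as singletons. The stability argument: deviations
from the synchronized manifold contract roughly by |f′|/(n−1) per step,
with the geometric mean of |f′| equal to 2 for the α=2 logistic map, so
contraction requires group size n ≥ 4 and is robust for n ≥ 5–6. This is
a property of the dynamics, not an implementation choice; the
synthetic-data defaults use group sizes ≥ 6 accordingly, and recovery
claims should not be extrapolated to 2–3-member clusters.

**Isolated items.** An item with C_i = 0 (possible only in sparsified
mode) evolves autonomously as x ← f(x) and becomes a singleton.

## UPGMA baseline

Size-weighted average linkage ("true" UPGMA, not WPGMA): the distance
between clusters is the mean over all leaf pairs, maintained by the update
d(A∪B, C) = (|A| d(A,C) + |B| d(B,C)) / (|A|+|B|). Merge nodes sit at
half the linkage distance, so the tree is rooted and ultrametric, and an
ultrametric input is reproduced exactly by the tree's cophenetic
distances. Ties break on the lexicographically smallest cluster-label
pair, making trees reproducible across platforms. Newick output writes
branch length = parent height − child height.

## Synthetic data

The generators produce inputs whose true partition is known by
construction, at the separations where the method is expected to work:

* `planted_distances` — uniform noise around an intra-group mean
  (default 0.1 ± 0.02) and an inter-group mean (default 2.0 ± 0.2), a
  20:1 separation comparable to converting similarities ≈ 0.995 within
  classes versus ≈ 0 between them. Uniform (not Gaussian) noise keeps
  every draw non-negative by construction.
* `charge_family_grids` — per group, a base system of 20 point charges
  (positions uniform in a central 15 Å box, standard-normal charges);
  members add N(0, σ) noise to the charges (default σ = 0.05) and grids
  come from the Coulomb generator on the default 65³ geometry.
* `mutated_sequence_family` — a random 167-residue base sequence; group
  ancestors differ from it by `between_subs` substitutions (default 30),
  members from their ancestor by `within_subs` (default 1, the
  single-point-mutation regime where identity ≈ 0.994), uniform over the
  19 non-identical residues.

What these fixtures do **not** emulate: real electrostatics (no
dielectric screening, no solvent, no correlated charge placement), real
sequence evolution (no indels, no substitution-rate structure), and real
structural noise (no missing residues, no conformational change). Passing
recovery tests therefore demonstrates that the algorithmic chain is
correct at honest separations, not that any particular protein family
would cluster cleanly.

## Numerical choices and conventions

* Matrices are symmetrized by averaging with their transpose after a
  symmetry check (1e-9 in memory, 1e-6 on file input), so downstream code
  assumes exact symmetry.
* Bitization uses x ≥ 0 → 1; the link condition is strict (I > ϑ);
  plateau ties break to the lowest ϑ.
* MI is clipped to [0, ln 2] against round-off; the MI diagonal stores
  each map's own entropy H_i.
* K-nearest-neighbour selection uses a stable argsort, so distance ties
  resolve to the lower index deterministically.
* OpenDX files store values with z varying fastest (the OpenDX
  convention), pinned by a hand-written 2×2×2 fixture test; only
  axis-aligned grids are supported.
* One seeded `numpy` generator per run; everything downstream of a seed
  is bit-reproducible, and workflow manifests record parameters and input
  checksums so artifact directories can be regenerated byte-identically.

## Problem sizes used in the validation suite

The test and acceptance runs use full dynamics (10000 iterations) on
matrices up to N = 60, Coulomb grid families on 17³–65³ geometries, and
sequence families of ~12 members × 120–167 residues — sizes chosen so the
whole suite documents the method's behaviour in minutes on a single core.
The clustering engine itself is O(N²) per iteration and handles the
hundreds-of-items regime the front-ends target.

## Known limitations

* Clusters of fewer than four items are structurally invisible to the
  dynamics (see above) and appear as singletons.
* The plateau criterion assumes the MI distribution separates cleanly;
  on weakly structured data the longest plateau can be the all-singleton
  (high-ϑ) regime, in which case a domain-informed `theta_override` is
  the intended escape hatch.
* The Coulomb generator is deliberately naive; do not interpret its
  grids physically.
* Skin masks use the nearest-atom-surface approximation rather than the
  true vdW surface; for tightly packed structures the difference is
  below the grid spacing.
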