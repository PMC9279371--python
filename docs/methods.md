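# Methods

This note documents the model behind `mcbuild`, the defaults that matter,
the numerical choices, and what the synthetic fixtures do and do not
demonstrate.

## The probability-field model

All scoring derives from a single resolution-dependent Gaussian kernel.
For a map of nominal resolution `R` (Å):

    lam   = (pi / (2.4 + 0.8 R))^2        [Å^-2]
    theta = (lam / pi)^1.5                [dimensionless]

`lam` decreases monotonically with `R` (fuzzier maps, wider kernels);
`theta` is the natural normalization of an isotropic Gaussian of decay
`lam` and makes grid correlation scores commensurate with the continuous
match score. A simulated main-chain probability map is the max-of-Gaussians
field over all main-chain atoms (N, Cα, C):

    p(x) = max_a exp(-lam ||x - a||^2)

The *max* (not sum) matters: p is a probability-like quantity in (0, 1],
equal to 1 exactly at atom positions, and does not inflate in dense
regions. Contributions below 1e-12 are truncated (the value is then set by
the nearest atoms only); kernel sums elsewhere in the package truncate at
1e-4 relative weight, recorded as `KERNEL_TRUNCATION`.

## Map preprocessing

Externally supplied maps are resampled to an isotropic grid (default
1.0 Å) by tensor-product cubic splines with not-a-knot boundaries, applied
axis by axis. This interpolant is exact at the original samples and for
polynomial fields up to degree 3 including at the boundary; scipy's
`RegularGridInterpolator(method="cubic")` was found *not* to interpolate
exactly at nodes (~2e-5 error) and is deliberately not used. Densities are
clipped at zero and scaled by the 99.999-percentile value (linear
interpolation between order statistics), then clipped to 1.0 — a single
outlier voxel therefore cannot compress the dynamic range. Axis-permuted
MRC files are normalized to internal (x, y, z) order on read; the MRC
ORIGIN record takes precedence, with nstart·voxel as the fallback.

## Mean-shift point reduction

Seeds start at every voxel with p above 0.1 (configurable down to 0; the
near-zero bulk of a continuous field contains no additional maxima) and are
shifted by the kernel-weighted mean of grid points,

    z <- sum_n K(z - x_n) p(x_n) x_n / sum_n K(z - x_n) p(x_n),
    K(d) = exp(-lam ||d||^2),

until the per-iteration displacement falls below 0.01 Å or 100 sweeps.
The two sums are, as functions of continuous z, Gaussian convolutions of
`p` and `p·x`; they are computed once on the grid with separable Gaussian
filters and evaluated off-grid by cubic-spline interpolation. This is two
orders of magnitude faster than per-seed neighbor sums and positions modes
to well under the convergence tolerance; the single approximation is the
spline evaluation between voxels.

The per-seed probability is P(z) = (1/N) Σ K(z−x_n) p(x_n) with N the
total voxel count. Any constant N rescales every match score uniformly and
cannot change a ranking; absolute match-score values in this package are
therefore *not* comparable to scores from other implementations whose
normalization differs, and any fixed reporting threshold on fragment scores
must be recalibrated for this scale. The threshold constant exposed in
`quality.py` is reporting metadata, not a decision rule.

Converged seeds are reduced by **greedy highest-probability suppression**
at a merge distance (default 1.0 Å, one map grid interval): visit seeds in
decreasing P, keep one, suppress all seeds within the merge distance,
repeat. On smooth fields the mean-shift endpoints line up quasi-
continuously along ridges (nearest-neighbor spacing ~0.1 Å on a helix
field); transitive single-linkage merging would chain an entire ridge into
one cluster and collapse the reduced representation to a single point,
which motivated the suppression rule. It also guarantees the stated
invariant that output points are pairwise at least the merge distance
apart.

Two empirical properties of this reduction worth knowing:

* **Mode retreat.** Modes of the smoothed field sit near the local
  centerline of the backbone tube and pull inward at chain termini. At
  R = 4 Å every interior Cα lies within merge_dist + spacing (2 Å) of a
  point; at R = 6 Å the helix Cα ring (radius 2.3 Å) is up to ~3.2 Å from
  the near-axis ridge, and termini up to one kernel width. This is physics
  of kernel smoothing, not an implementation artifact.
* **Helix direction ambiguity.** An ideal α-helix maps onto itself under a
  180° flip combined with an axial rotation; at 6 Å the reduced point set
  retains almost no azimuthal phase, so the flipped pose scores within
  ~0.5% of the true pose. Direction recovery for isolated idealized helices
  at this resolution is intrinsically unreliable; real (irregular) folds
  and assembly context break the degeneracy.

## Rigid fitting

Orientations come from a sin(β)-weighted Euler lattice: β on [0°, 180°)
and γ on [0°, 360°) at the angular step, and per-β-ring α counts
max(1, round((360/step)·sin β)), deduplicated by quaternion angular
distance (0.5° tolerance). At 15° this yields exactly 4392 orientations
(183 rings × 24 γ); the construction is frozen.

For each orientation the centered chain is rasterized onto the same grid as
the point set (1.5 Å spacing; the box is the point-set extent zero-padded
by the chain radius on every side, kept rectangular rather than cubic — the
correlation is identical and elongated boxes waste >5× FFT volume when
forced cubic) and all circular translations are scored with one
forward/inverse FFT pair. The grid score is used *only* to harvest the top
3 translations per rotation; every candidate is re-scored with the
continuous match score against the weighted points and the best `M`
(default 10) are kept.

Simplex polish: Nelder–Mead over 3 rotation increments about the posed
chain's centroid plus 3 translations; initial steps 5° / 2.0 Å, at most 500
evaluations, parameter tolerance 1e-3 (the function tolerance is kept very
small relative to the score scale so that termination is governed by the
simplex size). The refined pose is returned only if it scores at least as
well as the start, so refinement can never worsen a pose.

## Domain refinement

Domains come from an external segmentation sidecar (several candidate
assignments; the one with the most domains, all of at least 30 residues, is
selected) or from configured equal splits. Domains sharing sequence-
adjacent residues are connected in an undirected graph; from each seed
domain a single breadth-first pass visits every domain once (ties by
ascending id, disconnected components appended), simplex-optimizing each
domain's own six parameters against the points while the others stay
frozen. Because the atom-level score is a sum over atoms and each domain
optimization never worsens its own partial sum, the aggregate score is
monotone in the rigid parent. No covalent linker restraint is applied
during refinement; inter-domain junction distances are reported so that
chain breaks are visible, and stereochemical regularization is left to
external refinement tools. `M` rigid poses × `n` seed choices plus the `M`
rigid parents are pooled and ranked.

## Assembly

Clash constants: d_clash = 3.0 Å (saturation cutoff), C_thr = 0.1 (edge
threshold), K = 10 candidate placements per chain copy; all configurable
and deliberately permissive for toy systems. Clashes are evaluated over
main-chain atoms, keeping the whole method self-consistent. The directed
chain clash is asymmetric; an undirected compatibility edge requires the
max of both directions to stay at or below the threshold. Identical chain
copies (same sequence and coordinates) share one fitting run per cycle.
Maximal cliques are enumerated with Bron–Kerbosch with pivoting
(networkx `find_cliques`); since scores are non-positive, the best
combination is always attained on a maximal clique. Ties prefer more chains
placed, then the lexicographically smallest vertex set — determinism
matters more than the choice itself. Placed chains leave the vertex set but
clash-screen later candidates pairwise, and point probabilities are
multiplied by (1 − clash) after every commit, so later cycles fit into the
unoccupied remainder of the map. The loop ends when all copies are placed
or a cycle places none.

## Quality scores

Per-residue raw scores are means over the residue's available main-chain
atoms (residues with none are excluded and written with the 999.99
sentinel). Fragments are maximal runs of identical secondary-structure
labels (external labels, or a fallback that marks residues helical when the
Cα(i)–Cα(i+4) distance is under 7 Å); every fragment receives a score for
blending, but only runs of ≥ 5 residues enter fragment-level reports.
Blends are fixed 0.7/0.3 convex combinations (fragment with its domain,
residue with its fragment); smoothing uses the 1:2:4:8:16:8:4:2:1 window,
truncated and renormalized at termini, skipping excluded residues. The
alignment score against a reference uses index-paired Cα distances in the
shared map frame with **no superposition** and fixed d0 = 3.0 Å.

## Synthetic fixtures and their scope

Fixtures are deterministic given a seed: ideal α-helices (Cα rise 1.5 Å,
twist 100°/residue, radius 2.3 Å; N and C at fixed offsets in the residue
frame) and self-avoiding random walks (3.8 Å Cα bonds, 4.0 Å excluded
volume). Complexes place chains at known poses (verified clash-free),
simulate the map from the ground truth at R = 6.0 Å — the middle of the
intermediate-resolution regime — and hand the pipeline only the re-centered
(optionally hinge-perturbed) input chains. Default problem sizes (40-residue
chains, ~50–80 Å boxes at 1 Å spacing, a reduced 30° rotation set in tests)
keep every stage runnable in seconds to a couple of minutes on one core;
they were chosen as the smallest systems on which pose recovery is
non-trivial.

What passing fixtures shows: the search, refinement, assembly, and scoring
machinery recover known ground truth through the public interfaces. What it
does not show: robustness to experimental noise, anisotropy, missing
density, prediction error in externally supplied probability maps, or
sequence-register errors — none of which the analytic map model emulates.

## Known limitations

* Probability-map prediction from raw experimental density is external.
* Match-score absolute scale depends on the voxel-count normalization of
  P(z) (see above); use scores comparatively within a run.
* B-factor columns hold smoothed residue scores at PDB's two-decimal
  precision; on this normalization they may underflow the column and are
  best read from `quality.tsv`.
* No symmetry constraints, nucleic-acid chains, or ligands.
* Nonorthogonal map cells are rejected rather than reinterpreted.
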