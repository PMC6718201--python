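# Methods

## Problem setting and conventions

A still diffraction pattern yields K Bragg peaks. Through the experiment
geometry (wavelength λ in Å, flat detector panel at distance D mm, pixel
size p mm, beam centre in pixels, beam along +z) each peak maps to a
momentum-transfer vector

    q = (ŝ − ŝ₀) / λ ,

with ŝ₀ the unit incident-beam direction and ŝ the unit vector toward the
peak's lab-frame position. All q lie on the Ewald sphere of radius 1/λ
centred at −ŝ₀/λ, and |q| = 2 sin θ / λ. We use the crystallographic
convention (no 2π), so for a real-space lattice vector t of the crystal,
q·t is an integer whenever q sits on the crystal's reciprocal lattice. We
call the observed q vectors *nodes*: noisy samples of reciprocal-lattice
points, possibly contaminated by spurious detections and by nodes of other
crystals. Real space is measured in Å, reciprocal space in Å⁻¹. A lattice
basis is a 3×3 matrix with rows a, b, c; the fractional Miller indices of a
node are (a·q, b·q, c·q) and the predicted position for integer indices h
is h·(B⁻¹)ᵀ.

The sign conventions for ŝ₀ and the detector axes are internal choices;
correctness of the mapping is defined by round-trip consistency with its
inverse projection, which the tests check against an independently coded
inverse. Multi-panel geometries, per-event wavelength jitter and
polarization corrections are out of scope.

## Score function

Every node generates the real-space plane family {t : q·t ∈ ℤ}, orthogonal
to q with spacing 1/|q|. Lattice vectors lie where plane families from all
(true) nodes intersect. The score of a trial vector is

    S(t) = Σₖ wₖ c(xₖ) / Σₖ wₖ ,   xₖ = q·t − round(q·t) ∈ (−0.5, 0.5],

with a proximity function c that is even, periodic with period 1, equals 1
at 0 (on a plane) and −1 at ±0.5 (midway), and is non-increasing on
[0, 0.5]. Four members are implemented:

| kind     | form                                               | character |
|----------|----------------------------------------------------|-----------|
| cosine   | cos 2πx                                            | smooth; S is the real part of the Fourier transform of the nodes |
| triangle | 1 − 4·abs(x)                                       | linear interpolation between planes |
| sharp_a  | Gaussian bump, σ = 0.1, affinely scaled to [−1, 1] | smooth, narrow |
| sharp_b  | narrow triangle, half-width 0.15                   | piecewise linear, narrow |

Any function satisfying the defining properties is admissible; these four
were chosen to span the smooth/sharp and cheap/local axes the staged
heuristic needs. The midpoint tie x = ±0.5 is broken toward +0.5.

The tolerant variant excludes nodes whose nearest plane is farther than a
fractional tolerance ε (default 0.15, configurable):

    S_ε(t) = Σ_{k: |xₖ| ≤ ε} wₖ c(xₖ / 2ε) / Σₖ wₖ .

Two choices here were genuinely open. The argument is rescaled by 1/(2ε) so
the included band spans the proximity function's full dynamic range, and
the normalization runs over *all* node weights — not only the included ones
— so that a vector explaining few nodes is penalized rather than rewarded;
an empty inclusion set scores −1. The price of exclusion is that S_ε is
discontinuous across inclusion boundaries; the analytic gradient is exact
almost everywhere and one-sided at the kinks of the piecewise-linear
members.

Weights are unity by default. The first search stage uses inverse-radial
weights wₖ = 1/|qₖ|, which damp the short-period plane families of
high-resolution nodes and keep the early score surface smooth. Intensity
weighting is available but off by default: peak intensity carries little
information about lattice-plane geometry and the unweighted heuristic
proved at least as robust.

## Maxima search

Starting points fill the search volume: either a shell r_min ≤ |t| ≤ r_max
(unknown cell; defaults 20–300 Å) or thin shells of half-width 1 Å at the
known axis lengths, optionally extended by the |a+b|, |b+c|, |a+c|
face-diagonal lengths. Points are placed on concentric spheres built from a
Fibonacci spiral lattice (deterministic, O(n), nearest-neighbour spacing
within a factor ~2 of the ideal (4π/n)^½ — sufficient approximate
uniformity for this use). The radial increment between spheres equals the
sphere's own average point spacing, each sphere gets an independent seeded
random rotation, and — because even proximity functions make S
centrosymmetric — only one point of each antipodal pair is kept (fixed +z
half-space, lexicographic ties on the equator).

Each point climbs S with an extended gradient rule. The ascent direction is
the normalized gradient; if it turns back on the previous step (cosine
below −0.8), the new direction is the normalized sum of the two unit
directions, which breaks zigzag trajectories cheaply; an exactly antipodal
proposal falls back to a deterministic orthogonal direction. The step
length is not the gradient magnitude (near these maxima gradients are
large, which would overshoot) but an adaptive quantity:

    new_len = clip(prev_len · turn · (1 + γ(1 − S)/2), min_step, max_step)

with turn = 1.5 when the direction persists (cos > 0.7), 0.5 on a reversal
(cos < 0), 1 otherwise; defaults γ = 1, min_step = 0.01 Å, max_step = 2 Å,
initial length 1 Å. Steps grow on straight runs, shrink on turns, and slow
as S → 1. A zero gradient freezes the point and resets its step to
min_step.

The staged schedule (step counts fast/precise profile):

1. cosine, plain score, inverse-radial weights — 40/60 steps, full cloud;
   large convergence radius.
2. sharp_b, tolerant score, unity weights — 20/30 steps.
3. sharp_a, tolerant — 8/12 steps; precise localization.
4. sparse peak finding: only points that score highest within a 2 Å
   environment radius survive (score ties broken by index), at most 50
   kept.
5. sharp_a, tolerant — 30/60 fine steps on the survivors, then a final
   score evaluation orders the candidate lattice vectors.

The step counts, the two profiles (5 000 / 50 000 starting points) and the
2 Å environment radius were calibrated on the synthetic scenes described
below; all are configurable. Whether stage 4 ranks by the plain or tolerant
score was open; the tolerant (stage-3) score is used, as it is the quantity
the later stages optimize.

## Basis assembly and selection

From N ≤ 50 candidate vectors, candidate bases are formed as triples with a
filter cascade: vectors individually predicting fewer than 5 nodes are
dropped (a node is *predicted* when each fractional-index component is
within relative_tol = 0.15 of an integer; the value quantifies "correctly
predicted", which is otherwise a qualitative notion); pairs and then
triples must jointly predict ≥ 5 nodes; triples with |det| below
0.2·|a||b||c| (angle degeneracy) or 1000 Å³ (absolute floor) are rejected;
with a cell prior, candidates whose reduced cell differs by more than 5% in
lengths or 2.5° in angles are rejected; finally the best 500 by summed
vector score are kept.

Each kept basis is reduced to its shortest-vector form by iterated pairwise
Lagrange–Gauss size reduction plus ±1 cross-corrections over all three
vectors until no norm decreases — a greedy scheme that in three dimensions
attains the successive minima of the lattice (verified against brute-force
enumeration in the tests); the transform is unimodular so |det| is
preserved. For each reduced basis the *absolute defect* (mean
|q_obs − q_pred| over predicted nodes) and *relative defect* (mean
Euclidean distance between fractional and rounded integer indices) are
computed.

Selection shortlists the union of the 15 candidates with the best summed
scores and the 50 with the smallest relative defects (defect ties at the
candidate-noise level — bins of 0.02 — prefer the smaller determinant, so
primitive cells are not crowded out of the shortlist by their supercells).
Duplicated cells are collapsed beforehand. The shortlist is walked in
descending order of predicted-node count (ties: smaller |det| first, then
smaller defect); a candidate is accepted when it predicts at least five
nodes claimed by no accepted lattice, or replaces an accepted lattice when
it covers essentially the same nodes (≥ 80% overlap of the larger set) with
a relative defect below 0.7× the incumbent's and a determinant no larger
than the incumbent's (within 5%) — the determinant guard keeps the
replacement chain from drifting to supercells whose defects differ only by
noise. This yields several lattices in one pass; a delete-and-retry mode
(remove the strongest lattice's nodes, re-run, at most 5 rounds) is
available and is somewhat more reliable on multi-crystal patterns at extra
cost.

Two solution-significance guards close the pipeline, both needed because
the ≥ 5-node rule alone cannot reject chance fits when thousands of
candidate triples are screened: an accepted lattice must predict at least
25% of the pattern's nodes, and its refined relative defect must not exceed
relative_tol/3 (candidates are screened at twice that before refinement,
since unrefined defects carry the candidate-vector noise). A random node is
within tolerance of *any* basis with probability (2·relative_tol)³ ≈ 0.027
and chance inliers sit near the tolerance boundary, so genuine lattices
clear both guards by a wide margin while pure-noise patterns return no
solution. With these defaults a single lattice in a 3-lattice pattern still
clears the fraction guard, but heavily contaminated many-lattice patterns
may require lowering it.

Accepted bases are refined by alternating {inlier assignment →
least-squares update of the reciprocal matrix over the inliers}, accepting
an update only if the mean Euclidean node-prediction distance decreases; a
closed-form inner step was preferred over explicit gradient iterations
because the inner problem is linear, and the acceptance test keeps the
objective non-increasing by construction. Iteration stops when the
improvement falls below 10⁻⁸ Å⁻¹ or after 100 rounds, and aborts (keeping
the last valid basis) if the inlier count drops below five. Output bases
are reduced, sorted |a| ≤ |b| ≤ |c|, right-handed (det > 0).

## Synthetic scenes and evaluation

The generator draws 1–3 lattices of a given cell in uniformly random
orientations (random rotations), selects n distinct reciprocal-lattice
points within a resolution limit q_max, perturbs them with isotropic
Gaussian noise (rejection-truncated at 5σ so labels stay meaningful), and
appends spurious nodes. In `ewald_mode` (default) the lattice points are
restricted to a shell of half-thickness 0.002 Å⁻¹ around the Ewald sphere
(λ = 1 Å), mimicking still-image geometry — the nodes then sample a thin
spherical cap rather than a 3D ball, which is what makes supercell and
sublattice aliases a real hazard; spurious nodes are likewise placed on the
shell, as real false detections also originate on the detector. With
`ewald_mode` off the generator samples the full 3D ball, which the unit
tests use for closed-form checks.

Defaults define the study conditions: triclinic cell 35, 45, 60 Å / 85°,
95°, 100° (low symmetry, so basis-equivalence checks are unambiguous), 25
nodes per lattice, q_max = 0.25 Å⁻¹, noise expressed as a fraction of the
smallest reciprocal basis-vector length (1% in the noisy benchmarks, giving
σ ≈ 1.7·10⁻⁴ Å⁻¹), and a spurious count of 11 for the contaminated regime
(≈ 30% of the pattern, the 13-true/7-spurious ratio of the illustrative
example scaled to 25 true nodes).

A solution basis counts as correct when, after reducing both bases and
minimizing over the 48 signed axis permutations whose cell lengths match
within 5%, the proper-rotation (Kabsch) angle bringing it onto a true basis
is ≤ 3°. The Kabsch angle is computed by SVD superposition of the two
vector triads (det R = +1 enforced) and is cross-checked in the tests
against an independent quaternion-eigenvalue implementation. The 48-element
search is sufficient for primitive-cell comparison; centred-lattice
reindexing ambiguities are out of scope.

What passing these benchmarks does *not* show: the scenes have isotropic
Gaussian noise, no detector-geometry error, no intensity variation, no
resolution-dependent noise, and spurious nodes uniform on the shell rather
than clustered at shadowed panel regions — real-data indexing rates will
be lower and depend on peak-finder quality. Wall-clock performance is not
benchmarked.

## Benchmark problem sizes and numerics

The acceptance experiments use the fast profile (5 000 starting points)
with an unknown-cell shell of 20–100 Å — the "reasonable assumption" for
protein-scale cells that the benchmarks adopt; 100 scenes for the clean and
noisy single-lattice regimes, 50 per arm for the few-peak trend and the
two-lattice regimes, and 100 seeded refinement runs. These sizes give
percentage estimates with ~3–6 point standard errors while keeping the
whole suite in the minutes range on one CPU.

Numerical choices worth noting: fractional offsets are wrapped to
(−0.5, 0.5] with the tie toward +0.5; singular bases (|det| < 10⁻¹²) raise
errors rather than propagate; defect reports with zero predicted nodes use
an infinite sentinel; peaks at exactly zero scattering angle are dropped
with a warning rather than failing the pattern; and all randomness
(sphere rotations, scene generation, benchmark seeds) flows from explicit
seeds, making every pipeline run bit-reproducible.
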