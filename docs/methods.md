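# Methods

This note records the model, the algorithmic guarantees, the numerical
choices, and what the synthetic-data experiments do and do not establish.

## RMSD and superposition

For equal-length coordinate sequences **S**, **T** in dimension *d*,

RMSD(**S**, **T**) = min_{R ∈ SO(d), v} √((1/n) Σᵢ |sᵢ − (R tᵢ + v)|²).

The minimizing translation always superposes the centroids (expanding the
objective in v gives a quadratic minimized at the centroid difference, in
any dimension), so the problem reduces to Wahba's rotation problem on
centered coordinates, solved by Kabsch: with J = Σᵢ tᵢ sᵢᵀ and SVD
J = U Σ Vᵀ, the optimal proper rotation is R = V Uᵀ, unless
det(V Uᵀ) = −1, in which case the singular direction of the smallest
singular value is negated.  Rank-deficient J (collinear/coplanar points)
needs no special casing: the same sign rule applies and any minimizer is
acceptable because only the RMSD value propagates downstream.  A planar
point set therefore has RMSD 0 to its mirror image (it is achiral), while a
non-planar set does not — both cases are pinned by tests, the chiral one
against a brute-force rotation-search oracle.

Numerics.  The scalar kernel evaluates
n·RMSD² = Σ|s|² + Σ|t|² − 2(σ₁ + σ₂ ± σ₃) from singular values alone.
Near RMSD ≈ 0 this difference cancels catastrophically (absolute error
~machine-ε times the coordinate energy, i.e. RMSD error up to ~1e−8), so
whenever the computed n·RMSD² ≤ 1e−9 × (Σ|s|² + Σ|t|²) the kernel reforms
the explicit rotation and measures residuals directly, restoring ~1e−15
accuracy where tests and users expect exact zeros.  All equality-style
assertions in the test suite use 1e−9 absolute tolerance unless stated.
Both search engines share this one kernel so that engine comparisons test
search logic, not floating-point path differences; the kernel itself is
validated against independent oracles (random-rotation search, scipy's
`align_vectors`, closed forms).

## The half-split lower bound

For a chain **U** of length n, **U**ˡᵉᶠᵗ is its first ⌊n/2⌋ residues and
**U**ʳⁱᵍʰᵗ its last ⌊n/2⌋ (the middle residue of an odd-length chain
belongs to neither half; equal half sizes are what the proof needs).
F(**U**) = |G(**U**ˡᵉᶠᵗ) − G(**U**ʳⁱᵍʰᵗ)|/2 and
D(**S**, **T**) = |F(**S**) − F(**T**)|.

Proof of the bound.  Superpose **T** optimally onto **S** and let
δᵢ = sᵢ − tᵢ, so Σ|δᵢ|² = n·RMSD².  With h = ⌊n/2⌋, Cauchy–Schwarz gives
|G(**S**ˡᵉᶠᵗ) − G(**T**ˡᵉᶠᵗ)|² ≤ (1/h) Σ_left |δ|², likewise on the right.
Two triangle inequalities give D ≤ (a + b)/2 with a, b those two centroid
displacements, and (a+b)/2 ≤ √((a²+b²)/2) ≤ √(Σ|δ|²/(2h)) =
√(n/(2h))·RMSD.  For even n the factor is exactly 1: **D ≤ RMSD**.  For
odd n it is √(n/(n−1)) > 1, and the slack is real, not an artifact: for
**S** three coincident points and **T** = ((1,0,0),(0,0,0),(−1,0,0)),
D = 1 > RMSD = √(2/3).  The package therefore exposes
`half_split_slack(n) = sqrt(n/(2*floor(n/2)))` and multiplies every filter
threshold by it, so the no-false-negative guarantee holds for odd part
lengths too.  F is rigid-motion invariant, hence D needs no superposition
and costs O(1) per window once coordinate prefix sums are built (O(N) for
all windows of one length).

## The filter

The query is divided into 3k+2 parts of length m′ = ⌊m/(3k+2)⌋ plus an
unused remainder of length < 3k+2.  If **Q** matches at position i with
k′ + k″ ≤ k indels, at most k parts contain an indel and at most k more
straddle the induced frame shifts, so ≥ 2k+2 parts appear *ungapped* as
length-m′ windows of **P** starting within ±k of their nominal offset
i + (j−1)m′.  For such an ungapped pair the subsequence bound
RMSD(**S′**, **T′**) ≤ √(n/ℓ)·RMSD(**S**, **T**) (drop the non-selected
residuals from the optimal superposition of the full pair, then relax to
the subsequence optimum) caps the pair RMSD by √(m/m′)·c — using the full
query length m, which over-covers every reduced length m − k′ and is
therefore safe.  Replacing RMSD by D and multiplying in the odd-length
slack yields the implemented per-part test

D(**Q**ⱼ, **P**[ℓ..ℓ+m′−1]) ≤ c·√(m / (2⌊m′/2⌋)) for some
ℓ ∈ [i+(j−1)m′−k, i+(j−1)m′+k],

checked in O(1) per ℓ from the window table.  Positions with < 2k+2
hitting parts are provably non-matches; the rest are verified by
enumerating all (k′, k″) with k′ + k″ ≤ k and all deletion-index sets,
in lexicographic (k′, k″, query set, text set) order with
strict-improvement updates, so the reported witness is the
lexicographically smallest among the minimum-RMSD ones — a deterministic
tie-break shared verbatim by the brute-force engine.  Verification
enumerates the budget inequality k′ + k″ ≤ k (the problem definition),
not only the boundary k′ + k″ = k: the superset costs a constant factor
and makes the output match the problem statement exactly.

Queries with m < 2(3k+2) cannot be divided into parts of length ≥ 2 (the
half-split needs two residues per half); `search` then falls back to the
brute-force engine with a logged warning.

Multi-chain databases are concatenated once; the filter runs over the
concatenation, candidate positions whose minimal window (length m − k)
would cross a structure boundary are masked, and verification clips every
window at its structure's end.  Reported positions are 1-based and local to
their source structure.

## Average-case behavior

Under the freely-jointed chain (random-walk) model — fixed bond length r,
independent uniform bond directions, r = 3.8 Å for Cα traces — F of a
length-n window has a density with scale ∝ r√n, so Prob(D < c) = O(c/√n).
A part hits a position only if one of 2k+1 window starts passes the D
test, so the hit probability is O(k·c·√(3k+2)·(3k+2)/√m)... = O(c k²/√m),
and ≥ 2k+2 simultaneous hits occur with probability O(1/m^{k+1}) at fixed
c, k.  Hence the expected candidate count is O(N/m^{k+1}) and total
expected work O(k²N) + O(N) — linear in N.  These are *scaling laws*, not
theorems about any finite sample; the package tests them empirically:

- `lower_bound_tail_experiment`: Prob(D < c)·√n/c stays within a
  factor-3 band over n ∈ {16, 64, 256, 1024} and c ∈ {0.1r, 0.5r, r}
  (10⁴ pairs per cell, fixed seed).
- `candidate_scaling_experiment`: log–log slope of the mean candidate
  count versus m ∈ {40, 80, 160} at N = 2·10⁴, c = 0.1r is ≤ −(k+1)+0.5
  for k ∈ {0, 1} (30 replicates per cell); the counted step-1 cost is
  proportional to N by construction and asserted as such.  A zero mean in
  a cell is floored at half a count per replicate pool before taking logs;
  this can only steepen the observed decay, which is consistent with an
  upper-bound check.

The c = 0.1r default of the scaling experiment keeps the per-part hit
probability below saturation for k = 1 at the smallest m (at c = 0.5r the
filter saturates for small queries and the decay law is unobservable);
c ≈ 0.26r–0.5r corresponds to the practical 1–2 Å thresholds used for
protein searches at r = 3.8 Å.

## Synthetic data and planted instances

`generate_chain` emulates only the ideal chain: exact bond lengths,
uniform directions, no excluded volume, no dihedral or secondary-structure
preferences.  Green scaling tests therefore establish the algorithm's
behavior under its stated statistical model, not on PDB-like data; real
protein traces are stiffer and more self-similar, which changes the
constants (not the exactness guarantees, which hold for arbitrary input).

`plant` builds ground-truth instances: delete chosen query residues
(query-side witness k′), insert spurious residues (text-side witness k″,
coordinates interpolated between neighbors plus a bond-scale/2 Gaussian
kick), apply a uniformly random proper rotation about the copy's centroid,
translate onto the replaced text window, then add isotropic Gaussian
noise.  No noise model is implied by the search problem itself; isotropic
Gaussian is chosen purely for test construction, and the recorded witness
RMSD is recomputed from the final coordinates, never assumed.  A
per-coordinate σ gives witness RMSD ≈ σ√3 (slightly less after
superposition); σ = c/(2√3) targets RMSD ≈ c/2.

## Hardness demonstration

The geometric reduction needs, for each graph, a point set in n−1
dimensions with pairwise distance α on edges and β elsewhere.  The package
constructs it by classical multidimensional scaling (double-center the
squared-distance matrix, eigendecompose, scale eigenvectors) and *checks*
positive semidefiniteness per instance instead of assuming that every
0 < α < β < 2α is realizable: with α = 1, β = 1.05 the Gram matrix is
β²/2·P + (β²−α²)/2·PAP on the centered subspace, and the perturbation is
far too small to create a negative eigenvalue for any graph at the demo
scale (n ≤ 14, enforced), whereas β = 1.9 already fails for K₃,₃ — the
error message names the offending eigenvalue.  The closed form
RMSD = √(α²x + β²(C(k,2) − x))/k follows from the centroid identity
Σᵢ|pᵢ − G|² = (1/k)Σ_{i<j}|pᵢ − pⱼ|², and every tested subset checks it
against the general superposition routine, which simultaneously exercises
the arbitrary-dimension Kabsch path.  Equal edge counts give equal RMSDs
to ~1e−16, so argmin ties are harmless.  The module is a demonstration of
the reduction's mechanics at exhaustive scale, not a subgraph solver.

## Known limitations

- Average-case linearity carries the constant c^{2k+2}·k^{5k+4}; the
  filter is ineffective (though never incorrect) when c approaches r or
  when m is small relative to 3k+2, where it degenerates toward the
  brute-force cost.
- Verification is exponential in k (deliberately: exactness); k ≤ 3 is
  the practical regime, matching the constant-k assumption.
- The PDB reader keeps file order and drops residues without Cα atoms;
  chain breaks are not modeled beyond the indel budget itself.
- Positions are reported per structure; alignment *scores* (gap
  penalties, partial matches above c) are out of scope — the model is a
  hard indel budget under a hard RMSD threshold.
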