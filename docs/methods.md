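# Methods

## Model and cone

A metabolic network is the stoichiometric matrix S (m metabolites × r
reactions, dimensionless coefficients) with per-reaction reversibility and
exchange flags. Internal metabolites are assumed at pseudo-steady state,
S·v = 0. Extreme pathways are defined on the augmented matrix
S' = [S | −S[:, R_R]]: each reversible *internal* reaction contributes a
negated backward column, making the cone {v' ≥ 0, S'v' = 0} pointed. The
package enumerates the extreme rays of that cone.

Two split policies are offered. `internal-reversible` (default) splits only
reversible non-exchange reactions. A model whose *exchange* reactions are
reversible then has those backward directions excluded from the cone, which
restricts it; the loader logs this and `all-reversible` splits every
reversible reaction instead. Both are exposed because published models
differ in how boundary reversibility is meant.

Augmented solutions are projected back to original coordinates as net flux,
v[j] = v_forward[j] − v_backward[j]. The projection maps the augmented
nullspace into the nullspace of S exactly.

## Engines

**Canonical basis approach (CBA).** The tableau starts as [I | S'ᵀ]: every
unit flux vector, with a tail holding each metabolite's accumulation.
Iteration k partitions rows by the sign of metabolite k's accumulation into
T0/T+/T−, carries T0, and replaces the (+,−) pairs by the nonnegative
combinations

c = T[j+, col]·T[j−, :] − T[j−, col]·T[j+, :]

whose processed column is exactly zero. Both coefficients are positive, so
flux nonnegativity is preserved; previously zeroed columns stay zero
because the combination is linear. Each combined candidate must pass an
elementarity test (below) before entering the next tableau. After the last
metabolite the tableau rows are the extreme pathways.

**Nullspace approach (NSA).** The tableau starts from a rational kernel
basis of S' computed by reduced row echelon form; the free columns give a
permutation-identity sub-block (recorded as `identity_cols`). Steady state
holds for every row from the start, and the engine imposes v' ≥ 0 instead:
columns with any negative entry are processed in ascending index order,
keeping T0 ∪ T+ and consuming T− into combinations (the standard
double-description convention for one-sided constraints). Candidate gating
is identical to CBA.

Initial kernel rows that are already nonnegative and never enter a
combination are vetted against the full-support nullity condition before
output — a basis row can be nonnegative without being extreme. Rows that
passed a mid-run test need no re-check: their kernel-coefficient vector is
nonzero and vanishes on the zero set, so the kernel submatrix rank over the
full zero set is sandwiched between the mid-run value (q − 1) and q − 1.

**Stochastic filter.** With N = |T+|·|T−| candidate pairs in an iteration,
each pair is kept with probability P = K/(N + K), computed once per
iteration *before* any gating, and gating happens *before* elementarity
testing — the ordering that keeps memory and test counts proportional to
the kept candidates. K = ∞ disables the filter (P = 1); N = 0 is vacuous
(P = 1); K = 0 is rejected at configuration time. Gate verdicts are drawn
from per-candidate RNG substreams keyed by (seed, iteration, lexicographic
candidate index) via numpy `SeedSequence` spawn keys, so results are
independent of evaluation order and of `--workers`.

## Elementarity tests

Support: Z̄(v) = indices with |v_i| > tol·max(1, max|v|); exact mode uses
tol = 0.

* **Nullity test** (CBA, iteration k): `nullity(S'[1..k, Z̄]) = 1`, where
  nullity = columns − rank. At k = 0 the nullity of a 0-row matrix is
  defined as the column count, making the test total from the first
  iteration (only singleton supports pass).
* **Positive-definite (Gramian) test** (CBA): append a strictly positive
  row a to S'[1..k, Z̄]; by Gordan's theorem — valid precisely because the
  candidate is nonnegative and nonzero on Z̄ — the appended row absorbs
  exactly one nullspace dimension, so elementarity ⇔ the extended matrix
  has full column rank ⇔ its Gramian is positive definite. The full-width
  Gramian G = Σ_{i≤k} s_i s_iᵀ + aᵀa is maintained across iterations by
  rank-1 updates; each candidate slices G[Z̄, Z̄]. Default a = all-ones
  (keeps G integer for integer S); the verdict is invariant to any positive
  a, which is property-tested.
* **Kernel-structured reduced test** (NSA): with q kernel rows, a candidate
  with zero set Z is elementary over the processed columns iff
  rank(kernel[:, Z ∩ processed]) = q − 1. Identity columns inside the zero
  set contribute one independent column each, leaving a rank computation on
  the remaining rows and non-identity columns only. The structural
  precondition is checked on every call; on violation the engine logs a
  warning and evaluates the direct rank condition.

The PD/nullity equivalence is asserted empirically on every candidate of
the verification suite (tens of thousands per run), together with the exact
offset identity nullity(S* slice) = nullity(S' slice) − 1.

## Arithmetic and numerics

Default arithmetic is exact: coefficients are stored as stdlib
integers/Fractions, tableau rows are GCD-reduced to coprime integers after
every combination (rays are scale-free, so this only controls magnitude
growth), rank comes from rational row reduction and positive definiteness
from Sylvester leading minors evaluated by fraction-free (Bareiss)
elimination, whose pivots are exactly the leading principal minors.

Float mode mirrors every step with numpy: rank by SVD thresholding
(σ > max(m,n)·σ_max·10⁻¹²), positive definiteness by attempted Cholesky
with pivot acceptance d > n·√ε·max-diagonal (ε = 2⁻⁵²; the √ε scale sits
orders of magnitude above the pivot residue that accumulated roundoff
leaves on exactly singular Gramians, and orders below the smallest pivots
of genuinely positive-definite support Gramians of small-integer networks),
a relative zero tolerance of 10⁻⁹ for supports and sign partitions, and
per-combination rescaling to unit max entry (the float analogue of GCD
reduction — without it row magnitudes drift and relative tolerances
misclassify). Float rows wider than a configurable threshold (default 200
columns) are stored as scipy CSR vectors; storage must not and does not
affect results (tested by forcing the threshold down). Exact rows stay
dense object arrays.

## Output conventions

Rays are normalized (coprime integers in exact mode, max entry 1 in float
mode), deduplicated by value, and reported in both augmented and original
coordinates. Futile 2-cycles — rays supported exactly on one split
forward/backward pair, with zero net flux — are genuine extreme rays of the
augmented cone but pure augmentation artifacts, and are dropped from engine
output by default (`--keep-futile` retains them; oracle comparisons in the
tests run with them kept on both sides). No other ray can use both
directions of a split pair: the 2-cycle would be a strictly smaller
elementary support inside it; this is asserted on every run. Metabolite
processing order defaults to natural row order; a greedy `min-product`
order (fewest |T+|·|T−| next) is available — order affects which rays
survive *sampling*, never the K = ∞ set.

## Verification oracle and synthetic data

`brute_force_rays` enumerates all 2^r' supports in increasing cardinality:
a support is an extreme ray iff its column submatrix has nullity 1 with a
strictly one-signed nullspace vector. Supports containing an accepted
support are pruned (minimality), which is verified once against the
unpruned enumeration. The oracle deliberately runs on numpy's float SVD
path — independent of the engines' exact arithmetic — and is guarded at
r' ≤ 20 (override with force).

The random-network generator emulates desk-scale stoichiometry: integer
coefficients in [−3, 3] (magnitude bound configurable) at density 0.4, one
guaranteed producer and consumer per metabolite, reversibility and exchange
flags at rates 0.3 and 0.2. The verification suite draws m ∈ [3, 8],
r ∈ [4, 12] so that r' stays within oracle reach; the filter-sweep fixture
(m = 7, r = 12, density 0.45, coefficient bound 2, seed 3) was chosen for
a candidate-rich profile — 13 extreme pathways and per-iteration candidate
counts in the hundreds, so finite K actually bites. What these networks do
*not* emulate: genome-scale sparsity patterns, conserved moieties and
compartment structure of curated models, or coefficient magnitudes beyond
small integers; passing the suite therefore demonstrates algorithmic
correctness at oracle scale, not genome-scale performance. The only real
model exercised is the E. coli central-carbon network (95 reactions, 72
metabolites), for dimension and loader checks.

## Problem sizes and limitations

The shipped verification suite runs 50 random networks (oracle + three
engines), a 30-seed filter sweep at three K values, and the fixture set —
a few minutes on one CPU. The brute-force oracle is exponential by design
and is the scale limit of *verification*, not of the engines; the engines
themselves are limited by tableau growth at high K. Exact arithmetic on
Python objects trades speed for bit-exact reproducibility; float mode with
sparse storage is the path intended for larger models. LP-based
one-pathway-at-a-time generation, tree-based candidate narrowing, and
elementary-flux-mode augmentation variants are out of scope.
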