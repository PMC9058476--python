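# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic generator does and does not
emulate.

## Data model and conventions

A NAC table is an N × V matrix (atoms-in-molecules × methods) in
elementary charge units, with a molecule id per row and an integer net
charge per molecule.  All statistics default to the **population**
convention M = N (divisor in σ and Λ); the sample convention N − 1 is
available but must be applied uniformly to every variable in a joint
analysis, since mixing conventions breaks the correlation identities.
Missing values are never imputed: statistical operations reject tables with
missing cells, and the consistency checker reports them instead.

## Consistency checking

Molecules are greedily packed, in file order and never split, into blocks
of ≥ `target_size` atoms (default 500).  For each (block, method) the NAC
sum should land on the summed integer net charge of the block's molecules.
The distance to the *nearest* integer is graded against two tolerances:

* `tol_negligible` = 0.01 e — below this, residuals are attributed to
  numerical integration noise in the upstream charge partitioning;
* `tol_fatal` = 0.05 e — above this, a value is wrong or missing.

Landing on the *wrong* integer is always fatal regardless of the residual.
No published threshold exists for separating negligible integration error
from real error, so these defaults are this package's choice, sized well
above typical per-block integration drift (per-method mean-charge residuals
in real multi-method datasets are ~0.002 e) and well below half a charge
quantum; both are configurable.  Corrections are applied only through an
explicit, auditable corrections file (`set_value` / `drop_molecule`),
never silently.

Physical bounds: an atom with nuclear charge Z and NAC q holds Z − q
electrons, so q > Z is flagged; with an atomic spin moment given,
(Z − q) < |ASM| is flagged as chemically inconsistent.  The comparison
tolerance defaults to 1e−9 (a pure float guard; bounds violations of
interest are of order 0.1 e or more).

## Reversible regression (ILSF)

Standardization uses w = (x − mean)·s/σ with s ∈ {−1, +1}.  For a pair,
the second variable's sign is sign(Λ), so the standardized pair is always
positively correlated and the fitted line in original units has the
covariance's sign.  The optimum of both the total-least-squares loss
L⁽¹⁾ = Σ(Δw² + Δz²) and the orthogonal-distance loss L⁽²⁾ = ΣΔz²/(1 + ζ²)
is (ζ, η) = (1, 0) with L⁽¹⁾ = 4M(1 − Ω) = 4L⁽²⁾; the shipped fit path uses
these closed forms only — brute-force minimization exists solely in the
test suite as an independent oracle.  Degenerate cases: a constant column
raises; |Λ| ≤ 1e−12·σₓσᵧ is treated as exactly zero covariance, collapsing
the model to the point of the means (the line direction is undefined
there).

ILSF is not Deming regression (which normalizes by measurement-error
variances) and not ordinary least squares on standardized variables (whose
slope is Ω, not 1); the test suite carries one counterexample for each.

## Confluence analysis

S_α includes the self term Ω_αα = 1 (a fully uncorrelated method then has
S = 1 and threshold count 1 — self only).  S_φ, σ_φ and Ω(α, φ) follow the
identities in the README; when data are available φ is also computed
per-datapoint and the identity is cross-checked against direct correlation
in the tests.  When any Ω entry is ≤ 0 the group is outside the mutual
positivity premise; S_α is still reported but the result carries
`confluent=False`.

PCA uses a full symmetric eigendecomposition (numpy `eigh`).  Sign
convention: the first component is flipped so its coefficient sum is
positive (all-positive for a confluent group); other components are flipped
so their largest-magnitude coefficient is positive.  Eigenvalue gaps below
1e−9 are flagged degenerate: those components are rotation-free and
per-component quantities are not unique (requesting the MPC summary with a
degenerate top eigenvalue raises).  Ω(φ, MPC) is computed as the identity
S_MPC/S_φ with S_MPC = √λ_MPC·Σ_α v_α; this identity is reconstructed
rather than transcribed, and is validated in the tests against a
brute-force correlation of φ with MPC component scores.

Threshold counts default to strict ">" (the ranking-table convention); the
block-detection graph uses "≥" (the heat-map shading convention).  Both are
exposed.  Block detection is connected components of the thresholded graph
(scipy `csgraph`); the display ordering keeps components contiguous,
largest first, most-connected members first — any seriation with contiguous
components is equally valid.  Ranking ties are broken alphabetically by
method name and annotated.

Display rounding in the CLI follows the field's reporting habits (σ to 4
decimals, relative magnitudes and coefficients to 3, Ω(φ, MPC) to 5); all
internal math is full precision.

## Robustness

Spam variants are modeled as exact duplicates: correlation 1.0 to the
target and to each other, inheriting the target's correlation row.  This
gives the closed forms S_new = S_old + k·Ω(α, target) and count_new =
count + k·[Ω(α, target) > cut].  For k up to `explicit_limit` (default
1000) the enlarged (V+k) × (V+k) matrix is built explicitly and the closed
forms are asserted against its row sums at every call — the closed form is
never trusted blind.  A noisy-variant model (correlation 1 − ε) would
change the counts and is deliberately not assumed.  The ranking-abnormality
flag fires when the S-criterion winner differs from any count-criterion
winner; note this can also fire on an unspammed dataset whose count
criterion has ties at the top, so it is a detector, not a proof of spam.

Swap sensitivity treats one arbitrary method replacement as an adversarial
±1 on every method's threshold count (its own +1 with all rivals −1 for the
best case, and vice versa), with rank = 1 + number of strictly larger
counts.  Per-swap S_α changes are bounded by |ΔS| ≤ 2 and reported
informationally only.

## ESP models

Grids are axis-aligned cubic lattices centered at the geometric center,
clipped to the shell {p : |p − r_a| ≥ inner·R_a for **all** atoms, and
≤ outer·R_a for **at least one** atom}, in deterministic lexicographic
order.  The all-atoms inner exclusion is the standard choice and is an
assumption of this package.  Defaults inner = 1.4, outer = 2.0,
spacing = 0.4 bohr; published shell-error ratios are grid-converged, so
spacing matters little for RRMSE ratios, and the tests use coarser,
brute-force-verified grids.  Grid points are unweighted (uniform grid).

Units: coordinates/radii bohr, charges e, potentials kcal mol⁻¹ e⁻¹
(1 hartree/e = 627.509474), dipoles atomic units.  The model dipole is
Σq_a r_a (+ Σ atomic dipoles); for charge models with nonzero total charge
the origin is fixed at the center of nuclear charge, otherwise the origin
is irrelevant.  RRMSE = 100·RMSE/RMSE_zero; a zero reference potential
(e.g. a single neutral atom) makes RRMSE undefined and raises.

The bent-triatomic inversion solves q_B + 2q_A = Q together with the
on-axis dipole equation; the system's determinant is twice the
center-to-midpoint distance, so linear geometries raise, as do reference
dipoles with off-axis components (symmetry violation).

## Synthetic generator

The generator emulates the statistical *shape* of a large multi-method NAC
survey: defaults are 2000 molecules of 2–28 atoms (uniform; ≈30 000 atoms,
matching the ~2000-molecule / ~29 900-atom scale of the real surveys this
framework targets), net charges −1/0/+1 with probabilities 0.1/0.8/0.1, and
20 methods whose σ spans 0.13–0.63 e (the observed range across real
methods).  The method profile plants one 14-method main factor block
(θ = 0, noise η from 0.10 to 0.42) and two 3-method side blocks at
θ = ±0.7 rad with low noise — yielding one large Ω ≥ 0.9 block plus two
side blocks, all correlations positive (|Δθ| stays below π/2).

Per atom, two latent standard-normal patterns t, u are drawn and centered
within each molecule; method values follow the formula in the module
docstring, and a per-molecule uniform shift pins every method's molecular
sum to the integer net charge (the shift vanishes in expectation for
neutral molecules, so large-N correlations stay at the closed form
Ω_ab = cos(θ_a − θ_b)/√((1+η_a²)(1+η_b²))).  Three named RNG streams
(structure, latents, noise) derive from one seed, so corruption or method
changes do not reshuffle unrelated draws.

Known limits of the emulation — and hence of what passing tests show about
real data: values are Gaussian with a one- or two-factor linear structure
(real NACs have chemistry-driven heavy tails and element-specific
structure); the η = 0 "all correlations exactly 1" limit holds exactly only
for neutral molecules, because the integer-sum shift is method-independent
and breaks exact proportionality between different-σ columns on ions;
elements are assigned cyclically from second/third-row elements and carry
no chemical meaning (heavier elements only, so clean tables pass the
NAC ≤ Z bound); and reference ESP grids are generated from the same point
charges being tested, so ESP tests validate the error machinery, not any
charge method's physical accuracy.

## Problem sizes in tests

The suite generates its fixtures at import/run time: ~3 000- and
~15 000-atom tables shared session-wide, 20 replicates of a ~20 000-atom
10-method table for ranking recovery, 100-pair minimizer cross-checks, and
200-draw optimality scans.  These sizes keep the statistical assertions
(3/√N entrywise correlation recovery, ≥18/20 ranking recovery) sharp while
the full suite runs in seconds.
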