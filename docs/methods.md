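# Methods

## Response model and data generation

Item responses are generated from the graded response model (GRM). A scale
has k items (5 or 10) with J ordered categories (3, 5 or 7). Item *i* has a
discrimination a_i ~ U(1.5, 2) — the range typical of well-functioning
questionnaire items — and J−1 thresholds drawn i.i.d. N(0, 1) and sorted
ascending. Sorting alone guarantees a valid GRM; no minimum threshold
separation is enforced, so occasional items have nearly coincident
thresholds and rarely used middle categories, as happens in real scales.
Responses are sampled with a single uniform draw per (subject, item): because
the cumulative curves P*_j are decreasing in j, the events u < P*_j nest and
1 + #{j : u < P*_j} is a draw from the category distribution.

A fresh item bank is drawn for every replication, so scenario-level power and
Type I error average over the item-parameter distribution rather than
conditioning on one arbitrary bank. `run_scenario(..., fixed_bank=True)`
holds a single bank per scenario for sensitivity analysis; per-bank power in
a high-power cell (10 items, 7 categories, R500/F100, shift 0.5) ranges
roughly 0.89–0.99 across banks at 150 replications, which bounds how much
the bank policy can move a cell's estimate.

Latent traits are N(0, 1) or Beta(α, β) with (α, β) from
{(1,4), (0.5,4), (4,1), (4,0.5)}, standardized with the *analytic* Beta
moments (mean α/(α+β), variance αβ/((α+β)²(α+β+1))) so every replication's
trait distribution has population mean 0 and variance 1 exactly; only
skewness and kurtosis distinguish the conditions. The 13 reference/focal
combinations range from both-normal (condition 13) through same-direction
skew to opposite high skew (conditions 10/12).

Uniform DIF adds a constant Δ ∈ {0.25, 0.5, 1.0} to every threshold of the
studied item (item 1 by default) in the focal group only. The shift is
tracked against the base thresholds so applying −Δ restores the bank
bit-exactly. With group coded reference = 0, focal = 1, a positive Δ lowers
the focal group's expected score, so the true direct path β is negative.

## MIMIC estimation

Scores are treated as numeric 1..J and the model is fitted by normal-theory
maximum likelihood — the estimator choice matching how such models are
routinely fitted to Likert data, and deliberately *not* a categorical
(polychoric/WLSMV) approach. The model for the joint vector (items, group
code x) is

    theta = gamma * x + zeta,          Var(zeta) = psi_zeta
    y_i = tau_i + lambda_i * theta + beta_i * x + eps_i,

with beta_i free only for the studied item (and optionally for items whose
paths are deliberately freed; see below). Writing c = gamma*lambda + beta
(as a k-vector), the implied moments are mu_y = tau + c·E[x] and
Sigma_yy = psi_zeta·lambda lambda' + Var(x)·c c' + diag(psi), Sigma_yx =
Var(x)·c, with x's own mean and variance fixed at their sample values
(fixed-x convention, the default of mainstream SEM software). This form
makes the implied covariance positive definite whenever all variances are
positive, so the search space on log-variances is unconstrained and the
discrepancy

    F_ML = log|Sigma| + tr(S Sigma^-1) − log|S| − p + (m − mu)' Sigma^-1 (m − mu)

is always evaluable.

Identification: the first anchor item's loading is fixed at 1, psi_zeta is
free, and the latent intercept is absorbed into the item intercepts. The
Wald test of beta is invariant to this choice; exact chi-square/df values
would differ under other conventions. Degrees of freedom count the modeled
moments conditional on x — k means, k(k+1)/2 item (co)variances, k item–x
covariances — minus the free parameters (3k+2 for a single direct path),
e.g. df = 8 for k = 5.

Optimization is L-BFGS-B with the exact analytic gradient (verified against
finite differences to ~1e−7 relative error) from a deterministic start
(loadings 1, intercepts = item means, residual variances = half the item
variances, gamma = beta = 0), so repeated fits are bit-identical. Gradient
tolerance 1e−6, iteration cap 500; a fit that terminates on the relative
function-decrease test with projected gradient below 1e−5 is also counted
converged. Heywood cases are flagged when any variance estimate is pinned
within 1e−8 of zero or an implied correlation leaves [−1, 1]; improper or
nonconverged fits are reported via flags, never exceptions.

Standard errors come from the inverse expected (Fisher) information of the
multivariate-normal model at the optimum, scaled by N−1, with a
pseudo-inverse fallback for singular information. Under correctly specified
(linear-normal) generation the reported SE of beta matches the empirical
sampling sd within ~2% at n = 600. On coarse ordinal data (especially
3 categories) normal-theory SEs run somewhat small, which is visible as mild
Type I error inflation at the smallest designs — the same behavior the ML
estimator exhibits in practice on Likert data.

Model chi-square is (N−1)·F_ML. Fit indices use the independence baseline
(free means/variances, zero covariances; closed form F = Σ log S_ii −
log|S|): RMSEA from the noncentrality estimate, CFI/TLI against the
baseline, RMR as the root mean square of unique residual (co)variances, and
GFI = 1 − tr((Σ⁻¹(S−Σ))²)/tr((Σ⁻¹S)²), each clamped to its conventional
range.

## DIF testing and anchor purification

Each item is tested one at a time with the remaining items as anchors; an
item is flagged when the two-sided Wald p-value falls below α = 0.05 and the
fit is proper. No multiple-testing correction is applied. Power is the
flagging rate on the true DIF item; Type I error is the mean flagging rate
over DIF-free items.

When a DIF-free item is tested in a dataset that contains a true DIF item,
the DIF item's own direct path is freed (estimated, not tested) by default,
removing it from the anchor set. Leaving the DIF item as a clean anchor
biases the tests of DIF-free items: empirically it roughly doubles their
false-positive rate at Δ = 0.5 and grows with Δ, whereas with the freed path
the Type I error is essentially flat in Δ (≈0.050 at Δ = 0.5 vs ≈0.052 at
Δ = 1.0 in the R100/F100, 3-category design) — the behavior one expects from
a purified anchor set, and standard practice when a DIF suspect is known.
`evaluate_dataset(..., free_true_dif_path=False)` restores the contaminated
variant for comparison.

## Monte-Carlo design

The full factorial grid is 5 sample-size ratios × 2 DIF magnitudes ×
2 scale lengths × 3 category counts × 13 trait conditions = 780 scenarios
(the Δ = 0.25 axis ships as an optional preset). Per-scenario seeds are
derived from one base seed keyed to the scenario's identity, and replication
r (attempt a, for retries) uses the child stream (scenario seed, (r, a)), so
any single replication is reproducible in isolation, subset reruns match
full runs row-for-row, and serial and parallel execution agree exactly.

A replication whose fits do not all converge properly is redrawn with the
next attempt stream up to 5 times ("change the seed and repeat"); items
whose fits remain improper are excluded from both numerator and denominator
of their rate. In practice convergence is essentially complete: all tested
normal-trait cells converged 500/500.

Replication counts are configurable. The shipped analyses use 500
replications for single cells and 150 per scenario for the 60-scenario
all-normal aggregate, which keeps a full desk run in the minutes range while
holding the binomial standard error of a single cell near 0.01–0.02; the
reference tables this design mirrors used 1000. Aggregate contrasts
(`aggregate_contrast`) are unweighted means over scenario-level estimates,
with pairwise level differences in percentage points; the weighting
convention is documented rather than inferred, since aggregate percentages
depend on it.

## What the generator does and does not emulate

The simulation covers complete ordinal responses from a unidimensional GRM
with a single uniform-DIF item and exactly standardized trait distributions.
It does not emulate missing data, multidimensional traits, nonuniform DIF
(interaction effects), multiple DIF items, local dependence, or real-world
group differences in trait variance — the standardization forces variance 1
in both groups even for the "heterogeneous" skew conditions. Passing tests
therefore certify the estimator's behavior under these idealized
conditions, not robustness to the above complications.

## Known limitations

- Normal-theory ML on 3-category scores yields slightly anticonservative
  Wald tests at small n (Type I error ≈0.05–0.07); this is a property of the
  estimator being studied, not corrected away.
- High-power cells are sensitive to the fresh-bank-per-replication policy at
  the ±0.02 level (see the fixed-bank sensitivity range above); estimates in
  such cells are averages over banks, and can sit slightly below what any
  single well-behaved bank would give.
- The Wald test is the only detection rule implemented; likelihood-ratio or
  score variants, iterative anchor purification, and effect-size
  classification are out of scope.
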