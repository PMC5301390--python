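# Methods

`phylotrace` post-processes MCMC traces from Bayesian phylogenetic
samplers (MrBayes `.p`, BEAST `.log`, JPrIME/PrIMe tab-separated output,
NEXUS tree files). This note documents the statistical procedures, the
numerical conventions, and the choices made where more than one standard
definition exists.

## Trace model and parsing

A trace is an ordered record of sampled parameter values, one row per
retained MCMC iteration. Columns are classified per column: *numeric*
if every value parses as a decimal number (scientific notation and
`NA`/`NaN` tokens allowed — NA samples are dropped inside each
statistic, never at parse time), *tree* if every non-empty value is a
Newick string terminated by `;`, otherwise *ignored*. A column named
`Gen`/`state`/`Sample`/`Iteration` (case-insensitive) is the iteration
counter and must be strictly increasing. Fields are separated by tabs
only; splitting on spaces would be ambiguous because Newick labels may
contain them. Comment handling (leading `#` anywhere, a bracketed
`[ID: ...]` line before the header) is a deliberate superset of the
dialect quirks of the supported samplers; a file a sampler actually
emits parses, and some files no sampler emits parse too. Sample indices
are 0-based and every interval is half-open `[start, end)`.

NEXUS input is restricted to a `trees` block with an optional
`Translate` table (parsed with dendropy); `data`/`characters` blocks are
out of scope.

## Effective sample size

For a series of length *n* with lag-*k* sample autocorrelations ρ̂_k
(biased 1/n autocovariance, computed by FFT),

    ESS = n / (1 + 2 · Σ_{k=1}^{K} ρ̂_k),

where K stops just before the first non-positive ρ̂_k (initial positive
sequence), capped at n/2. The estimate is clamped to (0, n]; a
constant series returns n by convention, and fewer than 10 samples is an
error (10 lags cannot support an autocorrelation estimate). This
truncation is simpler than Geyer's monotone-pair rule but closely tracks
Tracer-style ESS values in practice, and is the documented, swappable
choice here. On simulated AR(1) chains with coefficient ρ the estimator
recovers the closed form ESS/n = (1−ρ)/(1+ρ) within sampling error
(tests check ρ = 0.5, n = 10⁴).

ESS converts to a *computational uncertainty*: the full width of the
95% confidence interval of the posterior-mean estimate, as a percentage
of the posterior standard deviation,

    u(ESS) = 100 · 2 · z₀.₉₇₅ / √ESS,  z₀.₉₇₅ ≡ 1.96.

z is fixed at 1.96 rather than looked up so the headline conversions are
exact after rounding: u(6000) = 5.06 ≈ 5%, u(200) = 27.7 ≈ 28%. The
latter is why an "ESS > 200" convergence rule of thumb is generous: it
tolerates a mean estimate whose CI is about a quarter of a posterior SD
wide.

## Parameter summaries

Computed on the post-burn-in samples: mean, sample SD (n−1), min/max,
and the equal-tail 95% credible interval (empirical 2.5%/97.5% quantiles
with linear interpolation). Equal-tail was chosen over HPD because it
is deterministic, assumption-free and trivially verifiable; HPD is a
non-goal. Below 10 post-burn-in samples the ESS falls back to n.

## Convergence diagnostics

**Geweke.** z = (x̄_A − x̄_B) / √(ŝ²_A/ESS_A + ŝ²_B/ESS_B), with window A
the first 10% and window B the last 50% (the classical defaults), and
each window's variance adjusted by its own ESS (ŝ²/ESS = s²·(n/ESS)/n).
The spectral-density-at-zero variance is thus approximated through the
same ESS estimator rather than a periodogram — one estimator, one set of
conventions. Under a stationary null the empirical type-I error at
|z| > 1.96 is ≈ 0.04–0.06 over 1000 replicates of n = 10⁴ (the ESS
plug-in adds a little noise to the nominal 5%). Both windows constant →
z = 0; fewer than 100 samples is an error.

**Gelman-Rubin.** PSRF = √(((n−1)/n · W + B/n) / W), W the mean
within-chain variance, B/n the ddof-1 variance of chain means.
Identical chains give the analytic floor √((n−1)/n). W = 0 with equal
means returns 1; W = 0 with differing means returns +∞ as an explicit
divergence signal. Applied to a single chain, the post-burn-in series
is split into halves as two pseudo-chains — a documented convention, not
a claim that half-splitting is as informative as independent chains.

**Burn-in estimation.** Candidate burn-ins lie on the grid
{0, 1%, 2%, …, 50%}·n. The ESS-based estimator returns the smallest
candidate maximising ESS of the retained tail (ties toward smaller); the
Geweke-based estimator returns the smallest candidate whose tail passes
|z| < 1.96, or the grid maximum flagged non-converged if none does. The
suggested burn-in is the maximum of the two (conservative). On a chain
whose first 20% is mean-shifted by 10 SD, the ESS search lands on 20%
almost exactly; the Geweke search alone can accept slightly earlier
(≈16%) because a contaminated early window carries a large,
low-ESS-adjusted variance that deflates z — one reason the combined
maximum, not either component, is the suggestion.

**Verdict.** converged ⇔ |z| < 1.96 at the suggested burn-in, PSRF < 1.1
on the half-split, and ESS ≥ `ess_min` (default 200, configurable — see
the uncertainty arithmetic above for why 200 is a weak floor). The
report carries every component so stricter rules can be applied
downstream.

## Topology identity, posterior, consensus

A topology's identity is its set of non-trivial leaf bipartitions
(splits), each canonicalised as the side excluding the lexicographically
smallest leaf label. Identity is therefore **unrooted** and ignores
branch lengths; a degree-2 root vanishes automatically. This matches
the unweighted Robinson-Foulds metric used downstream; genuinely rooted
analyses (clade supports) would need a rooted mode, which is a known
limitation. Posterior tables sort by probability descending, ties by
first occurrence, and the exemplar Newick of each topology is its first
post-burn-in occurrence with branch lengths stripped.

The weighted majority-rule consensus retains splits with weighted
frequency strictly greater than 0.5 (weights renormalised over the
selection). Strict majority guarantees pairwise compatibility, so the
tree assembles by nesting the retained splits — viewed as clades of the
tree rooted at the smallest leaf — without any greedy tie-break; splits
at exactly 0.5 are dropped and surface as polytomies. Supports are the
weighted frequencies, computed only from the selected trees.

## Tree space

Unweighted RF distance = |S(T₁) Δ S(T₂)|, verified against dendropy's
bipartition machinery as an independent oracle. The pairwise matrix is
restricted to topologies with posterior probability ≥ 0.2% (default);
more than 45 qualifying topologies emits a `TreeSpaceSizeWarning` — the
computation still runs, the warning only flags the quadratic cost.
Embedding is classical (Torgerson) MDS: B = −½·J·D²·J, top-2 eigenpairs,
negative eigenvalues clamped to 0. Classical MDS was chosen over
non-metric variants as the reproducible, closed-form baseline; it is
exact for 2-D-Euclidean-embeddable inputs (tested to 1e-6) and otherwise
a least-squares projection. Eigenvector sign is fixed by making each
axis's first nonzero coordinate positive, so outputs are deterministic;
embeddings are still only meaningful up to rotation/reflection.

## Two-chain comparison

Numeric parameters: two-sided Mann-Whitney U with midranks and tie
correction; the reported statistic is min(U_x, U_y). Samples with
n₁·n₂ < 20 and no ties use the exact permutation distribution, otherwise
the normal approximation with continuity correction (scipy's
implementation behind this module's interface). No multiple-testing
correction is applied by default — results are reported per parameter.

Tree samples: per-split presence counts in each chain are compared with
a chi-square homogeneity test against pooled expected proportions;
splits whose smaller expected count is below 5 are pooled into an
"other" category, df = categories − 1. Splits within one tree are
correlated, so the statistic does not follow its nominal chi-square
distribution exactly; simulation under the null shows the test is
mildly conservative (empirical size ≈ 0.02–0.04 at α = 0.05), which is
the safe direction for a convergence alarm. The calibration is asserted
in the test suite.

Chain concatenation drops the iteration column (a joined counter would
not be increasing) and requires identical column names and kinds.

## Synthetic traces

Numeric columns are stationary AR(1) processes,
x_t = μ + ρ(x_{t−1} − μ) + σε_t with x₀ drawn from the stationary
distribution, optionally with a mean-shifted prefix emulating an
unconverged start: AR(1) is the simplest process with the tunable
autocorrelation that drives ESS and burn-in behaviour. Tree columns are
iid draws from a fixed topology distribution. These emulate the
*marginal* structure real traces have, not their joint behaviour: real
tree chains are serially correlated and correlated with the numeric
parameters, and real numeric posteriors are rarely Gaussian. Passing
tests therefore demonstrate estimator correctness and calibration under
controlled conditions, not performance guarantees on any particular real
dataset. All generators are pure functions of their spec including the
seed; there is no global random state.

Default simulation sizes in tests and the acceptance script (n = 10⁴ for
single-series calibrations, 500–1000 replicates for type-I-error
estimates, 300-tree chains for split tests) were chosen so Monte-Carlo
error is comfortably inside each asserted band.

## CLI and report format

JSON reports have sorted keys and floats fixed at 6 significant digits,
so identical inputs and flags yield byte-identical output. Burn-in
arguments: `auto` (per-parameter verdicts, overall burn-in = max over
parameters), a fraction when < 1, an absolute count when ≥ 1. `analyze`
exits 3 when any parameter fails the convergence verdict so pipeline
scripts can branch on it. The report structure is versioned
(`schema_version`) and validated structurally in the test suite against
`report_schema.json`.

## Known limitations

- No HPD intervals, batch-means variance estimators, FWSR stopping
  rules, or ESS for tree-valued parameters.
- Single-chain PSRF via half-split is a convention, not a substitute for
  truly independent chains.
- The split chi-square is approximate (correlated splits) and the
  Mann-Whitney is per-parameter (a Bonferroni-style correction is left
  to the caller).
- Tree identity is unrooted only; at most two chains are compared; the
  NEXUS reader covers tree traces, not full NEXUS.
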