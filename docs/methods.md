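# Methods

## Model and procedures

All procedures operate on a family of m marginal p-values whose null
members are assumed *super-uniform*: P(p ≤ t) ≤ t for all t ∈ [0,1] under
the null. Nothing is assumed about the joint distribution; every
guarantee below holds under arbitrary dependence unless stated otherwise.

**Classical rules.** Bonferroni (p ≤ α/m), weighted Bonferroni
(p_i ≤ α·w_i, w ≥ 0, Σw = 1) and Šidák (p ≤ 1 − (1−α)^{1/m}) are
implemented as single-step per-hypothesis comparisons — the union-bound
logic that proves their FWER control — rather than through the step-up
engine; for constant thresholds the counts coincide. Holm is the
step-down rule with Δ(r) = α/(m−r+1); Benjamini–Hochberg (BH) and
Benjamini–Yekutieli (BY) are step-up rules with Δ(r) = αr/m and
Δ(r) = αr/(m·H_m) respectively, H_m = Σ_{j≤m} 1/j computed by direct
summation in double precision (exact at any practical m; no asymptotic
approximation). Šidák's FWER control is exact only under independence and
conservative under positive dependence; BH controls FDR under
independence/PRDS and only empirically under other dependence. π₀ is
fixed at 1 throughout: adaptive π₀ estimators are excluded because they
are unreliable under arbitrary dependence, and a fixed π₀ keeps every
rule's guarantee distribution-free.

**Step-up/step-down engines.** Step-up: R = max{r ∈ {0,…,m} :
p_(r) ≤ Δ(r)} with p_(0) ≡ 0, computed by one vectorised scan; a
brute-force maximisation serves as the oracle in tests. Step-down: reject
sequentially until the first rank with p_(r) > Δ(r). The rejection set is
always the R smallest p-values under a *stable* ascending sort, so ties
are broken by original index. Caveat: the rule is rank-based, so boundary
p-values tied across ranks R and R+1 can split — one rejected, one not —
and, in the DP analysis, tied p-values can receive different significance
probabilities.

**Measures and shape functions.** A probability measure ν on the bins
(r−1, r] induces the shape function β_ν(r) = Σ_{j≤r} j·ν_j and thresholds
Δ(r) = α·β_ν(r)/m (clipped to [0,1]); any such step-up rule controls
FDR ≤ π₀α under arbitrary dependence. The BY baseline ν₀ with masses
1/(r·H_m) makes β linear, β(r) = r/H_m, recovering BY exactly (asserted
to 1e-12 in tests).

**DP sensitivity analysis.** ν ~ DP(M·ν₀) restricted to the integer-bin
partition is exactly Dirichlet_m(M·ν₀(B₁), …, M·ν₀(B_m)); E[ν] = ν₀ and
V[ν(B)] = ν₀(B)(1−ν₀(B))/(M+1), so small M means large spread around the
BY rule. Each Monte-Carlo draw samples M (fixed value, or one
Exponential(1) variate per draw under the default hyperprior — the joint
prior-predictive scheme), then ν, then records the step-up count R. The
significance probability of the rank-r hypothesis is the fraction of
draws with r ≤ R; the events {r ≤ R} are nested, so it is non-increasing
in rank, and it is identically zero for p-values above α because every
realised threshold satisfies Δ(r) ≤ α·β(m)/m ≤ α.

Dirichlet draws use the gamma representation: independent Gamma(M·ν₀_r)
components normalised by their sum. With small M the concentrations fall
far below 1 and individual components underflow to exact zero — harmless
while the sum is positive; a draw whose whole vector underflows is
retried up to 100 times before raising an error that advises a larger M.

**Precision-parameter elicitation and posterior.** The expected number of
distinct values among m DP draws is Σ_{i=1}^m M/(M+i−1), bracketed by
[max{1, M log((M+m)/M)}, 1 + M log((M+m+1)/M)]; M = 1/m expects about one
cluster, M = m² about m. Given an observed distinct-value count k (exact
floating comparison of the p-values; k = m for continuous statistics) and
a Gamma(a,b) prior (Exponential(1) is a = b = 1), the posterior is
π(M|k) ∝ π(M)·M^{k−1}·(M+m)·B(M+1, m), the Beta function being the closed
form of ∫₀¹ z^M (1−z)^{m−1} dz and evaluated via log-gamma differences.
Two independent routes are provided: the Escobar–West auxiliary-variable
Gibbs sampler — η|M ~ Beta(M+1, m); M|η a two-component mixture
Gamma(a+k, b−log η) / Gamma(a+k−1, b−log η) with odds
(a+k−1)/(m(b−log η)) — and trapezoid quadrature of the density on an
adaptive grid (mode located on a log-spaced scan, window ±12 posterior
sd from local curvature). The two agree within Monte-Carlo error in
tests, which arbitrates the density's printed form. The chain starts at
the prior mean a/b, mixes within a few sweeps (lag-1 autocorrelation
≈ 0.3 at k = m ≈ 29k), and defaults to 10,000 burn-in + 10,000 retained
draws. η is clamped to the open unit interval by one representable step
so that b − log η stays finite and > b.

## Synthetic data generator

`simulate_pvalues` draws latent normals X_i = √ρ·Z₀ + √(1−ρ)·Z_i (one
shared factor, pairwise correlation exactly ρ ∈ [0,1)); each hypothesis
is independently a true null with probability π₀. Null p-values are the
upper-tail probability 1 − Φ(X_i), exactly Uniform[0,1] marginally (the
super-uniformity condition holds with equality); alternatives shift the
latent by +effect, giving stochastically smaller p-values. Defaults
m = 100, π₀ = 0.8, effect = 3, ρ ∈ {0, 0.5} in the calibration studies —
a moderately sparse signal regime with clearly separated but not trivial
alternatives. What it does *not* emulate: negative or heterogeneous
dependence, heavy-tailed or discrete test statistics, composite-null
conservatism (strictly super-uniform nulls), or any specific alternative
family — no alternative distribution is prescribed by the theory, so the
Gaussian shift is this package's choice. Passing calibration tests
therefore show that the implemented rules keep FDR/FWER ≤ α under
exchangeable positive dependence with uniform nulls; they do not certify
behaviour under other dependence structures (which the *theoretical*
guarantees nevertheless cover for Bonferroni/Holm/weighted
Bonferroni/BY and the DP ensemble).

## Numerical and design choices

- Seeding: every stochastic routine takes an integer seed or a numpy
  Generator; Monte-Carlo replicate studies spawn per-replicate child
  seeds from one `SeedSequence` so different procedures see identical
  families.
- Monte-Carlo error: control assertions use a 3-standard-error margin;
  chain standard errors come from batch means (50 batches), which absorbs
  autocorrelation; a quantile's standard error is taken as 1.2533× the
  mean's (normal-target asymptotics).
- Problem sizes in tests: calibration studies use m = 100 with 2,000
  replicates, Gibbs-vs-quadrature checks use chains of 8,000-10,000
  draws; the full k = m = 28,679 posterior run takes well under a second.
- Degenerate inputs: m = 1 reduces every rule to p ≤ (adjusted) α; all-p
  = 0 and all-p = 1 families short-circuit to R = m and R = 0; a
  single-bin measure is the point mass.
- Weighted-Bonferroni sensitivity uses flat Dirichlet(1,…,1) weights and
  reports mean/sd with denominator n−1.

## Known limitations

- The rank-based tie caveat above.
- Negative equicorrelation is not representable by the one-factor
  generator.
- The DP analysis is prior-predictive by design; the posterior of M is
  provided for completeness but concentrates (large k) on inference
  equivalent to plain BY, and is deliberately not wired into the
  sensitivity analysis defaults.
- Continuous hypothesis spaces, weighted FDR over general measures, DP
  mixtures for continuous ν, and online testing are out of scope.
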