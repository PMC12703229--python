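# dpmtp

Sensitivity analysis of multiple testing procedures (MTPs) under arbitrary
dependence between p-values, via a Dirichlet-process prior over the space
of distribution-free FDR-controlling step-up rules.

## The problem

Given m marginal p-values p₁, …, p_m from dependent hypothesis tests, the
classical procedures — Bonferroni, weighted Bonferroni, Šidák, Holm
(family-wise error rate control) and Benjamini–Yekutieli (false discovery
rate control under arbitrary dependence) — each pick a single threshold
rule and declare the R smallest p-values significant. Different valid
rules can disagree by thousands of discoveries on large families, and
committing to any one of them ignores that selection uncertainty.

The key fact (Blanchard–Roquain): for *any* probability measure ν on the
integer bins (r−1, r], r = 1…m, the step-up procedure with shape function

    β_ν(r) = Σ_{j≤r} j·ν_j,    thresholds Δ_α(H_(r)) = α·β_ν(r)/m,

controls FDR ≤ π₀α under arbitrary dependence. The Benjamini–Yekutieli
(BY) rule is the special case ν_r = 1/(r·H_m), with H_m the m-th harmonic
number. Placing a Dirichlet-process prior ν ~ DP(M·ν₀) — baseline ν₀ the
BY measure, precision M fixed or given a standard Exponential(1)
hyperprior — therefore defines a prior over this whole space of valid
procedures. Monte-Carlo draws of ν propagate to a prior-predictive
distribution of the discovery count R_α and, per hypothesis, a
*significance probability*: the fraction of draws in which its rank falls
at or below R_α. The spread of R_α across draws is the sensitivity of the
"how many discoveries?" decision to the choice of procedure.

The package also provides the Escobar–West Gibbs sampler for the
posterior of the precision M given the number k of distinct values among
m DP draws, π(M|k) ∝ π(M)·M^(k−1)·(M+m)·B(M+1, m), with an independent
quadrature oracle; the expected-cluster-count formula Σᵢ M/(M+i−1) for
eliciting M; and a simulator of equicorrelated p-value families with
known ground truth for FDR/FWER calibration studies.

## Worked example

```python
import dpmtp

family, truth = dpmtp.simulate_pvalues(m=200, pi0=0.8, effect=3.0,
                                       rho=0.5, seed=1)
for proc in (dpmtp.bonferroni, dpmtp.holm, dpmtp.by, dpmtp.bh):
    print(proc.__name__, proc(family, 0.05).R)

res = dpmtp.dp_mtp_run(family, dpmtp.DPSpec(n_draws=1000, seed=2))
print(f"DP-MTP: mean R = {res.mean_R:.1f}, sd = {res.sd_R:.1f}")
print("top-ranked significance prob:",
      round(res.sig_prob[family.order[0]], 3))
```

prints

```
bonferroni 27
holm 29
by 36
bh 41
DP-MTP: mean R = 31.2, sd = 10.6
top-ranked significance prob: 0.946
```

The four classical rules disagree (27-41 discoveries; this draw has 40
true alternatives); the DP sensitivity analysis spreads over that range
(mean 31.2, sd 10.6 discoveries), and the smallest p-value is declared
significant in 94.6% of the sampled procedures.

The same pipelines are available from the shell:

```sh
dpmtp generate --m 200 --pi0 0.8 --effect 3 --rho 0.5 --seed 1 --out p.csv
dpmtp classic --pvalues p.csv --out classic.tsv
dpmtp dpmtp --pvalues p.csv --draws 1000 --seed 2 --out-prefix dp
dpmtp mcmc-m --k 200 --m 200 --out mpost
dpmtp simulate --m 100 --reps 1000 --out sim.tsv
```

Each run writes TSV/JSON outputs plus a `*.params.json` echo sufficient
to reproduce it.

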