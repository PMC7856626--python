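# Methods

This note records the models implemented by `pqxinar`, the numerical and
design choices that were genuinely open, what the synthetic data emulate, and
the limitations a user should know about.

## The PQX distribution

PQX(α, θ) is the Poisson mixture whose rate follows a quasi-xgamma density —
an exponential(θ)/gamma(3, θ) mixture with weight α/(α+1) on the exponential
component. Both parameters are dimensionless and positive; α controls the
mixture balance (α = 0 is the NB(3, θ/(θ+1)) boundary, α → ∞ the geometric
limit) and θ is the rate of the latent-mean density, so the mean
(α+3)/(θ(α+1)) falls as θ grows. The dispersion index exceeds 1 on the whole
parameter space, which is the point of the family: it cannot represent equi-
or under-dispersed data even approximately, and the estimators fail loudly
(see below) when presented with such data.

All probability quantities are closed-form. The survival function deserves a
remark: the textbook complement 1 − F(x) loses all precision below ~1e-12 in
double arithmetic, but the complement of the closed-form cdf simplifies
algebraically to

    P(X > x) = [2α(θ+1)² + θ(x+3)(θ(x+2)+2) + 2] / [2(α+1)(θ+1)^(x+3)],

which has no subtraction and is evaluated in log space. Tail probabilities
are therefore exact to machine precision at any depth; the test suite
cross-checks them against log-space summation of the pmf. The published
tail-comparison table was itself computed as 1 − cdf in double precision, so
its cells below ~1e-15 sit at the double-precision floor (2.22e-16 and
multiples); the acceptance test accordingly compares each cell to its printed
precision with one additional double-ulp of absolute slack.

Shape classification follows the successive-probability-ratio analysis: the
ratio P(x+1)/P(x) crosses 1 at the roots x₀* ≤ x₀** of a quadratic, which
partitions the (α, θ) plane into unimodal-at-zero, mode-at-one, interior-mode
and bimodal regions. One refinement was necessary: in part of the nominal
bimodal strip no integer lies in (x₀*, x₀**), the pmf is then strictly
decreasing, and the "interior mode" ⌈x₀**⌉ is not a local maximum (e.g.
α = 0.34, θ = 0.5). `classify_modality` verifies the candidate against the
exact pmf and demotes such points to unimodal-at-zero, so its output always
agrees with a brute-force scan. Exact ties (x₀** integral, or α exactly on
the mode-at-one boundary) put equal mass on two adjacent points; both are
reported as modes.

Random variates use the exact mixture route (draw the component, the latent
rate, then the Poisson count); no pmf table or inversion is needed and the
draws are exact.

## Estimation for iid samples

*Maximum likelihood* maximizes the exact log-likelihood on the log-parameter
scale (L-BFGS-B with the analytic score; box |log param| ≤ 20). Standard
errors come from the inverse observed information, computed by numerical
differentiation (statsmodels) on the natural scale at the optimum; Wald
intervals default to the 95% level. Two boundary behaviours are handled
explicitly: all-equal samples are flagged degenerate, and fits that reach the
upper log-α bound are flagged non-converged, because beyond moderate α the
profile likelihood is flat toward the geometric limit and α is effectively
unidentified. This flatness is a real feature of the family at small n: a
noticeable fraction of n = 50 samples produce arbitrarily large α̂ with
likelihood differences below 0.01.

*Method of moments* is closed-form in the first two raw sample moments
(divisor n). The inversion raises a "moments incompatible" error whenever the
discriminant is negative or α̂ < 0 — which is exactly the under-dispersed-
sample case — rather than silently clipping. Two structural facts are worth
recording: (i) the moment map is not globally injective — the curve
c(α) = (α²+8α+3)/(α+3)² peaks at α = 9, so for c ∈ (1, 13/12) two parameter
pairs share the same first two moments and the closed form returns the
smaller-α root; (ii) for fixed α the moment estimator of θ is positively
biased (Jensen) but consistent and asymptotically normal with variance
v²(θ) = θ²[α(8+α) + (α+1)(α+3)θ + 3]/(α+3)², both verified by simulation in
the test suite.

*EM.* The natural complete data are (x, λ, z) with z the quasi-xgamma
component indicator; the complete-data log-likelihood is linear in (z, λ), so
the E-step needs only the closed-form posterior expectations
w = P(z=1|x) and u = E[λ|x], and the M-step is exact:
α ← w̄/(1−w̄), θ ← (3−2w̄)/ū. As a genuine EM the iteration never decreases
the observed-data log-likelihood — this is asserted at every step — and its
fixed points solve the score equations, so it agrees with the MLE (observed
agreement ~1e-5 at n = 5000). Defaults: tolerance 1e-8 on the maximum
relative parameter change, at most 5000 iterations. A fixed-point recursion
based on the companion expectations t = E[λ²/(2α+θ²λ²)|x] and
s = E[1/(2α+θ²λ²)|x] shares the same fixed points but is not an EM (the
log(2α+θ²λ²) term is nonlinear in λ) and can decrease the likelihood from
distant starting values, which is why it is not used for fitting; t, s, u
remain exposed and are tested against numerical quadrature of the posterior.

Starting values everywhere: the method-of-moments estimate when admissible,
else (α = 1, θ = 1/m₁).

## The INAR(1) layer

The process X_t = p ∘ X_{t−1} + ε_t uses binomial thinning and an iid
innovation law. Innovation families are pluggable through a small contract
(vectorized log-pmf, exact moments, sampler, parameter transforms); provided
families are Poisson(λ), Poisson–Lindley(θ) (pmf θ²(k+θ+2)/(θ+1)^{k+3}),
geometric(θ) with θ the success probability and support from 0, NB(n, π),
and PQX. New families plug in without touching the INAR machinery.

One-step transition probabilities are the binomial-thinning/innovation
convolution with summation index starting at i = 0 (a lower limit of 1, as
sometimes typeset, would leave transition rows unnormalized); the
conditional likelihood evaluates them by log-sum-exp for safety at large
counts. Stationary moments use the generic forms μ_ε/(1−p),
(pμ_ε+σ²_ε)/(1−p²), (DI_ε+p)/(1+p); for PQX innovations the closed forms are
implemented independently and checked to agree to 1e-10.

Simulation starts from an innovation draw and discards a burn-in of 500
steps; mixing is geometric at rate p, so this is ample for p ≤ 0.95.

## Fitting the process

*Conditional maximum likelihood* maximizes the sum of log transition
probabilities over t = 2..T on transformed parameters (logit for p and
probability-type parameters, log for positive ones) by Nelder–Mead,
warm-started from Yule–Walker when admissible. Standard errors are
observed-information as above. AIC = 2k + 2(−ℓ) and BIC = k log T + 2(−ℓ)
use the **full** series length T even though the likelihood conditions on
X₁ — this convention is required to reproduce the published information
criteria from their printed −ℓ.

*Yule–Walker* matches the lag-1 sample autocorrelation (p̂, clipped to [0,1)
with a warning when negative), the sample mean and the sample dispersion
index (divisor T throughout) to their stationary counterparts. Eliminating θ
leaves a quadratic in α whose smaller root is taken (the same root as the
closed-form moment inversion); a negative discriminant or non-positive root
raises a "YW moments incompatible" error — under-dispersed series always
fail here. By construction a successful fit reproduces the sample mean and
dispersion index exactly.

*Diagnostics.* Pearson residuals standardize one-step prediction errors by
the conditional standard deviation p(1−p)x + σ²_ε; under a correct model
they have mean ≈ 0, variance ≈ 1 and no autocorrelation, and the variance
moves away from 1 in the direction of the dispersion misspecification. The
over-dispersion test uses the asymptotic null distribution of the empirical
dispersion index under a Poisson INAR(1):
√T(DÎ − 1) → N(0, 2(1+p²)/(1−p²)) with plug-in p̂; the variance form was
confirmed by Monte Carlo against the simulated null, and the test's type-I
error and power are part of the acceptance suite. One-step forecasts are the
conditional means p̂x_{t−1} + μ̂_ε, with the stationary mean for the first
point; predictions are real-valued by design (no integer coercion).

## Simulation studies and synthetic data

The replication harness runs the two study designs — iid PQX at
(α=0.5, θ=1.5) over a grid of sample sizes, and INARPQX(1) at
(p=0.3, α=0.5, θ ∈ {0.5, 2}) at n ∈ {100, 300, 500} — and aggregates bias,
MSE and MRE per parameter. Each replication draws its generator from
(master seed, size index, replication index), so enlarging the replication
count extends earlier replications instead of reshuffling them. Replications
whose fit fails (moments incompatible, boundary-flagged, non-converged) are
excluded and the exclusion rate is reported; at n = 50 the method of moments
excludes roughly a quarter of samples, which makes its raw θ-MSE look better
than the MLE's through selection alone — on common replications the MLE
dominates at every n. Default scale is 200 replications (the CLI `--reps`
flag raises it); the acceptance script uses 1000 replications at n = 500,
which reproduces the published CML accuracy within Monte-Carlo error in
about two minutes.

The "earthquake-like" fixture simulates INARPQX(1) at the published monthly
earthquake estimates (p = 0.461, α = 94.964, θ = 0.238): stationary,
over-dispersed, long-run mean ≈ 7.95, DI ≈ 3.99. It emulates the marginal
and serial moment structure of the real catalog counts, not their seasonal
or non-stationary features (the real series may have neither, but no such
structure is generated); passing tests on it demonstrate correct model
mechanics, not geophysical validity. The real AFAD catalog is not
redistributed, and month-aggregation of raw event lists is out of scope —
the package consumes already-aggregated counts.

## Known limitations

- PQX cannot represent equi- or under-dispersion; estimators raise rather
  than extrapolate.
- α is weakly identified at small samples (flat likelihood toward the
  geometric limit) and the first-two-moment map is two-to-one in a narrow
  band around α ≈ 9; report intervals, not just point estimates.
- Only first-order autoregression, deterministic thinning probability and
  one-step-ahead point forecasts; no higher-order INAR(p), random
  coefficients, covariates or coherent integer forecasting.
- The over-dispersion test and the Wald intervals are asymptotic; the test
  requires T ≥ 30 and is calibrated in simulation at T = 500.
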