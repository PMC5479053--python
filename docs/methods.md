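# Methods

`repfid` quantifies when a fluorescent reporter faithfully represents the
expression of its target gene in single cells, and when it systematically
perturbs the very dynamics it is meant to observe.  The package has three
scientific layers — a stochastic model of allele coupling, a deterministic
positive-feedback model with bifurcation analysis, and a flow-cytometry
statistics pipeline — plus a synthetic-data layer that emulates the study
conditions with known ground truth.

## Allele coupling under shared regulation

Two alleles of the same gene are modeled as linear birth–death processes for
their mRNA counts (m₁, m₂), with per-allele production rates k_b⁽ⁱ⁾ and decay
rates k_d⁽ⁱ⁾, λᵢ = k_b⁽ⁱ⁾/k_d⁽ⁱ⁾.  Uncoupled, the stationary joint law is a
product of Poissons.  When both birth rates are modulated by a shared
upstream regulator with stationary density ρ(x), the joint law is the Poisson
mixture ∫ Pois(m₁; λ₁x) Pois(m₂; λ₂x) ρ(x) dx.  For x ~ Gamma(r, θ)
(shape–scale, Var = rθ²) this is the bivariate negative binomial

    p(m₁,m₂) = Γ(m₁+m₂+r)/(m₁! m₂! Γ(r)) (1−p−q)^r p^{m₁} q^{m₂},
    p = λ₁θ/[1+θ(λ₁+λ₂)],  q = (λ₂/λ₁)·p,

computed in log space via log-gamma.  Key distribution-free results:

* Cov(m₁,m₂) = λ₁λ₂·Var(x) for any regulator law (constant → 0);
* Var(mᵢ) = λᵢE[x] + λᵢ²Var(x), so for identical alleles the correlation is
  λF/(1+λF), monotone in the regulator Fano factor F = Var(x)/E[x];
* with two-state (telegraph) bursting at slow switching, Cov(m₁,m₂) =
  (wλ₊+(1−w)λ₋)²·Var(x) ≤ λ₊²·Var(x): extrinsic noise couples the alleles,
  intrinsic bursting always decorrelates them.

The exact sampler compounds (draw x, then conditional Poissons).  The
Gillespie simulation runs two 2-state promoters with birth propensity
k_d·λ_state·x and per-molecule death k_d, batched across replicates; the
regulator is drawn once per replicate (quenched extrinsic noise, matching the
stationary-mixture derivation; a per-episode refresh would mix the two noise
timescales and has no closed-form target to validate against).  Promoter
states are initialized from their stationary Bernoulli(w) law, counts from
zero, and the first 10% of each episode is excluded from occupancy averages.
The slow-switching covariance comparison uses switching rates 100× below the
decay rate; this separation is a package choice — the approximation's
validity threshold is qualitative.

## Positive feedback and reporter-induced bifurcation

Total protein n from two alleles with basal production c_b, shared Hill
feedback up to c_f (half-max K, coefficient H ≥ 1), and decay c_d reduces,
via n = (2c_f/c_d)·n̄ and t = τ/c_d, to

    dn̄/dτ = α + n̄^H/(γ^H + n̄^H) − n̄,   α = c_b/c_f,  γ = c_d·K/(2c_f).

Reporter designs rescale γ by a factor in [1, 2]: knock-in 2 (one allele's
production lost), pre/post insertion 2/(1+ε_m) (reporter-allele transcription
scaled by ε_m, nonincreasing with insert count m), fusion 2/(1+εδ) (fusion
additionally degrades feedback efficacy by δ), BAC 1.  The ε_m schedule is
user input; no canonical form exists.

Equilibria are roots of f(n̄) = α + n̄^H/(γ^H+n̄^H) − n̄ in [0, α+1]
(f(0) = α ≥ 0 and f < 0 beyond α+1), found by sign-change bracketing at step
10⁻³ and Brent polishing to 10⁻¹²; a root is stable iff f′ < −10⁻⁹, and
|f′| ≤ 10⁻⁹ flags a degenerate fold.  Bistable ⇔ exactly two stable roots.

The saddle-node locus {f = f′ = 0} is computed parametrically in the
equilibrium level: eliminating u = γ^H from f′ = 0 gives
u² + u(2n̄^H − Hn̄^{H−1}) + n̄^{2H} = 0, whose larger root yields
γ = u^{1/H} and α = n̄ − n̄^H/(u+n̄^H) for n̄ ∈ (0, H/4].  The locus is
traced parametrically rather than from any printed closed form because the
parametric form is unambiguous for all H > 1; for H = 2 it matches the
closed-form fold curves γ±² = −(α² − 5α/2 − 1/8) ± (1/4 − 2α)^{3/2} and has
its cusp (f″ = 0) at (α, γ) = (1/8, 3√3/8), which the implementation locates
by maximizing α along the locus (bounded scalar optimization, xatol 10⁻¹²).
For H ≤ 1 no bistability is possible and an empty locus is returned.

Risk maps compare the classification at (α, γ) with that at
(α, factor·γ) per grid cell.  Dual-allele variants of the pre/post and
fusion designs are not modeled: only the qualitative ordering (knock-in
riskiest, BAC safest, risk growing with insert count) is asserted, via the
single-allele factors.

ODE trajectories use LSODA at rtol 10⁻⁸, integrating in chunks until the
right-hand-side norm falls below 10⁻¹⁰.  The reporter protein is slaved to
the same Hill drive with its own decay rate ρ; at steady state
r* = (c_d/ρ)·n* when production matches, so matched half-lives give r* = n*.

## Flow-cytometry statistics

* **MESF calibration** — least-squares fit of log₁₀(MESF) on
  log₁₀(intensity) over the bead levels; channels map through the fitted
  line.  Beads must be ≥ 2 strictly increasing levels.
* **Alignment** — per day and channel, log-scale values are shifted so the
  1st percentile matches the reference day's.  A shift (not a scale) is used
  because it preserves distribution shape, which is the point of inter-day
  comparability; the operation is idempotent.
* **Mixture fits** — 1- and 2-component Gaussian mixtures on natural-log
  fluorescence (the fitting scale is a package choice, made for consistency
  with the MI preprocessing and standard cytometry practice), via
  expectation–maximization (scikit-learn backend): ten random restarts plus
  one quantile-initialized start screened at loose tolerance, the best
  candidate polished until the total log-likelihood gain is below 10⁻⁸;
  variances floored at 10⁻⁶× the data variance.  BIC = −2ℓ + p·ln n with
  p = 3k−1; lower BIC wins, ties prefer one component.
* **Bimodality criteria** — a 2-component fit is robustly bimodal iff both
  weights exceed 0.1 and each component's weighted peak density exceeds the
  other component's weighted density at that peak (evaluated at the
  component means — the only canonical location for "the same point").
  With equal weights and equal variances the peak-dominance condition is
  always satisfied; it bites exactly when one component is buried under the
  other's flank.
* **Bayesian blocks** — optimal piecewise-constant segmentation with the
  event fitness N·ln(N/T) and prior penalty 4 − ln(73.53·p₀·N^−0.478) at
  false-alarm rate p₀ = 0.05 (measured false-alarm rate ≈ 6% on uniform
  data, n = 1000, 200 seeds).  Tied values are aggregated as weighted
  events; cell boundaries are Voronoi midpoints.  A consequence worth
  knowing: for tightly clustered data the outermost point of a cluster owns
  a cell spanning the inter-cluster gap, so the optimum brackets the gap
  with a near-empty block rather than cutting it in the middle.
* **Shrinkage MI** — each variable is discretized separately per day by
  Bayesian blocks; the joint table is shrunk toward the uniform distribution
  over occupied cells with the closed-form James–Stein intensity
  λ* = (1 − Σθ̂²)/[(n−1)·Σ(t−θ̂)²] clipped to [0,1]; MI (nats) is computed
  from the shrunken joint.  The occupied-cell target keeps the estimator's
  support honest; margins are per-day, never pooled across days.

Nonpositive intensities are excluded before any log transform, with the
excluded fraction reported — background-subtracted cytometry data routinely
contain such events and no principled imputation exists at this level.

## Synthetic data: what it emulates and what it does not

`generate_population` integrates the dimensionless feedback equation (and the
slaved reporter) by Euler–Maruyama with additive noise σ·dW, reflection at 0,
step 0.01 and burn-in 20 decay times, then maps endpoints to intensities via
floor + gain·concentration·exp(N(0, s)).  Defaults: σ = 0.01 (dimensionless
concentration per √dimensionless time), s = 0.25 (natural-log units),
floor = 10, gain = 1000 intensity units per concentration unit.  σ is
deliberately specified on the rescaled concentration scale, identically
across reporter designs, so wild-type and knock-in variants of one circuit
have comparable basin-escape behaviour.  Its default keeps the low
expression state about three stationary standard deviations clear of the
reflecting boundary: larger σ piles the low state onto the autofluorescence
floor and manufactures a spurious shoulder component that has nothing to do
with bistability.  Half the cells start near the high state and half near
zero (configurable), emulating a heterogeneous starting culture; under
bistability the population partitions into basins, under monostability it
collapses.  Bimodality in these populations therefore reflects basin
structure, not metastable barrier hopping — the generator does not emulate
slow stochastic switching between states, nor instrument artifacts
(spillover, doublets, gating).  Passing pipeline tests show that the
statistics recover known dynamical structure under this measurement model;
they do not certify behaviour on real cytometry data.

`generate_timecourse` draws per-day two-channel log-normal mixtures whose
high-state weight decays exponentially (default 0.7·e^(−0.4·day) over days
0, 1, 2, 3, 5, 7) and whose high-component means drift down by 0.08 log
units/day, emulating gradual loss of expression after withdrawal of the
self-renewal stimulus.  `generate_beads` produces intensity =
gain·MESF^slope·e^noise fixtures.  All generators are pure functions of
their spec (byte-identical CSV on re-run at fixed seed).

## Problem sizes and numerical choices

The shipped studies and tests use: 10⁵ draws for sampler-vs-moment checks,
60,000 Gillespie replicates for the slow-switching covariance comparison
(sized so the 10% comparison band is ≈ 3 standard errors of the sample
covariance), 100×100 classification grids, 50 replicates of 10⁴-cell
populations for the verdict-separation study, and 1000-draw MI estimates
across 20 seeds for the dispersion-ordering study.  PMF support truncation
for normalization checks uses mean + 12 standard deviations.  Fig-1-style
count studies use mean-1 regulators (Gamma shape r = 1/θ) so λ keeps its
interpretation as the mean count — an assumption, since the source figure
does not print r.

## Known limitations

* The slow-switching covariance formula is exact only in the limit of frozen
  promoter states; at 100× separation a few percent of replicates flip
  states mid-episode, which is part of the physics the 10% band absorbs.
* The peak-dominance rule cannot reject symmetric equal-variance overlaps;
  that is a property of the published criterion, not of this implementation.
* Dual-allele reporter γ-factors and BAC copy-number effects are not
  modeled; only single-allele designs carry quantitative factors.
* MI estimates depend on the blocks discretization; values are comparable
  across conditions analyzed with the same procedure, not absolute
  information contents.
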