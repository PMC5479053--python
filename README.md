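# repfid — reporter fidelity in single cells

Fluorescent reporter cell lines are the workhorse for watching protein
dynamics in live cells, but a reporter is only useful if its signal tracks
the target protein *in the same cell*, and if inserting the construct did not
change the dynamics being watched.  `repfid` implements a quantitative
framework for both failure modes, motivated by the contested variability of
the pluripotency factor Nanog in embryonic stem cells:

* **Technical error — allele decoupling.**  For two alleles with mRNA means
  λ₁, λ₂ sharing an upstream regulator X, the stationary joint count law is
  a Gamma–Poisson mixture (bivariate negative binomial for X ~ Gamma(r, θ)),
  with Cov(m₁,m₂) = λ₁λ₂·Var(x) for *any* regulator law and correlation
  λF/(1+λF) in the regulator's Fano factor F.  Extrinsic regulatory noise
  synchronizes alleles; transcriptional bursting (telegraph switching,
  occupancy w, levels λ₊/λ₋) always decorrelates them:
  Cov = (wλ₊+(1−w)λ₋)²·Var(x) in the slow-switching regime.  Closed forms,
  exact samplers and a Gillespie simulator are provided.
* **Systematic error — feedback perturbation.**  Total protein from a
  positive-feedback gene obeys dn̄/dτ = α + n̄ᴴ/(γᴴ+n̄ᴴ) − n̄ with
  α = c_b/c_f and γ = c_d·K/2c_f, bistable inside a cusped wedge of the
  (α, γ) plane.  Reporter designs multiply γ by 2 (knock-in), 2/(1+ε)
  (pre/post insertion), 2/(1+εδ) (fusion) or 1 (BAC), and can push the
  system across a saddle-node curve — making a reporter line bimodal where
  the wild type is unimodal, or vice versa.  The package computes
  equilibria, bifurcation loci and per-design risk maps.
* **The measurement pipeline.**  MESF bead calibration, first-percentile
  alignment across days, 1-vs-2 component Gaussian mixture fits with BIC and
  robust-bimodality criteria (weights > 0.1 and mutual peak dominance), and
  mutual information between channels via a James–Stein shrinkage estimator
  over Bayesian-blocks discretization.

A seeded synthetic-data layer (`repfid.synthetic_data`) generates stochastic
feedback populations with known mono/bistability, differentiation
time-courses over days 0–7, and calibration-bead fixtures, so every pipeline
claim is testable against ground truth.  See `docs/methods.md` for models,
assumptions and numerical choices.

## Worked example

```python
import numpy as np
import repfid as rf

# --- allele coupling: dispersion of the shared regulator sets correlation
kin = rf.AlleleKinetics.from_means(50, 50)
model = rf.JointCountModel(kin, rf.RegulatorDistribution.gamma(2.0, 0.5))
print(rf.joint_covariance(model))     # 1250.0        (= 50·50·Var(x))
print(rf.allelic_correlation(model))  # 0.96154       (= λF/(1+λF), F=0.5)

draws = rf.sample_joint_counts(model, 1000, seed=1)
mi = rf.mi_shrinkage(draws["m1"].astype(float), draws["m2"].astype(float))
print(mi.value)                       # 0.712 nats; a constant regulator
                                      # gives 0.018 nats on the same seed

# --- feedback perturbation: a knock-in reporter destroys bistability
fb = rf.FeedbackParams(basal_rate=0.02, feedback_max_rate=1.0,
                       decay_rate=1.0, half_max=0.7, hill_coeff=2)
print(rf.classify(rf.nondimensionalize(fb, rf.ReporterDesign.wildtype())))
# 'bistable'   (α=0.02, γ=0.35)
print(rf.classify(rf.nondimensionalize(fb, rf.ReporterDesign.knock_in())))
# 'monostable' (γ doubled to 0.70)

# --- and the pipeline sees exactly that in simulated cells
pop = rf.generate_population(rf.PopulationSpec(feedback=fb, n_cells=10_000, seed=1))
logv = np.log(pop.data["nanog"].to_numpy())
fit1, fit2 = rf.fit_gmm(logv, 1, seed=0), rf.fit_gmm(logv, 2, seed=0)
print(rf.select_model_bic(fit1, fit2).n_components)  # 2 (BIC 19051 vs 39335)
print(rf.bimodality_filter(fit2))                    # (True, [])
print(np.round(fit2.weights, 2), np.round(fit2.means, 2))
# [0.5 0.5] [4.09 7.48]  — two subpopulations, as the bistable dynamics imply
```

The numbers above are what the code prints: the wild-type circuit at
(α, γ) = (0.02, 0.35) is bistable and its simulated population is robustly
bimodal on log fluorescence, while the same kinetics read through a
heterozygous knock-in (γ → 0.70) are monostable and fail the bimodality
criteria.

## Command line

Each study kind runs from a YAML config (the config is the sole source of
parameters, so runs are reproducible):

```sh
repfid risk-scan    --config risk.yaml    --out results/risk
repfid coexpress    --config coexpr.yaml  --out results/coexpr
repfid timecourse   --config tc.yaml      --out results/tc
repfid flow-analyze events.csv --beads beads.csv --config flow.yaml --out results/flow
repfid simulate     --config tc.yaml      --out results/sim
```

Outputs are deterministic CSV tables and JSON reports carrying a provenance
block (config hash, seed, package version).

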