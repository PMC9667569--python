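# screenmf

Latent-state matrix factorization for sparse, irregular screening
histories — reconstruction of continuous risk profiles from scarce
longitudinal state data and prediction of each individual's next
screening result, with Kaplan-Meier / probability-of-agreement
evaluation.

## The problem

Population screening programs (the motivating case is cervical-cancer
screening) record, for each participant, a handful of exam results
scattered over decades. Encoding results as ordered states
1 = normal, 2 = low-risk, 3 = high-risk, 4 = cancer and binning time at
3-month resolution turns a cohort into a partially observed integer
matrix `Y ∈ {1..4}^{N×T}` with observation set Ω covering only a few
percent of the entries, observed irregularly (long routine gaps after
normal results, rapid follow-up after abnormal ones) and with extreme
class imbalance. The goal is to fill in each row with a continuous
latent risk profile and use it to predict the next result.

## The model

Each observed state is a noisy measurement of a slowly varying latent
profile through a Gaussian kernel with reliability θ:

    p(Y_nt = s | M_nt) = C_M exp(−θ (s − M_nt)²),   s ∈ {1,2,3,4}

and the latent matrix is low-rank, `M ≈ U Vᵀ`, with r shared basic
profiles (columns of V) and subject coefficients U. The factors solve

    min_{U,V,z}  Σ_n ‖W_n ⊙ (Y_n − U_n Vᵀ Z_n)‖² + β₁Σ_n‖U_n‖²
                 + β₂‖V‖_F² + β₃‖R V‖_F²

where W carries discrepancy weights (zero off Ω; optionally inverse
propensity × state confidence), R is a temporal roughness operator —
either the forward difference D or its damped form K·D with Toeplitz
`K_ij = exp(−γ|i−j|)` — and Z_n is the 0/1 shift matrix that translates
the shared profiles by z_n bins (|z_n| ≤ 12 bins = 3 years) to align
subjects whose dynamics are offset in time. Five named variants (MF,
CMF, WCMF, SCMF, SWCMF) toggle the regularizer, the weights and the
shifts. The solver is block coordinate descent with exact ridge
updates and an exhaustive shift search; θ is then set to its
closed-form MLE `|Ω| / (2 Σ_Ω (Y − M̂)²)`.

The next-state distribution for a history x with priors at bins
t_p..t_q marginalizes the kernel over the empirical distribution of
fitted profiles:

    p̂(x_{t+} = s | x) ∝ Σ_n p(s | M̂_{n,t+}) · Π_j p(x_{t_j} | M̂_{n,t_j})

(accumulated in the log domain). Classification applies a threshold
cascade — cancer, then high-risk, then low-risk, tested against
τ₄, τ₃, τ₂, with normal as fallback — and the thresholds are fitted by
differential evolution to minimize Σ_s ∫ |S_s(t) − Ŝ_s(t)| dt between
per-state Kaplan-Meier curves of true and predicted labels. Model
quality is the probability of agreement φ_s(t) = P(|S_s(t) − Ŝ_s(t)| ≤
δ_s(t)) with margin δ = 2·bootstrap-sd of the reference curve, and its
normalized area Φ_s ∈ [0,1].

A synthetic-data module generates cohorts with the same statistical
signatures (≈8% density, state-dependent observation timing, normal-state
majority) from Gaussian-bump basic profiles and Exp(1) coefficients.

## Worked example

```
$ screenmf simulate --config sim.yaml --out hist.csv --latent-out latent.csv
wrote 120 subjects x 60 bins (density 0.2551) to hist.csv

$ screenmf fit --input hist.csv --variant CMF --model-out model.npz
converged after 178 sweeps; theta=4.9502; model written to model.npz

$ screenmf predict --model model.npz --input hist.csv --horizon-bins 4 --out pred.csv
wrote 1453 case predictions to pred.csv

$ screenmf evaluate --truth hist.csv --pred pred.csv --state 2 --out poa.json
Phi_2 = 0.6592 [0.6472, 0.6760] -> poa.json
```

with `sim.yaml` containing `n_subjects: 120`, `n_bins: 60`,
`target_density: 0.25`, `seed: 5`. The `fit` line reports the number of
alternating sweeps to convergence and the estimated kernel reliability
θ (≈5 means observed states sit tightly around the latent profile).
Each prediction row carries the four state probabilities, the cascade
classification and the held-out true state; `evaluate` reports the
normalized agreement Φ for the requested state with a 95% bootstrap CI
— here 0.66 for low-risk predictions half a year ahead.

`screenmf benchmark reconstruction|prediction --spec spec.yaml --out
results.csv` runs the density-sweep comparisons of the model variants
on synthetic cohorts.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the main computation from scratch: it generates synthetic
cohorts at densities 0.1/0.3/0.5, fits MF, CMF and SCMF, scores the
reconstruction error of each against the ground-truth latent matrix,
runs the full prediction pipeline (threshold selection, cascade
classification, per-state Kaplan-Meier + probability-of-agreement),
logs the summary tables to stderr, and writes the result manifest to
`--out`.
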