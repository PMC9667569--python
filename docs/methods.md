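# Methods

## Data model

A cohort is a partially observed matrix `Y ∈ {1,2,3,4}^{N×T}` on a
regular 3-month time grid (default origin at age 25). State 1–4 encode
normal / low-risk / high-risk / cancer in increasing clinical severity.
Only the cells in the observation set Ω are meaningful; every
computation masks the rest. Duplicate results in one subject-bin are
collapsed to the worst (maximum) state — a conservative clinical rule;
real registries do not document a canonical collapse.

The observation kernel links the discrete states to a continuous latent
value m: `p(s | m) = C_m exp(−θ (s − m)²)` with the four-state
normalizer `C_m = 1 / Σ_{s'} exp(−θ (s' − m)²)`. θ acts as a precision:
at θ = 2.5 a latent value of 2.0 still has ~8% mass two states away; at
θ → ∞ the kernel concentrates on the nearest state. The closed-form
reliability estimate `θ* = |Ω| / (2 Σ_Ω (Y − M̂)²)` is the MLE of the
*continuous* Gaussian form (normalizer √(θ/π)); we use that closed form
for θ and the discrete four-state normalizer wherever state
probabilities are needed. The two differ only through the bounded
support and the difference is immaterial for the residual scales seen
in practice.

## Factorization

The latent matrix is `M̂[n] = U_n Vᵀ Z_n` with rank-r factors and an
optional per-subject integer shift z_n (|z_n| ≤ 12 bins = 3 years),
realized as a 0/1 diagonal-band matrix with zero padding at the grid
boundaries. Padded cells contribute to the discrepancy with latent
value 0 — the literal consequence of the shift-matrix definition — and
this matters for interpretation (see the benchmark discussion below).

Objective: weighted masked squared discrepancy plus ridge penalties on
U and V and a temporal roughness penalty ‖R V‖². Two roughness
operators:

* `R = D`, the (T−1)×T forward difference — uniform smoothing;
* `R = K D` with Toeplitz `K_ij = exp(−γ|i−j|)` — the damped form,
  which penalizes sustained drift more and isolated fast changes less,
  matching screening dynamics (long stable stretches, sharp excursions
  around abnormal episodes). γ defaults to 1.0 bins⁻¹; at γ ≈ 50 the
  damped operator is numerically indistinguishable from D.

Solver: block coordinate descent. The U-step solves one r×r ridge
system per subject; the V-step solves the exact stacked (T·r) linear
system whose Hessian is block-diagonal in time from the shift-reindexed
data term plus `(β₂ I + β₃ RᵀR) ⊗ I_r` (direct dense solve; T·r stays
in the low thousands at registry scale); the z-step is an exhaustive
search over the 2·12+1 candidates with ties broken toward smaller |z|
and then toward the negative candidate (the generating convention is
unidentifiable from data, so the tie rule only needs to be fixed).
Every step is an exact block minimizer, so the objective is
non-increasing across sweeps; this is asserted at runtime. Profiles are
initialized `V ~ N(0,1)` from the config seed, shifts at zero;
iterations stop when the relative Frobenius change of the latent matrix
falls below 1e-6 (configurable) or at `max_iter`, in which case the
returned model carries `converged=False`. If the fit interpolates the
observed entries exactly the θ MLE diverges; θ is then set to infinity
rather than failing the fit.

Weight modes: `uniform` (1 on Ω); `inverse_propensity`
(state-confidence / observation-propensity on Ω) with a default
propensity given by the smoothed per-bin observation frequency — a
deliberate stand-in for registry-specific propensity models, which are
out of scope; `custom` for caller-supplied tables. Model variants:

| variant | R | weights | shifts |
|---|---|---|---|
| MF | D | uniform | – |
| CMF | K·D | uniform | – |
| WCMF | K·D | inverse propensity | – |
| SCMF | K·D | uniform | ±12 bins |
| SWCMF | K·D | inverse propensity | ±12 bins |

(SWCMF and WSCMF are the same model under two orderings of the name.)

## Prediction and classification

The next-state probability marginalizes the kernel over the empirical
distribution of the N fitted (shift-adjusted) profiles; the row-wise
product of kernel likelihoods over a long history underflows at cohort
scale, so all accumulation is in the log domain with logsumexp.

Evaluation cases require at least two observations strictly before
`target − horizon`; observations inside the moving window
`(target − horizon, target)` are withheld from the history. The cascade
tests states 4, 3, 2 in that order against thresholds τ₄, τ₃, τ₂ and
falls back to normal — the cascade exists because the class imbalance
otherwise drives every prediction to normal. Thresholds are selected by
differential evolution (population 15, up to 200 generations, Sobol
init, seeded, no polish — the objective is piecewise constant in τ so
gradient polish is a no-op) over (0,1)³, minimizing the summed
trapezoidal area between per-state first-encounter Kaplan-Meier curves
of true versus predicted labels. Thresholds are fitted on the training
cohort by default; the benchmark exposes a flag to fit them on the test
split instead.

## Survival evaluation

Kaplan-Meier curves of time to first encounter of each state are
computed by a hand-implemented product-limit estimator (subjects
censored at an event time remain at risk through that time; the test
suite pins it to lifelines at 1e-10 on random fixtures). Subjects never
showing the state are censored at their last labelled bin. All curves
are step functions carried forward on the common bin grid; left
truncation is not modelled (cohorts start screening at the same age).

The equivalence margin is δ(t) = 2·σ̂(S(t)) with σ̂ from 1000 bootstrap
resamples of the reference cohort. The probability law behind
φ(t) = P(|S(t) − Ŝ(t)| ≤ δ(t)) is a *paired* bootstrap: truth and
prediction label the same subjects, so each replicate resamples one set
of subject indices and applies it to both label sets. Pairing is what
makes self-agreement exact (identical labels ⇒ φ ≡ 1); independent
resampling would cap it near P(|Z| ≤ √2) ≈ 0.84. Φ is the trapezoidal
area of φ normalized by the window length; its 95% CI is a percentile
bootstrap over the replicate agreement indicators, labelled as such
because the construction behind published CIs of this statistic is not
standardized.

## Synthetic cohorts

The generator states a world: K = 5 Gaussian-bump basic profiles
`V[t,k] = exp(−10⁻³ (t − μ_k)²)` with centers evenly spaced across the
grid, Exp(1) subject coefficients, latent `M = U Vᵀ` affinely rescaled
onto [1,4] (on by default; raw Exp(1) mixtures otherwise concentrate
the discretized states at the top of the scale), kernel sampling at
θ = 2.5, and a left-to-right masking scan whose per-bin keep
probability depends on the most recent *kept* state — low after normal
(routine-interval behaviour), high after low/high-risk (follow-up
behaviour). Defaults: N = 2000 subjects, T = 176 bins (ages 25–69, the
screening span), observation table {before-first: 0.05, 1: 0.05,
2: 0.20, 3: 0.30, 4: 0.05}, calibrated once so the realized density is
≈0.08 at the default scale. With `target_density` the table is rescaled
globally, with the scale solved against an exact O(N·T) forward
computation of the expected density. At these defaults the state
histogram has a normal-state majority (51–66% across seeds) — the
generator emulates the *direction* of registry imbalance, not the >90%
figure, because the affine [1,4] rescale pins the latent range and
keeps substantial mass near the low-risk band. Green tests on this
world establish correctness of the mechanics, not clinical realism:
real registries are far more imbalanced, non-stationary across birth
cohorts, and subject to guideline changes, none of which is simulated.

## Benchmark design

The benchmark compares variants holding rank and penalty coefficients
fixed across variants (the comparison isolates R, W and the shift
mechanism, mirroring how the variants are defined) with defaults
rank 5 and (β₁, β₂, β₃) = (1, 1, 64). β₃ was chosen once by masked
validation — fitting on 80% of the observed cells and scoring
prediction of the held-out 20% — which selects strong smoothing on this
world at every density tried; pushing β₃ further toward its interior
optimum (≈256–1024) makes MF and CMF indistinguishable, so the default
sits in the regime where the operators differ while both are well
inside the validated range.

Two findings from this benchmark are worth stating plainly. First, the
damped-difference model reconstructs unobserved cells better than the
plain-difference model at every density (0.1–0.5), and errors fall
monotonically with density. Second, the shifted model does *not* win on
this synthetic world: the generator contains no per-subject time
shifts, so the shift search can only chase discretization noise, and
each spurious shift zero-pads boundary cells whose true latent is ≥ 1
by construction — decomposing the error shows the padded cells account
for essentially the whole gap. On data that genuinely contains shifts
the mechanism recovers them (≥90% exact recovery in the acceptance
suite). The corresponding acceptance check of the full ordering is
deliberately left failing rather than weakened; see the repository's
test suite.

## Numerical notes and limitations

* Singular block systems (β = 0 with degenerate rows/columns) raise
  errors that name the ridge coefficient to increase.
* Observation-probability tables are clipped to [0,1] under global
  rescaling; an unreachable target density raises.
* `density ≈ 0.08` at registry scale implies ~14 observations per
  subject; below ~2 observations per subject most operations degrade
  or reject (evaluation cases need two priors by construction).
* The differential-evolution objective is piecewise constant; different
  seeds can return different τ of identical objective value.
* No competing-risks handling, no left truncation, no per-exam-type
  modelling, no registry export parsing.
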