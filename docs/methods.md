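# Methods

## Model and decomposition

`fedcox` fits the Cox proportional hazards model on right-censored data whose
covariate columns are distributed over K institutions while the outcome stays
with a central aggregator. The estimand is the maximizer of the Breslow-form
partial likelihood; tied event times are grouped into a single event set E_t
with multiplicity d_t. The risk-set convention is R_t = {n : observed time ≥ t}
(a subject is at risk at its own event time) — the standard choice, and the
one under which the federated coefficient update is the exact minimizer of its
local subproblem of the centralized objective.

The ADMM splitting introduces per-record, per-party consensus copies z_nk of
the local linear predictors σ_nk = x_nkᵀβ_k and duals γ_nk with penalty ρ.
The augmented Lagrangian separates as follows:

* the event-linear term Σ_t Σ_{n∈E_t} x_nkᵀβ_k and the quadratic coupling go
  to the party subproblem, whose exact solution is the closed form
  β_k = [ρ Σ_n x_nk x_nkᵀ]⁻¹ [Σ_n (ρ z_nk − γ_nk) x_nk + Σ_t u_kt];
* the log-partition term goes to the z-subproblem. It depends on {z_nk} only
  through the per-record sums, so minimizing over the per-party deviations in
  closed form leaves a reduced problem in the consensus mean z̄:

      F(z̄) = Σ_t d_t log Σ_{m∈R_t} exp(K z̄_m) + (Kρ/2) Σ_n (z̄_n − σ̄_n − γ̄_n/ρ)²,

  after which z_nk = z̄_n + (σ_nk − σ̄_n) + (γ_nk − γ̄_n)/ρ; the mean over k of
  z_nk equals z̄_n identically.
* dual ascent γ_nk += ρ(σ_nk − z_nk), executed identically at the party and at
  the aggregator's mirror (after distribution the updated duals are equal
  across parties for each record — verified as a test property).

Initialization is β = γ = z̄ = 0; one iteration runs β-updates → σ reports →
z̄ Newton solve → distribution of z_nk, γ̄, σ̄ → dual updates. The default
stopping rule is a fixed iteration budget (500); an optional primal-residual
threshold (max |σ_nk − z_nk|) can stop earlier but is off by default, since a
fixed budget is the conventional way to run and report this solver.

## Secure computation of u_kt

u_kt = Σ_{n∈E_t} x_nk is the only outcome-dependent input a party needs, and
it is constant over iterations. It is computed once, at preparation, as a
2-party scalar product between the party's fixed-point-encoded column (Alice)
and the aggregator's raw Boolean event vector (Bob), with a commodity server
supplying correlated masks R_a, R_b, r_a + r_b = R_a·R_b. The commodity role
rotates over the other institutions (for party k, the next institution
(k+1) mod K serves; with K = 1 a dedicated neutral commodity process stands
in, flagged in the role name). The commodity role is a pure function of its
seed: it never sees data or transcript messages.

The protocol yields additive shares V_1 (party) + V_2 (aggregator) = A·B. The
party needs the full u_kt for its closed-form update, so the aggregator
reveals its scalar share V_2 to the party, which reconstructs
(V_1 + V_2)/10^p. Revealing V_2 discloses only the masked sum itself — the
quantity the party is entitled to — not the event vector.

Arithmetic runs on unbounded Python integers: the share identity is exact,
with no modular ring and no overflow. Only the party's real-valued vector is
encoded (round half-away-from-zero, chosen for sign symmetry); the Boolean
mask stays unscaled, so decoding divides by the scale exactly once and the
result deviates from the plaintext masked sum by at most 0.5 · d_t · 10⁻ᵖ.
With integer-coded covariates (the default generator setting) encoding is
exact and the federated solver reproduces the centralized trajectory to
floating-point accuracy — the analogue of registry data whose codes have few
digits. Masks default to the range ±2⁴⁰, which dwarfs any encoded magnitude
at precision 5 while keeping integer products cheap.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| ρ | 0.25 | ADMM penalty; the conventional setting for this solver, kept as the study condition throughout |
| precision p | 5 | decimal digits of the fixed-point codec; enough that encoding error (≤ 0.5·10⁻⁵ per element) is negligible against coefficient scales, small enough that integer products stay cheap |
| inner_tol | 1e-5 | gradient max-norm tolerance of both Newton solvers (aggregator z̄ solve and the central baseline) |
| max_iter | 500 | outer ADMM budget; accuracy vs the central fit improves monotonically with it |
| mask_range | 2⁴⁰ | uniform mask bound for the protocol |
| separation guard | ‖β‖_∞ > 50 | the central fit fails loudly when the partial likelihood is monotone (separated data) and has no finite maximizer |

## Numerical choices

* Both Newton solvers damp by step-halving (≤30 halvings) with a tiny
  acceptance slack (1e-12 relative) so that full steps remain acceptable at
  floating-point resolution near the optimum; the central fit converges on
  gradient max-norm, from β = 0.
* The aggregator's z̄ solve warm-starts from the previous iteration and always
  takes at least one Newton step per outer iteration: the warm start often
  already satisfies the 1e-5 tolerance, but one quadratic-convergence step
  from there resolves the consensus point orders of magnitude deeper, which
  the outer loop needs to drive the primal residual below ~1e-6.
* Because risk sets are nested once subjects are sorted by time, every
  log-sum-exp quantity is a suffix sum: the Breslow value/gradient/Hessian
  cost O(N M²) and the N×N Hessian of F is assembled in O(N²) (outer products
  of cumulative weights) before a dense solve. These are exact Hessians, not
  approximations. All exponentials are max-shifted.
* Local Gram matrices are inverted once per run; condition numbers above 1e12
  (collinear or constant local features) are rejected at preparation.
* Per-t u_kt values are stored even though the β-update needs only their sum,
  because per-event-time preparation is the natural protocol unit and the
  cached matrix is the object whose constancy is asserted; the sum shortcut
  would hide that contract.
* Ties: the generator rounds times to 6 decimals (creating controlled ties);
  equality of times is exact numeric equality.

## Synthetic data generator

`generate_synthetic_survival` draws event times from an exponential
proportional-hazards model with hazard `baseline_rate · exp(xᵀβ_true)` and
independent exponential censoring whose rate is solved numerically (Brent) so
that the expected censored fraction, given the realized hazards, equals the
requested `censor_rate`. Defaults emulate registry-style data: integer-coded
covariates drawn uniformly from {0,…,9} (single-digit codes), baseline rate
0.1, censored fraction 0.3. The comparison experiments use
β_true = (0.1, −0.1, 0.05, −0.05) — hazard ratios ≈ 1.05–1.1 per code unit,
a realistic effect size that keeps linear predictors in a moderate range at
n = 100.

What the generator does **not** emulate: covariate correlation and
confounding structure, informative or administrative censoring, time-varying
effects, competing risks, missingness, and the heavy categorical structure of
real registries. Passing tests therefore demonstrate algorithmic equivalence
(federated = centralized on the same data) and protocol exactness, not
clinical validity of any fitted model.

## Problem sizes

The test and reproduction runs use N = 100, M = 4, K ∈ {2, 3, 5} for the
equivalence sweep (100 and 500 iterations), N ≤ 50 grids for the accounting
identities, and n = 2000, M = 2 with 100 ADMM iterations for parameter
recovery — at that accuracy the federated estimate sits within ~10⁻³ of the
central one, far inside the 3-standard-error recovery band, so longer budgets
would not change the conclusion.

## Known limitations

* All roles run in one process over an explicit message bus; there is no
  network transport, fault tolerance, or asynchronous execution.
* Privacy is argued at the protocol-structure level (what each role receives);
  no cryptographic hardness or malicious-adversary guarantees are claimed,
  and the commodity server must be honest.
* Only the 2-party scalar product with a commodity role is implemented; no
  n-party generalization, no hybrid (horizontal+vertical) splits.
* No baseline-hazard recovery, stratification, penalization, time-varying
  covariates, competing risks or left truncation.
* The aggregator's Newton solve is O(N³) per step; dense N×N solves make
  N ≳ 10⁴ impractical without further structure.
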