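# Methods

## The growth model and its propagation

Each tissue is a two-compartment linear system: proliferative cells P
self-renew at rate γ, die at rate δ, become quiescent at rate α, and are
killed by the drug at rate s·f(t); quiescent cells Q die at rate λ and
re-enter the cycle at rate β. All rates are in days⁻¹ and are packaged in
`data/parameters.yaml` for bone marrow (γ=1.470, δ=0, α=5.643, β=0.480,
λ=0.164), breast cancer (0.500, 0.477, 0.218, 0.050, 0) and ovarian cancer
(0.6685, 0.4597, 0.2225, 0.0500, 0).

Treatment starts from the untreated steady-state composition: the
proliferative fraction ρ* solves the stationarity quadratic of P/(P+Q) and
the total mass is normalised to 1, so P(0)=ρ*, Q(0)=1−ρ*. For the packaged
sets ρ* is 0.1031 (bone marrow), 0.2003 (breast) and 0.3600 (ovarian). The
root must lie strictly inside (0, 1); parameter sets violating this (e.g.
β=0 with a draining proliferative pool) are rejected rather than patched.

Because the dose is held constant over each decision interval, every step
is an exact linear map. The package propagates with the matrix exponential
of the rate matrix, and carries the running integral of P+Q as a third
coordinate of an augmented linear system, so per-step rewards and the
episode objective are exact to round-off rather than quadrature-limited.
Adaptive Runge–Kutta integration appears only as an independent oracle in
the tests. Numerical consequences: step composition holds to ~1e−15,
reward additivity (sum of per-step rewards = episode objective) to
~1e−12, and the positive orthant is preserved exactly (the off-diagonal
rates are non-negative, so the step matrices are non-negative).

## The objective and its calibration

`J_b(f) = ∫ (P_bm + Q_bm) dt − (b/2) Σ (1−f_t)² dt` rewards surviving bone
marrow and penalises withheld dose. Two constants are genuine calibration
choices of this package because no canonical values exist for them: the
drug strength `s` and the penalty weight `b`. Both default to 1.0. This
calibration follows a qualitative criterion: under it, a
full-strength 21-day course depletes the
bone marrow to ~10% of its pre-treatment mass, and the nominal optimal
schedule is an interior rest-then-ramp profile (13 rest days, then doses
ramping 0.2→1.0) rather than a degenerate all-zero or all-one schedule.
Every downstream number that depends on controller scores — random-agent
means, scaled-score gaps, Wilcoxon statistics — is therefore
calibration-dependent and is reported as such; the deterministic
quantities (steady states, sensitivities, solver exactness) do not depend
on s or b.

An alternative objective trading bone marrow against tumour burden,
`∫ [P_bm + Q_bm − b (P_c + Q_c)] dt` with two decoupled model copies, is
provided as `alt_objective` for experimentation; all shipped analyses use
the primary functional.

## Exact discrete optimal control

The scheduling problem discretises dose (11 levels, 0 to 1 by 0.1) and
time (daily). For fixed parameters the value function is a maximum of
affine functions of the 2-d state: each action contributes an affine
reward (w_a·x + d_a) and a linear transition (M_a x). The solver runs
backward dynamic programming over these affine pieces; at each stage the
piece set is pruned to the extreme points of the dual point cloud
{(g, h)}, computed with a convex hull. A piece whose dual point is a
convex combination of others is dominated by their maximum *everywhere*,
so this pruning is exact, not approximate. Degenerate (affinely
dependent) clouds are pruned in their affine span. Piece counts stay in
the low thousands at the 21-day horizon; a nominal solve takes ~1 s on one
CPU, which makes exact per-patient maxima for hundreds of virtual patients
routine.

The forward pass extracts the schedule greedily from the piece sets,
taking the lower dose at exact value ties (and `brute_force` breaks ties
toward the lower total dose, then lexicographically) so solutions are
deterministic. Reported values are always recomputed from the returned
schedule with `episode_objective`, so solution objects are self-consistent
by construction, and the optimality gap of the DP solver is 0. Exactness
is anchored to `brute_force`, an independent vectorised enumeration of all
schedules at short horizons: the suite checks identity over T ∈ {3, 4},
b ∈ {0, 0.5, 1, 5, 100} on randomly perturbed patients.

## Local sensitivity analysis

Each non-zero rate is scaled one-at-a-time by +1%, the initial condition
is re-derived from the perturbed steady state, the untreated system (f≡0 —
the dose function is deliberately off, so the analysis probes the disease
model rather than a particular schedule) runs to day 21, and the relative
sensitivity R = (Δx/x₀)/(Δp/p₀) of P(21) and Q(21) is tabulated. Zero
rates are excluded — a multiplicative perturbation cannot move them. The
mean absolute sensitivities are ≈2.3 (P) and ≈0.97 (Q) for breast, ≈5.3
and ≈3.4 for ovarian, ≈4.1 and ≈3.5 for bone marrow: a 1% parameter error
moves day-21 predictions by several percent, which is the quantitative
motivation for asking whether nominal-patient schedules transfer. Halving
the perturbation changes the coefficients by well under 10%, so the
first-order reading is stable.

## Virtual patients

A virtual patient multiplies the four non-zero bone-marrow rates (γ, α, β,
λ; δ is zero and never perturbed) by factors drawn from [1−k, 1+k] with
4-dimensional Latin hypercube sampling (scipy's implementation: one sample
per equal stratum per dimension, uniform within strata, independent
per-dimension permutations, no correlation control — the rates are treated
as independent). Strengths k ∈ {0.15, 0.20, 0.25} are studied; reference
cohort sizes are 1000 (training, used only to build the NTNOC library) and
200 (testing). Every sampled patient is verified to possess a valid
steady-state fraction in (0, 1); at k ≤ 0.25 this always holds, and a
violation raises instead of resampling. Cohorts serialise to CSV with both
factors and derived rates so downstream runs are replayable. Cohort
realisations are reproducible only given the seed; distribution-level
properties (stratification, uniform marginals) are what the tests assert.

## The learning agent

The Q-network is a numpy MLP — 11 inputs, two ReLU hidden layers (64, 96),
11 outputs — trained with Adam (lr 0.003809) on the squared error of the
selected action's Q-value against the double-Q target (online network
selects the successor action, a target network hard-copied every 500 steps
evaluates it; no bootstrap past day 21). The 11-entry input is the day
index plus a 10-day most-recent-first window of relative bone-marrow
totals, padded with 1.0 before treatment; the day index is fed raw (0–20).
Remaining defaults: discount 0.9553, batch 96 sampled uniformly without
replacement from a FIFO replay buffer (capacity 10⁶), 5000 random warm-up
steps, ε annealed linearly 1→0.01 over 25000 steps, at most 50000
episodes with early stopping after 500 episodes without a new best
behaviour-policy episode return, and best-of-5 run selection *by greedy
objective value*, never by training loss. Where the protocol is
underdetermined the package makes these choices: episodes (21-step resets)
are the unit of the stopping rule; the greedy policy is additionally
evaluated every 50 episodes and the best-scoring weight snapshot is what a
run returns (stabilises run selection against late-training drift);
rewards are used raw. Training is bit-reproducible for a fixed seed on a
single CPU.

`reduced_budget_config()` (2000 warm-up steps, ε annealed over 15000
steps, ≤10000 resets, the usual patience of 500) is the problem size used
by the shipped tests and examples: on this environment the best of five
such runs typically reaches ~99% of the exact optimum in about a minute
per run, and the suite asserts the ≥95% convergence property at this
scale.

The hyperparameter search explores (hd1, hd2 ∈ {64, 96, …, 256}, batch ∈
{32, 64, 96, 128}, lr ∈ (10⁻⁴, 10⁻¹) log-uniform, discount ∈ (0, 1)) with
a Gaussian-process surrogate and expected-improvement acquisition after a
short random warm start, and returns the full per-trial score table for
conditioned-versus-unconditioned distribution comparisons
(`ks_two_sample`).

## NTNOC

The nearest-training-neighbour optimal controller gives classical control
the same observations as the RL agent: solve the exact OC problem for
every training patient (parameters known), simulate each under its own
optimal schedule, and log the observation window and dose at every day. A
test patient is treated closed-loop by replaying, each day, the dose of
the Euclidean-nearest *same-day* logged window (cross-day matching is
disallowed, which also makes the day component of the state irrelevant to
the distance). Ties — which genuinely occur at day 0, where every window
is all-ones — resolve to the lowest patient id, so the day-0 dose is
library-wide deterministic and exact self-retrieval holds for the
lowest-id patient.

## Evaluation and statistics

Controllers are scored per patient and normalised by that patient's exact
discrete-control optimum; scaled scores must lie in (0, 1] up to float
tolerance and a violation raises (it would mean the normaliser is not the
true optimum). The random baseline simulates i.i.d. uniform dosing
(vectorised; 10⁶ episodes in seconds) and reports the mean with both the
sample standard deviation and the standard error of the mean, on the raw
and max-normalised scales — at the packaged calibration the normalised
mean is ≈0.68 with sample std ≈0.05. Paired controller comparisons use
the one-sided Wilcoxon signed-rank test (zero differences discarded,
average ranks on ties, exact null enumeration up to 25 non-zero pairs,
normal approximation beyond); distribution comparisons use the two-sample
Kolmogorov–Smirnov test. Score histograms use 0.025-wide bins with edges
at multiples of 0.025 on (0, 1].

The robustness experiment in the shipped suite uses 50-patient testing
cohorts per strength (k ∈ {0.15, 0.20, 0.25}) and asserts the directional
findings at this scale: the feedback RL policy's median scaled score
exceeds the open-loop nominal schedule's at k = 0.20 and 0.25 (one-sided
Wilcoxon, α = 0.01) and the open-loop mean degrades monotonically in k.

## What the synthetic cohorts do and do not show

The virtual patients emulate exactly one kind of real-world uncertainty:
multiplicative error in the bone-marrow rate constants, independent across
rates and bounded by ±k. They do not emulate measurement noise in the
marrow observations, intra-patient temporal drift, pharmacokinetics,
correlated parameter errors, model misspecification, or cancer-tissue
variability (only bone marrow enters the objective, so only its rates are
perturbed). Passing tests therefore show that the feedback advantage is
real *within the model family*, not that it transfers to clinical data.

## Known limitations

- `s` and `b` are calibration constants; magnitudes of all score-based
  results move with them (directional conclusions proved stable across the
  perturbation strengths studied).
- The discrete solver is exact for this linear-dynamics/affine-reward
  class only; nonlinear growth models would need the branch-and-bound or
  MINLP routes it was designed to replace.
- The DDQN is a small, single-CPU implementation: no prioritised replay,
  dueling heads, GPU paths or continuous actions — deliberately, since the
  action set is discrete and small.
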