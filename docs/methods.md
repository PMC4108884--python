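# Methods

## The model

`flowpht` analyses the recurrence–progression process of non-muscle-invasive
bladder carcinoma (NMI-BC) as a three-state illness–death model: state 0 is
disease-free after transurethral resection (the time origin), state 1 is the
first recurrence, state 2 is progression to muscle-invasive stages. The
process is treated as semi-Markov: the sojourn clock restarts on every state
entry, and sojourn laws need not be exponential. Time is measured in years
throughout; there is no unit-conversion layer.

The multistate model is represented as a *flowgraph*: a directed graph whose
branch (i, j) carries the transmittance `p_ij · LT_ij(s)` — the probability
of taking the branch times the Laplace transform of the branch's
waiting-time density. Transmittances compose by two rules (series branches
multiply, parallel branches add), which gives the 0→2 first-passage
transform of the illness–death graph

    LT(s) = [ p01 p12 LT01(s) LT12(s) + p02 LT02(s) ] / (p01 p12 + p02).

The division by the total path probability `p01 p12 + p02` conditions on
eventual passage: in the wider disease process a patient may never progress,
so the unnormalised sum is the transform of a defective law. The carried
probability of the composed transmittance is exactly that passage
probability. Only series/parallel composition on this acyclic three-state
graph is implemented; graphs with feedback (multiple recurrences) would
require Mason's rule and are an explicit extension point, not a feature.

## Waiting-time family: Erlang mixtures as phase-type laws

Each branch law is a three-component Erlang mixture
`G(t) = p1 F1(t) + p2 F2(t) + p3 F3(t)` with Erlang components
`E[r_i, mu_i]`, default shapes `(1, 3, 5)` (configurable). The family is
dense enough to capture the decaying-then-humped waiting-time shapes seen in
recurrence data while keeping every object phase-type: an Erlang is a chain
of `r` sequential exponential states, and the mixture is the block-diagonal
direct sum with initial mass `p_i` on each block's first state (a 9-state
chain for shapes (1, 3, 5)). All functionals come in two interchangeable
routes:

* matrix-analytic — `F(t) = 1 − α exp(Tt) e`, `f(t) = α exp(Tt) T⁰`,
  `L(s) = α_{m+1} + α (sI − T)^{-1} T⁰`, with `expm` by scaling-and-squaring
  (no eigendecomposition: Erlang blocks are defective) and the transform by
  a linear solve per evaluation point, never an explicit inverse;
* closed-form — gamma CDFs and rational transforms
  `Σ p_i (mu_i/(s+mu_i))^{r_i}`, used by the fitting loop and the transform
  algebra because they are orders of magnitude cheaper.

Tests hold the two routes against each other and against `scipy.stats.gamma`.

Hazard evaluation refuses to divide once the survival mass falls below
1e−12: below that, `f` and `S` carry independent absolute errors of order
machine epsilon and their ratio is noise, so the package raises rather than
returning a silently wrong hazard.

## Estimation

**Branch curves.** For each branch the cohort yields a censored sojourn
sample: time to the destination if the transition was observed, time to any
other exit (competing transition or end of follow-up) as censored. The
product-limit (Kaplan–Meier) complement `F̂ = 1 − Ŝ_KM` is provided and
tested against hand-computed risk-set products, with event-before-censoring
tie handling; estimation is delegated to `lifelines`.

The pipeline's default branch-curve estimator, however, is the
cause-specific **Aalen–Johansen cumulative incidence**
`CIF(t) = Σ Ŝ_any(t_k−) d_j(t_k)/Y(t_k)`, renormalised by its plateau. The
reason is a bias that matters here: under the latent branch structure
(a patient who will never take a branch is only ever observed as censored),
the cause-specific KM complement converges to a curve whose shape is
distorted by the competing branch's survival in the risk set. The
distortion is negligible when the never-transitioning mass dominates
(sup-error ~0.004 under the published branch probabilities) but reaches
~0.05 when the competing branch is large — enough to dominate the
end-to-end error budget. The AJ incidence is consistent for
`P(sojourn ≤ t, exit by this branch)` regardless, its plateau estimates the
branch probability, and it reduces exactly to `1 − KM` when no competing
exit is present. `branch_estimator="km"` restores the pure product-limit
route.

Renormalisation by the plateau converts the defective incidence curve into
an estimate of the *conditional* sojourn CDF given the transition, which is
what a transmittance needs. It assumes follow-up long enough that the
branch's sojourn law is essentially exhausted at the last event time; with
the default 15-year horizon and sojourn medians of 1.5–2.5 years this
truncation bias is well under 1%.

**Branch probabilities.** Default: the AJ plateau per branch (consistent
under independent censoring). The naive ratio — observed i→j transitions
over patients at risk in i — is available as `method="ratio"` and is what
one would read off the raw counts, but it is biased low under censoring.
Both can be overridden with user-supplied values, since published analyses
of this model treat the p's as fixed inputs.

**Mixture fitting.** With shapes fixed, weights and rates minimise the
Euclidean norm of `F̂(t_k) − G(t_k)` over the estimate's jump times (its
support; a uniform grid is available). Initialisation is two-stage:
moment-style rates `r_i / t_med` from the KM median (restricted mean when
the median is not reached), then non-negative least squares
(Lawson–Hanson, `scipy.optimize.nnls`) for the weights on the stacked
system including the sum-to-one row. The constrained minimisation runs
unconstrained in a reparameterised space — weights through softmax, rates
through log, log-rates clipped to ±30 so the map can never underflow to an
infeasible zero — with Nelder–Mead (the objective is cheap and the
parameter space is 6-dimensional). Feasibility of the returned spec is
therefore unconditional; weights are floored at 1e−6 and renormalised to
honour strict positivity. The better of {initial point, optimiser result}
is returned, so the objective never exceeds its NNLS-start value. A
deterministic multi-start over rate scalings (×0.5, 0.75, 1, 1.5, 2.25)
guards against local minima; ties go to the first start. When the supplied
curve still plateaus below 0.9 the fit report flags it: a proper CDF must
overshoot a defective tail.

## Transform inversion

The first-passage density is recovered from its transform by the EULER
algorithm (Abate–Whitt): trapezoidal discretisation of the Bromwich
integral along `Re(s) = A/(2t)` with step `π/t`, accelerated by Euler
(binomial) summation of the alternating partial sums. Defaults
`A = 18.4` (discretisation error ~1e−8), `m_euler = 11`, `n_base = 15` are
the classic settings; all are configurable, and the closed-form battery
(exponential, Erlang 1/3/5, hypoexponential, three-component mixture) holds
the implementation below 1e−6 absolute error on t ∈ [0.1, 20].

Survival is `1 − ∫₀ᵗ f`, accumulated with 12-point Gauss–Legendre
quadrature per grid interval and clipped to [0, 1]; a pre-clip rise beyond
1e−4 triggers a warning (it signals an inaccurate or improper density).
Hazard is the pointwise ratio, masked (NaN) where survival ≤ 1e−8. The
default output grid is 512 uniform points on [0, 1.25 × largest observed
total time].

As an independent cross-check the conditional first-passage law is also
built explicitly as a phase-type object: a two-component mixture of the
concatenated 0→1→2 chain (convolution) and the direct 0→2 chain, with
mixing weights `p01 p12/(p01 p12 + p02)` and `p02/(p01 p12 + p02)`. The
matrix-exponential survival of this representation and the EULER-inverted
survival agree to better than 1e−7; the package treats any disagreement
beyond 1e−4 as a defect.

## Markov baseline

The comparison model is the homogeneous continuous-time Markov chain on
{0, 1, 2} with occurrence/exposure intensities
`q_ij = (# i→j transitions)/(time at risk in i)` — the exact-observation
MLE, applicable because the event-history table records transition times
exactly (panel-observation schemes are out of scope). Its 0→2 first-passage
survival is the transient row-0 mass of `exp(Q_sub t)`, i.e. the phase-type
survival with `α = (1, 0)`, `T = Q_sub`. Note the structural mismatch this
baseline carries by construction: absorption is certain in the Markov
chain, so its curve is an unconditional non-absorption probability, whereas
the flowgraph curve conditions on eventual progression. Both are compared
against the plateau-normalised empirical progression curve; on strongly
non-exponential (Erlang-5-dominated) sojourns the Markov curve misses the
truth by a wide margin while the flowgraph curve tracks it — the restatable
core of the semi-Markov argument.

## Synthetic cohorts

No event-history dataset with this structure is public (the motivating
hospital cohort is not deposited), so validation runs on synthetic cohorts
whose generator mirrors the assumed structure exactly: latent branch choice
in state 0 with probabilities `(p01, p02, 1 − p01 − p02)` — the last mass
never leaves and can only be observed censored — Erlang-mixture sojourns
per branch, a second branch choice `(p12, 1 − p12)` in state 1, and
independent censoring from an exponential drop-out and/or an administrative
horizon. All randomness flows from one `numpy.random.Generator` seed;
regeneration is byte-identical.

Defaults are the published analysis conditions: branch probabilities
p01 = 0.3967742, p02 = 0.02507837, p12 = 0.03252033, and — since no fitted
sojourn parameters are published — three distinct shape-(1,3,5) mixtures
with medians of roughly 1.5–2.5 years, a realistic recurrence/progression
time scale. The 957-patient profile (`paper_like_profile`) adds a 15-year
administrative horizon (the 1995–2010 follow-up window) and a light
exponential drop-out of 0.03/yr. One structural tension is worth stating
plainly: the published cohort reports 434 recurrences + 24 progressions of
957 patients (47.9% state-0 events), which is arithmetically incompatible
with the published p01 + p02 = 0.4219 under this generator — state-0
censoring can never fall below 57.8%. The profile keeps the published
probabilities and accepts a censored fraction at that structural floor
rather than distorting the probabilities to chase the counts.

What the generator does *not* emulate: multiple recurrences, covariate
effects, dependent censoring, and any calendar-time structure. Passing
tests therefore demonstrate internal consistency of the estimation chain
under the model's own assumptions, not robustness to their violation in
real registry data.

## Validation scenarios and problem sizes

* Closed-form battery and oracle cross-checks: exact, grid-based, seconds.
* Simulation equivalence: 1e5 conditional first-passage paths under the
  published branch probabilities; KS distance ~0.003–0.01.
* End-to-end recovery: n = 5000 patients, branch probabilities
  (0.45, 0.20, 0.40), drop-out 0.05/yr plus 15-year horizon. This
  *validation scenario* populates all three branches well; the recovered
  0→2 survival lands within sup-distance ~0.01–0.03 of the analytic truth.
  Under the published (rare-progression) probabilities the same pipeline is
  information-limited — only ~110 direct progression events at n = 5000 —
  and the recovery distance is ~0.03–0.07, a sampling-noise floor rather
  than an estimator defect; the acceptance script reports this measurement
  for the 957-patient profile honestly.
* Markov contrast: same scenario with Erlang-5-dominated mixtures
  (weights (0.05, 0.10, 0.85)); flowgraph error ~0.02 vs Markov error ~0.7.

## Known limitations

* Single recurrence only; the general recurrence–progression graph with
  feedback is out of scope.
* The plateau renormalisation presumes follow-up exhausts each sojourn law;
  with heavily truncated follow-up the conditional-law estimates are
  conditional on transition *within* follow-up.
* Fitting is curve-matching (minimum-distance on the incidence estimate),
  not maximum likelihood; no standard errors are produced.
* The ratio p-estimator is kept only for fidelity to how such probabilities
  are usually quoted from raw counts; it should not be used on heavily
  censored cohorts.
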