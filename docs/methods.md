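# Methods

`pesddm` analyzes post-error behavior in a two-alternative visual-search
task through the lens of the drift-diffusion model (DDM). This note
documents the model, the synthetic-data generator, the estimation
machinery, the numerical choices, and the limitations that matter when
interpreting results.

## The decision model

Each trial is modelled as a Wiener diffusion between two absorbing
boundaries separated by *a* (the decision threshold). Evidence starts
midway (relative start point z = 0.5, unbiased) and accumulates at drift
rate *v* with within-trial noise *s*; absorption at the upper boundary is
a correct response (accuracy coding), at the lower an error. Observed
response time is the first-passage time plus a non-decision offset
*T_er* covering stimulus encoding and motor execution.

Conventions: *s* = 1 and time in seconds. Fitted group-level magnitudes
(*a* ≈ 2.8–3.2, *v* ≈ 0.6–0.8, *T_er* ≈ 0.78 s) are only meaningful under
this scaling; the Ratcliff *s* = 0.1 convention would rescale *a* and *v*
by 0.1. Only the three central parameters are estimated. The start point
is fixed at 0.5 and no inter-trial variability parameters (sv, sz, st)
are included: with an unbiased start and no variabilities, correct and
error RT distributions coincide — a property several tests exploit.

The defective first-passage density is evaluated with the dual-series
representation: a small-time image sum and a large-time eigenfunction
sum, switching to whichever needs fewer terms for a truncation error of
1e-12 (far below the 1e-7 design bound; the switch is invisible at
double precision, which a test verifies at the exact handover point).
Likelihood: the summed log density at rt − T_er; any trial at or below
T_er yields −∞ (hard support — the likelihood stays a true density, no
soft penalty).

Sampling is by inverse transform of the numerically integrated defective
CDFs on a sqrt-spaced grid (dense near zero where the density peaks),
4096 points by default, total-mass tolerance 1e-9. The independent check
of the density is an Euler–Maruyama random-walk histogram (dt = 1e-4);
the sampler is checked against an independently integrated finer-grid
CDF by Kolmogorov–Smirnov, keeping the two routes separate.

## Trial-log preprocessing

Preprocessing is two-stage, in this order:

1. **Participant exclusion** — remove participants whose overall accuracy
   is at least 3 SD below the cohort mean (mean/SD over participants'
   accuracies; a degenerate SD of 0 excludes nobody) and participants
   with any single response above 10 s.
2. **Trial trimming** — remove trials whose log RT falls outside
   mean ± 2 SD of the pooled post-exclusion log-RT distribution (removes
   ≈ 4.6% for log-normal RTs). Trimming is global, not per participant:
   the protocol states the rule without qualification and a global 2σ
   rule matches the reported ≈ 5% removal.

Both stages return the thresholds they used and accept them back;
re-applying a stage with its recorded thresholds is a no-op. Naive
re-application recomputes the statistics on already-trimmed data and
would remove a further ≈ 4.6% — an inherent property of any
recompute-and-trim rule, which is why the thresholds are first-class
outputs.

## Sequence extraction

Episodes are anchored on an error (E) or correct (C) trial with a
required correct context: error anchors must be preceded by two correct
trials (C C E), correct anchors by two further corrects (C C C) — the
matched control. The analyzed target sits *d* ∈ {1..5} trials after the
anchor; for d ≥ 2 every intervening trial must be present and correct.
The two-correct pre-anchor context is enforced at all distances (the
distance-1 rule extended, keeping anchors comparable across distances).
The target's own correctness is never constrained — it is the outcome
under study. Trials removed by trimming break sequences; episodes never
cross participants. Recycled displays are ordinary trials for sequencing.

Robust post-error slowing is ΔRT = RT(E+1) − RT(E−1) per episode,
computed only when the two trials share a trial type (the
"trial-type-specific" pairing, so type-specific RT differences do not
masquerade as slowing); mismatching episodes are skipped and counted.

Two further partitions of the distance-1 post-error trials: by whether
the five trials following the post-error trial are all correct
(insufficient or broken lookahead joins neither set), and by the
anchoring error display's deviant emotion (angry vs happy; errors on
no-target displays join neither).

## Synthetic cohort generator

The generator emulates the walk-in museum experiment: per participant a
fixed emotional-intensity level (80/90/100, randomized), 40% no-target
displays, angry/happy deviants split 50/50 at a uniform position 1–6
(the 12-display-type design implies the even split; it is configurable),
a run-until-20-correct stopping rule, and errored displays re-inserted
uniformly at random among the remaining planned displays.

Trial outcomes are drawn from the DDM with parameters determined by the
display cell and the lag state: the distance *d* since the most recent
error (any error resets the count; d > 5 means baseline). Defaults:

* **Baselines** — a = 2.874, T_er = 0.795 s (the group post-correct
  estimates); drift by trial type v = 1.06 / 0.91 / 0.55 for
  neutral / happy / angry (reproducing the observed accuracy ordering
  ≈ 95 / 93 / 83%) with a small difficulty gradient (−0.04 / 0 / +0.02
  for I80/I90/I100).
* **Post-error offsets** (reference post-error minus post-correct
  differences by distance): Δa = +0.345, +0.242, +0.308, +0.276, +0.235;
  Δv = −0.125, +0.053, +0.124, +0.107, +0.082; ΔT_er = −0.028, −0.024,
  −0.021, −0.040, −0.020 for d = 1..5 — boundary elevated throughout,
  drift dipping then rebounding above baseline, non-decision time
  slightly reduced.
* **Emotion offset** — an extra Δv at d = 1 of −0.05 after errors on
  angry displays and +0.05 after happy ones (direction from the
  reference drift contrast; magnitudes are generator choices).
* **Between-participant heterogeneity** — multiplicative lognormal
  factors on (a, v, T_er) with log-SDs (0.10, 0.25, 0.25). A walk-in
  cohort is heterogeneous, and heterogeneity is what keeps the pooled
  2σ trim from selectively censoring slow conditions (see Limitations).

RTs are emitted in milliseconds (the behavioral reporting unit) with a
50 ms floor / 60 s ceiling sanity clip that is essentially never active
at these parameters; the diffusion core works in seconds throughout.

What the generator does **not** emulate: real stimulus rendering and
timing (fixation, feedback, RSI — documented paradigm constants only),
learning or fatigue trends, gender effects, response biases (z ≠ 0.5),
and any within-participant parameter variability beyond the lag state.
Passing tests therefore show that the pipeline recovers the processes
the generator contains, not that real museum data satisfies the model.

## Estimation

All trials of a condition are pooled across participants ("group level")
and fitted by adaptive Metropolis-within-Gibbs over the scalar
parameters. A `ModelSpec` states which of {a, v, T_er} vary across
condition labels; the seven-model set enumerates every non-empty subset.
Priors are weakly-informative truncated normals — a ~ N(2, 1²) on
(0.3, 6), v ~ N(0.7, 2²) on (−8, 8), T_er ~ N(0.4, 0.35²) on (0.05, 2) —
standing for the toolbox-default literature-informed priors whose exact
hyperparameters the protocol does not state; all are configurable.

Proposal scales adapt every 50 sweeps during burn-in toward ≈ 30%
acceptance and are frozen afterwards, keeping the retained chain Markov.
Chains start from moment-based values (T_er below the fastest response,
v from the accuracy logit), jittered per chain; a guard walks T_er down
until the start has finite likelihood. Desk-scale defaults are 4 chains
× 5,000 draws with 1,000 burn-in; the production-scale 50,000/10,000 is
available through the same settings.

Diagnostics and comparison: classic Gelman–Rubin potential scale
reduction from between/within-chain variances (cross-checked against
arviz's rank-normalized version in tests); non-convergence is flagged on
the result, never silent. DIC = D̄ + pD with pD = D̄ − D(θ̄) computed
from the per-sweep total log-likelihood and the posterior mean; lower is
better, the winner is the minimum, and ties within a few DIC units are
reported as such. Posterior contrasts are simple draw fractions
P(x > y), the Bayesian posterior probabilities quoted in the tables.

## Posterior predictive checks

For each condition, the observed choice probability and the mean RTs at
the 10/30/50/70/90% quantiles (linear interpolation of order statistics,
the type-7 convention) are compared with replicates simulated from
posterior draws at the observed sample size; the predictive mean ± SD
per quantile is the "ellipse" of a quantile-probability plot.
Error-boundary quantiles are reported only for conditions with ≥ 50
observed errors (configurable stability guard).

## Test-design notes

* Recovery and model-recovery tests run at reduced problem sizes
  (1,500–5,000 trials per condition, 2–4 chains, hundreds to a few
  thousand draws) — sizes chosen so the checked effects are identifiable
  with comfortable margins while the suite stays quick.
* The end-to-end dynamics-recovery cohort is homogeneous (heterogeneity
  zeroed) and uses modulation magnitudes power-calibrated to the cohort
  size and to the measured attenuation from trimming (ΔT_er −0.09 to
  −0.12 s), so that every configured sign is identifiable; the default
  generator keeps the reference magnitudes.
* Null-safety tests use an exchangeable null: zero modulation, zero
  heterogeneity, recycling off, single difficulty, and no
  at-least-one-error participant filter (see Limitations for why each of
  these breaks exchangeability). Under a true null the posterior
  contrast probability is approximately uniform on (0, 1) — not
  concentrated at 0.5 — so the tests assert the absence of decisive
  false effects and replicate-mean closeness to 0.5, not a tight band on
  single realizations.

## Limitations and known artifacts

* **Pooling over heterogeneous participants attenuates T_er contrasts.**
  Fitting one parameter set to a lognormal mixture of participants
  compresses genuine condition differences in T_er (measured: a −0.12 s
  configured difference fits as ≈ −0.02 s at log-SD 0.25). Mirroring the
  study's own report that subject-level fits did not converge,
  subject-level hierarchy is out of scope here; treat pooled T_er
  contrasts on strongly heterogeneous data as conservative.
* **Global log-RT trimming censors slow conditions selectively.** The
  ±2σ cut removes more mass from slow, low-drift conditions (post-error
  at distance 1), biasing fitted boundary contrasts toward zero and
  non-decision time upward for the censored condition. The effect
  shrinks as between-participant variance widens the pooled bounds.
* **The paradigm is not null-safe by composition.** Error recycling
  re-presents (disproportionately hard, angry) displays after errors,
  and difficulty correlates with error frequency, so the post-error
  condition inherits a harder stimulus mix even with no parameter
  dynamics at all.
* **The at-least-one-error inclusion filter deflates post-correct
  accuracy.** Error-free participants contribute only correct
  post-correct targets; removing them (as the reference protocol does
  before diffusion fits) lowers post-correct accuracy by ≈ 2 percentage
  points under a null generator and appears as a drift contrast. The
  filter is kept in the default pipeline for fidelity; interpret small
  drift contrasts accordingly.
* Headline numbers from a production-scale (> 5,800-participant)
  dataset — episode counts, exact accuracy percentages, DIC tables — are
  not reproducible at desk scale and serve only as generator inputs and
  qualitative expectations.
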