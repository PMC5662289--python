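# Methods

## Task environment

Three slot machines each deliver one of three food items per pull, with
fixed hidden probabilities collected in a 3×3 matrix Δ (rows = machines,
columns = outcomes ordered by the *agent's* preference rank; every row on
the probability simplex). The default Δ is

    (0.6, 0.3, 0.1)
    (0.3, 0.4, 0.3)
    (0.1, 0.3, 0.6)

chosen so that both the agent and a preference-reversed observer face a
clear best / mid / worst machine ordering; it is fully overridable. A
session schedule holds 150 trials — 100 agent-observation and 50
self-choice — with pair presentations balanced within each trial kind
(each of the three unordered pairs ⌊n/3⌋ or ⌈n/3⌉ times, remainder assigned
at random) and a single seeded shuffle of the overall order.

Outcomes are indexed internally by agent preference rank (index 0 = agent's
favorite). Preference-value vectors default to (3, 2, 1) by rank. The
observer's own values are re-indexed into agent-rank space through the
condition's food-identity correspondence: identity when the agent is
*similar*, reversal when *dissimilar* (arbitrary permutations are
supported). Choice ratio is defined throughout as the number of times a
machine was chosen divided by the number of times it was offered, per
chooser; a machine never offered yields NaN, not 0.

## Agent

The observed agent is simulated, not fitted: values start at 1/3 per
machine, choice between the two offered machines is pairwise softmax
P = σ(β_a·ΔV), and the chosen machine's value follows a prediction error
V ← V + α·(code − V) on the scalar outcome code (1–3, increasing in agent
preference). Defaults α = 0.3, β_a = 3 give a stable best > mid > worst
late-session choice ordering (≈ 0.81 / 0.51 / 0.17 choice ratios averaged
over 200 seeds). The 1/3 initialization lies below the attainable 1–3 code
range; this mismatch is deliberate and preserved, because it is part of the
generating procedure being modeled. It makes the agent's early behavior
mildly perseverative (all early prediction errors are positive).

## Observer models

Shared choice rule: P(choose c over u) = 1/(1 + exp(−β·(V(c) − V(u)))),
with exploitation intensity β constrained to [2, 22] during fitting.

**Approximate inverse RL.** Beliefs Δ̄ start uniform (1/3 per cell). After
an observed choice of c over u, the chosen row is multiplied elementwise by
updating constants ε = (ε₁, ε₂, ε₃) ∈ (0, 1)³ and renormalized; the
unchosen row by the reversed vector (ε₃, ε₂, ε₁), renormalized; the
unoffered machine's row is not updated. Renormalization is required for the
rows to remain probability vectors under a multiplicative update. Self
values are V(m) = Δ̄(m)·v_s. No ordering is imposed on ε during fitting.
Note the identifiability structure: a common rescaling of ε cancels in the
renormalization, so only the ratios ε_i/ε_j are identifiable (2 effective
degrees of freedom); recovery analyses therefore summarize ε by the
scale-free spread log(ε₁/ε₃). An optional integer forgetting window
*decay* ∈ [1, 100] (disabled by default) recomputes beliefs from only the
most recent observations; it is fit by iterating the continuous optimizer
over candidate integers.

A property worth knowing: a machine that is chosen and unchosen about
equally often accumulates mass on the *middle* outcome (chosen updates
scale the row by ε, unchosen by reversed ε; balanced counts multiply the
extremes by ε₁ε₃ but the middle by ε₂², which dominates whenever
ε₂² > ε₁ε₃).

**Imitation RL.** Values init 0.5; chosen machine moves toward 1 with rate
η; on self trials every value passes through the inversion
V_self = (1−θ)·V + θ·(1−V), so the self-choice likelihood depends on the
combination β·(1−2θ)·ΔV — θ near 0.5 makes the observer blind to its own
learning, and β trades off against θ.

**cf-Imitation RL.** Additionally decays the unchosen-but-offered machine
toward 0 with its own rate η_unchosen.

**Preference-ranking learner.** A belief over the 6 strict orderings π of
the machines, initialized uniform. Likelihood of an observed choice under π
is the shared pairwise softmax on ordering scores s_π(m) = 4 − rank_π(m)
with sharpness κ (fit box [0.01, 10], log-uniform sampling in generation);
posterior by Bayes rule. Self choice uses the belief-expected score with a
condition-fixed orientation flip (+1 similar, −1 dissimilar). The score
function, κ likelihood and flip are this package's construction — only the
model's general shape (beliefs over machine rankings, softmax exploration)
was externally specified.

**Trial-wise signals.** On every agent trial the inverse RL observer emits
the agent-referential expected values Δ̄(m)·v_a of the offered machines
(before the update) and the belief-update signal
KL(posterior ‖ prior) in nats for the chosen machine's row; on self trials
it emits the self-space values of chosen and unchosen machines. These are
exported per trial as a tidy CSV for downstream GLM use. Agent-referential
trajectories are identical across conditions for a fixed agent log — the
condition enters only through the self-value mapping.

## Fitting and model selection

Per subject and session, each model's negative log likelihood over the 50
self choices (agent trials drive state but add no likelihood terms) is
minimized by L-BFGS-B inside box constraints, with 3 random interior
starting points (configurable). Per-trial likelihoods are floored at 1e-12;
inside the β box the floor is never active. BIC = 2·NLL + k·ln n with
n = number of self choices, since only those enter the likelihood. Group
comparison approximates log model evidence by −BIC/2 and applies
random-effects Bayesian model selection: a variational Dirichlet posterior
over population model frequencies (uniform prior α₀ = 1) and Monte-Carlo
exceedance probabilities (default 10⁵ Dirichlet draws). The variational
posterior is the field-standard approximation; against an exact
quadrature-based posterior for two models it agrees to < 0.01 for
symmetric, opposed and decisive evidence configurations but can deviate by
up to ~0.07 when a few subjects all weakly favor the same model — a known
property of the approximation, kept as is.

The optimizer's inner loop uses a plain-float reimplementation of each
model's replay for speed; its exact agreement with the reference observer
state machines is enforced by tests.

## Synthetic cohorts

A cohort holds 43 subjects by default (matching the included-sample size
the analysis is designed around), each with one similar and one dissimilar
150-trial session, a per-subject generating model, and ground-truth
parameters sampled inside the fitting boxes: ε components uniform(0.05,
0.95) (optionally sorted decreasing, which makes the observed choices
informative about the agent's preference ordering), η and θ uniform(0, 1),
β uniform(2, 22), κ log-uniform(0.1, 5). Per-subject seeds derive
deterministically from the master seed, so cohorts are byte-reproducible.

What the generator emulates: the trial structure, the hidden-outcome
design, the simulated-agent statistics, and observers that follow one known
strategy with fixed parameters. What it deliberately does not emulate:
human preference heterogeneity (every synthetic observer has exactly linear
values (3, 2, 1)), within-session strategy mixing or switching, lapses, and
motor/attentional noise beyond the softmax. Passing recovery tests on these
cohorts therefore demonstrates the estimator works when its assumptions
hold, not that human data were generated this way.

A consequence of the linear-value assumption worth stating explicitly: with
linear values, reversing preferences maps v_dis = 4 − v_sim, so a
dissimilar observer's choice probabilities are an exact mirror of the
similar case, and the observer's belief state depends only on the agent log,
whose distribution is condition-independent. The generative process is thus
(near-)symmetric across conditions — mean best-machine performance matches
across conditions, but so, to first order, does worst-machine performance
(measured: worst-machine dissimilar−similar ≈ −0.02 ± 0.02 at n = 600). An
asymmetric worst/mid-machine pattern between conditions requires
heterogeneous non-linear preference values (especially for the middle
item), which this generator intentionally does not include. The only
residual asymmetry channel is the agent's below-range 1/3 initialization,
and it is too weak to matter.

## Behavioral metrics

- **Referential reordering**: machines sorted best-first by true expected
  value under an actor's preference values; ties break by machine label.
- **Cohort Spearman**: rank correlation between observer self-choice ratios
  in self space and agent ratios in agent space, pooled over
  subject × machine pairs (the pooling unit is a package choice).
- **Fisher comparison**: z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3)),
  one-tailed normal p.
- **Plateau window**: late-session choice ratios from trial 76 (second half)
  by default; the plateau criterion is a package choice.
- **SI index**: both actors' choice-ratio vectors normalized to
  distributions, each reordered into its own referential space, compared by
  base-2 Jensen–Shannon divergence; SI = 1 − JSD. JSD was chosen over raw
  KL because the index must be symmetric and bounded in [0, 1] with 1 =
  identical ordered distributions and 0 = disjoint support.

## Parameter and model recovery

Recovery studies simulate subjects with parameters drawn from the generator
distributions above, refit, and correlate (Spearman) generating with
recovered values. Under these conditions ε-spread recovers well (ρ ≈ 0.85)
and θ moderately (ρ ≈ 0.74); η and β are weakly identified from 50 choices
(ρ ≈ 0.3): β trades off against the learned value contrast in both model
families, and θ near 0.5 erases the imitation likelihood's dependence on η
and β entirely. More multistarts do not change this — it is an
identifiability limit of the design, not an optimization failure.

Model recovery (inverse RL vs imitation RL, 30 subjects per generator,
well-separated decreasing ε) is clean: the diagonal exceedance
probabilities are ≈ 1.0 in both rows. With an uninformative generator
(all-equal ε, hence exactly chance-level choices) both models reach the
same likelihood and BIC's complexity penalty decides: the 3-parameter
imitation model then wins decisively over the 4-parameter inverse RL model
at the group level. This is the intended behavior of BIC-based selection on
uninformative data, not a confusion between strategies.

## Numerical choices

- Softmax exponents clipped at ±700 to avoid overflow; likelihood floor
  1e-12.
- ε fitting box [1e-3, 1 − 1e-3] (open-interval constraint made closed for
  the optimizer).
- Simplex tolerance 1e-12 on Δ rows at construction, 1e-10 on belief rows.
- KL uses the convention KL(posterior ‖ prior), in nats; zero posterior
  entries contribute zero, and a zero prior entry with positive posterior
  mass raises an error (unreachable under multiplicative updates with
  ε ∈ (0, 1)).
- Exceedance probabilities by 10⁵ Dirichlet samples (Monte-Carlo SE ≈
  0.0016 at p = 0.5).
- Problem sizes used by the shipped analyses: 43-subject cohorts for
  behavioral metrics, 20 subjects for the model-selection demonstration, 15
  subjects per generator row in the confusion study, 40–100 subjects in
  recovery studies.

## Known limitations

- The fully Bayesian inverse-RL observer (posterior over hidden outcome
  sequences with Dirichlet updating) is out of scope by design; only the
  reduced multiplicative-update form is implemented.
- The ε update is applied only on observed agent choices, never on the
  observer's own choices.
- The rank-learner's mechanics beyond its general shape are this package's
  construction; alternative likelihoods would define a different model.
- Group-level t-tests on synthetic cohorts characterize the generator, not
  human behavior; see the mirror-symmetry note above.
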