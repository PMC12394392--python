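# Methods

## The estimation problem

A trial-based experiment produces an observable sequence
Y = (y_1 … y_T) — per-trial stimulus, action, reward — generated by a
cognitive model with time-invariant parameters θ and time-varying latent
variables Z = (z_1 … z_T): z_{t+1} ~ f(z_t, y_t; θ_f), y_t ~ g(z_t; θ_g).
The classical two-step route infers θ̂ = argmax P(θ | Y) and then derives
Ẑ = f(Y; θ̂); it requires a tractable likelihood and is fragile when θ is
poorly identified. This package implements the simulation-based
alternative: train a sequence-labeling network on simulated (Y, Z) pairs
so that inference on new data amortizes to a single forward pass,
targeting Ẑ = argmax P(Z | Y) directly and sidestepping both likelihood
evaluation and parameter recovery.

## Estimator architecture

* Bidirectional GRU, 64 units per direction (configurable). The summary
  at trial t concatenates the forward pass over y_1..t and the backward
  pass over y_t..T, so the estimate of z_t uses both past and future
  observations (a smoothing, not filtering, estimator). A unidirectional
  toggle exists for causal ablations.
* Pyramidal MLP trunk on top of the 128-wide summary: two ReLU layers,
  each half the width of the previous (64, then 32).
* Output heads sharing the trunk: a linear head for continuous latents
  (mean-squared-error loss) and/or a softmax head for discrete latents
  (cross-entropy). Dual-head models use the unweighted sum of the two
  losses (weights configurable); padded trials are masked out of both.
* Training: Adam (default learning rate 3e-4, batch 128, at most 600
  epochs), early stopping when the validation loss — computed on a held
  -out 10% of training agents — fails to improve for 35 epochs; the
  weights of the best validation epoch are restored. An optional plateau
  schedule halves the learning rate after a configurable number of
  non-improving epochs; the desk-scale presets enable it because they
  trade epochs for wall time.

The network, backpropagation through time, and Adam are implemented
directly on numpy arrays; the two sequential GRU recurrences are
JIT-compiled with numba and the transcendental functions run as
vectorized SIMD calls. Analytic gradients are verified against central
finite differences (float64, relative tolerance 1e-3) for both
directions and both heads in the test suite. Weights use float32;
recurrent matrices are initialized with per-gate orthogonal blocks,
input/readout matrices with Glorot uniform, biases at zero.

## The five benchmark models

All priors below are the package defaults; every simulator is exactly
reproducible from a numpy Generator.

**Four-parameter RL (`4prl`)** — two-armed bandit with reward
probabilities 0.8/0.2 and reversal probability 0.02 per trial. Q-values
start at 0.5; the chosen action updates by the delta rule with learning
rate α⁺ when the prediction error is non-negative and α⁻ otherwise; the
policy is a softmax over βQ with stickiness κ added to the previous
action's logit. Priors: α± ~ U(0,1), β ~ U(0,10), κ ~ U(−1,1).
Observable coding [a, r]; latent: the chosen action's Q-value *before*
the trial's update, so rpe = r − Q̂ is recoverable by subtraction.

**Meta RL (`metarl`)** — the same learner gated by a 2-state hidden
Markov chain over attentive states. Engaged (state 0) uses the sticky
softmax; random (state 1) draws action 1 with a fixed bias b ~
U(0.2,0.8) regardless of value. The unchosen action forgets toward 0.5
at rate f ~ U(0,0.3). Stay probabilities ~ U(0.9,0.99) (engaged) and
U(0.8,0.95) (random); initial engaged probability ~ U(0.5,1). Nine
parameters in total. Latents: chosen Q (continuous) and the state label.
Because value updates do not depend on the hidden state, the likelihood
is exact by the 2-state forward algorithm.

**Hierarchical RL (`hrl`)** — three arrows, each pointing left/right
i.i.d. per trial; the agent softmax-samples an arrow from three arrow
values (α ~ U(0,1), β ~ U(0,10)), deterministically emits that arrow's
side, and is rewarded iff the side matches the currently correct
arrow's side. The correct arrow resamples with probability 0.03 per
trial. Only the chosen arrow's value updates, and the chosen arrow is
unobservable — computing the likelihood requires marginalizing over all
3^T arrow histories. Latents: chosen arrow (discrete) and its pre-update
value (continuous).

**Weber-imprecision task-set learner (`weber`)** — three stimuli map
injectively to four actions (24 possible mappings); the true mapping
resamples with probability 0.03 per trial and reward is deterministic
given the mapping. The agent is a noisy Bayesian observer: it holds a
belief over the 24 mappings, updates it each trial by exact Bayes
(change-hazard prediction then conditioning), and then corrupts the
log-posterior with i.i.d. Gaussian noise whose amplitude ε_t is uniform
on (0, μ + λ·d_t), where d_t is the KL divergence between consecutive
beliefs — imprecision proportional to the size of the belief update,
after Weber's law. Actions follow a mapping sampled from the sharpened
belief P(m) ∝ b(m)^η. Priors: μ ~ U(0,0.5), λ ~ U(0,1), η ~ U(1,10).
The noise lives in the *inference* process: this is what makes the
beliefs (and d_t) genuinely latent and the likelihood intractable; noise
applied only at the policy stage would leave d_t a deterministic
function of the observables and a known-θ filter would recover it
exactly, which contradicts the benchmark's premise. Stimuli are coded
as 7-wide one-hot rows; the three task stimuli occupy three of seven
slots chosen per agent, with stimulus s on the s-th smallest active
slot so the identity is recoverable from the coding.

**3-state GLM-HMM (`glmhmm`)** — two-choice perceptual task with signed
contrasts drawn uniformly from {0, ±0.0625, ±0.125, ±0.25, ±0.5, ±1}.
Each hidden state k carries a Bernoulli GLM over four regressors:
signed stimulus, bias, previous choice (±1), and win-stay-lose-switch
(previous choice signed by previous reward); history terms are 0 on
trial 1. The generator samples weights around canonical profiles —
engaged (6, 0, 0.5, 1), biased-right (1, 3, 0, 0), biased-left
(1, −3, 0, 0) — with noise scale σ (default 1). Transitions are built
as κI + (1−κ)·1πᵀ with κ ~ U(0.90, 0.97), which makes the stationary
occupancy exactly π; the skew parameter γ ∈ {−1, 0, +1} sets
π ∝ exp(γ·(1, 0, −1)). 12 weight + 9 transition = 21 parameters.

## Likelihood-dependent comparators

* **MLE / MAP** (4P-RL, Meta RL): multi-start (default 10) bounded
  L-BFGS-B on the exact log-likelihood (plus log-prior for MAP); latents
  derived by replaying the model with θ̂ (forward–backward posteriors
  for the Meta RL state).
* **Particle filtering** (HRL, Weber; known θ, per the benchmark's
  evaluation protocol): HRL particles carry the 3-vector of arrow values
  along sampled arrow histories; Weber particles carry the noisy belief.
  Both use the model's own choice distribution restricted to
  observation-consistent latents as the proposal, with the consistent
  mass as the incremental weight (the Rao-Blackwellized form of the
  bootstrap step — same filtering distribution, strictly lower variance,
  and immune to the wasted-particle degeneracy of rejection-style
  proposals), and systematic resampling when the effective sample size
  drops below half the particle count. Outputs are *filtered* per-trial
  posteriors; the network, which sees the future, is a smoother — that
  asymmetry is the point of the comparison.
* **EM** (GLM-HMM): Baum–Welch with closed-form transition/initial
  updates and posterior-weighted Newton logistic regressions for the
  per-state GLMs (ridge 1e-6 for conditioning). Initialization fits one
  pooled GLM to all trials and perturbs it per state; three restarts,
  best final likelihood kept. The likelihood is non-decreasing across
  iterations up to the ridge term. Fitted states are aligned to
  ground-truth labels by Hungarian assignment on co-occurrence before
  scoring, and one model is fitted to the whole evaluation corpus (the
  per-individual alternative overfits badly at a few hundred trials).
* **Exact enumeration oracles**: 2^T (Meta RL) and 3^T (HRL, GLM-HMM)
  path sums, feasible to T ≈ 12, used only to validate the forward
  algorithm, forward–backward, and the particle filters.

## Metrics

Per held-out agent, averaged over trials: RMSE for continuous latents;
negative log loss of the predicted state probabilities (probabilities
clipped at 1e-12); balanced accuracy (macro-averaged recall over the
states present in the ground truth) of the argmax state. Aggregation
reports mean and a 2·SD band over agents (population SD).

## Scale choices and reproducibility

Paper-scale corpora (9000/6000/22000 training agents, 720 trials, 600
epochs) are expressible through `full_scale_config` but take hours on a
CPU. The shipped desk-scale preset — 1000 training agents, 200 trials,
200 test agents, ≤100 epochs, 2000 particles — runs the complete
intractable benchmark on one CPU core; `scripts/acceptance.py` uses the
same sizes with per-model epoch budgets (150/130/130/100/130), batch 16,
learning rate 1e-3 with plateau halving. At these sizes the discrete
-state estimates are close to converged, while the continuous Q-value
heads remain optimization-limited: their RMSE keeps improving with
epochs well past the desk budget, so desk-scale RMSE overstates the
estimator's asymptotic error (the tractable-model RMSE at desk scale is
roughly the same magnitude as per-agent MLE at the same sequence
length, which bounds what any estimator can do at T = 200).

Every stage draws from `numpy.random.Generator` streams spawned
deterministically (SeedSequence) from one global seed: corpus
simulation, network initialization, batch shuffling, test-set
generation, particle filtering and EM restarts all reproduce exactly,
and test seeds are spawned from a stream disjoint from training.

## What the generator does and does not emulate

The synthetic agents hold their parameters fixed across trials, start
from neutral values (Q = 0.5, uniform beliefs), and experience
stationary task statistics apart from the scripted reversals. Real
subjects drift in engagement and learning rate within a session, have
session boundaries, and violate the model class outright; passing these
benchmarks therefore demonstrates recovery of latents *under the
assumed model*, not robustness to model misspecification. The
prior-misspecification harness probes the adjacent failure mode —
training prior ≠ test prior — but still within the correct model class.

## Known limitations

* Desk-scale training budgets leave the continuous heads underfit
  relative to the published full-scale runs (see above); the discrete
  comparisons and all ordering claims are the meaningful desk-scale
  results.
* The Weber-imprecision noise amplitude interacts with the
  deterministic reward rule: belief updates after surprising outcomes
  are large (several nats of KL), so the distance latent has heavier
  tails than in tasks with probabilistic feedback.
* The particle filters assume known θ; joint parameter-and-latent
  SMC is out of scope. For the task-set learner this makes the filter a
  very strong comparator — it does near-exact Bayesian arithmetic with
  the true noise parameters — so a desk-trained network does not
  overtake it on that model; overtaking requires the smoothing
  advantage plus far longer training.
* No uncertainty quantification on the network's point estimates.
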