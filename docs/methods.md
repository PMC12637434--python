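# Methods

## Task model

The simulator reproduces the logical structure of a head-fixed two-choice
probabilistic reversal task: within a block the designated side is rewarded
with probability `p_high` (default 0.7) and the other with `p_low` (0.1);
default block lengths are uniform on [20, 40] trials; the high side flips at
each transition. A debiasing rule holds a block open until at least 7 of the
last 10 completed choices in the block went to the high-probability side.
Two points the task description leaves open are resolved as follows: the
debias window is only evaluated once 10 completed choices have accrued in
the current block (earlier it is undefined), and the drawn default length is
kept (not redrawn) while debiasing extends a block. Timed-out trials produce
a CS− with `choice = none`; they are skipped by all model updates and do not
count toward the debias window.

Rewarded choices emit a CS+; collection of the reinforcer is modeled as an
independent Bernoulli(`collection_prob`) event per CS+ trial (the animals
occasionally forgo collection, but no mechanistic model of licking is
attempted). In the no-lick variants the reinforcer is delivered
automatically (`stim_collected` equals the reward indicator and
`t_stim = t_outcome`); in the variant without the tone the CS+ event is
absent from the neural timeline while the reward indicator is unchanged.
Event timestamps are drawn from the stated ranges (quiescent 0.2–0.5 s, ITI
4–5 s) plus configurable choice-latency and movement-duration ranges
(defaults 0.2–0.8 s and 0.15–0.35 s); the empirical latency distributions of
the rigs are not reproduced. One PCG64 stream per session, seeded
explicitly, is consumed in a fixed documented order, so sessions are
byte-identical given (config, agent, seed).

## Behavioral models

Four learners predict the per-trial probability of a right choice through a
sigmoid with an innate bias. The extended Q-learning model (CS+ as reward)
updates the chosen reward value toward 1 on CS+ trials (collected or not)
and toward 0 on CS− trials, decays the unchosen value by `gamma_forget`, and
keeps a perseveration trace `Q_stay` updated toward 1/0 for
chosen/unchosen. The printed form of the unchosen-perseveration update
references the reward value on its right-hand side; this is treated as a
typographical slip and implemented with the stay value (the flag
`literal_eq5` reproduces the literal form). The stimulation-as-RPE variant
adds `alpha_rew` to the chosen value on collected-stimulation trials
(additive, hence unbounded above — asserted by a growth test) and treats
uncollected CS+ as unrewarded via the ordinary extinction update. REINFORCE
updates a single propensity by the action prediction error with win/loss
rates and weights; the actor-critic multiplies that step by the critic's
RPE `δ = R − V`. All latent states start at 0; the propensity and critic
value initialisations are stated for V and assumed for π by symmetry.

Decision variables for neural analyses are computed off-policy over the
observed choices and outcomes and are always *pre-update* (trial t reflects
learning through t−1 only). Composite action values are
`Q = β_rew·Q_rew + β_stay·Q_stay`; relative value is their right−left
difference; state value follows `δ = R − V`, `V ← V + α_rew δ`. Laterality
follows the recording convention (left hemisphere: contra = right choices).
Slowly learned values drift across a session, so every variable entering an
encoding or decoding model is first detrended by OLS on trial number.

## Fitting

Per-session fits are MAP estimates in a latent space: rates pass through a
log-odds transform, weights are untransformed, and every latent coordinate
has a Normal(0, 1) prior (the weakly informative default; configurable).
L-BFGS runs from 10 random restarts (the first at the origin). Accuracy is
defined — because no standard definition exists — as the fraction of trials
where the model assigns the observed choice probability > 0.5, ties counted
as 0.5. Likelihood contributions are clipped to [1e−9, 1−1e−9]. Laplace
standard errors from a finite-difference Hessian diagonal are available on
request.

The hierarchical fitter models each parameter at population
(`μ_k, ln σ_k ~ N(0,1)`), subject (`θ_{k,i} ~ N(μ_k, σ_k)`) and session
(`ψ_{k,i,j} ~ N(θ_{k,i}, s_{k,i})`, `s` uniform on (0, s_max]) levels and
samples the joint latent vector with emcee's affine-invariant ensemble;
split-R̂ per coordinate comes from arviz with walkers treated as chains.
The desk-scale default (600 steps, 200 burn) is sized for smoke-level
problems; converged inference at the reference scale (4 × 1850 iterations in
a gradient-based sampler) requires raising `n_steps` until all R̂ < 1.01,
and the summary flags when that bound is not met.

Held-out model comparison uses blocked cross-validation: the session is cut
into contiguous folds, parameters are fitted on the remaining trials (the
state scan still runs over the whole session, so values stay sequential),
and held-out choices are scored. In the confusion analysis a model claims a
simulated session outright only when its held-out log-likelihood beats a
competitor's under a fold-level paired t-test (5 blocked folds, α = 0.05) —
the standard way to compare cross-validation scores without pretending
held-out errors are independent; statistically tied models share the win.
Plain argmax is available (`tie_split=False`) but rewards the most flexible
family for margins of ~0.003 nats/choice, an order of magnitude below the
fold-level noise. Generators for recovery and confusion studies are fitted
to a common reference session whose predictability matches the animals'
(≈ −0.48 log-likelihood per choice, ≈ 77% accuracy), since
distinguishability depends strongly on how deterministic behavior is.

The κ refit frees the target of CS+-without-stimulation updates (prior
N(0, 1)) while CS+-with-stimulation keeps target 1; only sessions with at
least 5 uncollected-CS+ trials are informative and others are excluded. At
desk scale κ is estimated by MAP with a Laplace standard error; estimates
discriminate κ = 1 from κ = 0 cleanly but carry upward bias of order 0.3
when the value weight is strongly shrunk by the prior — the test asserts
discrimination, not unbiasedness.

## Synthetic neurons

Ground-truth neurons are built from the same bilinear form the encoder
fits: unit-norm raised-cosine-mixture kernels per event, per-trial gains
affine in the value variables, and the *same* kernel-placement code path
used to build the design matrix, so ground truth lies exactly in the model
span and noiseless Gaussian fits can recover it. Gaussian mode adds iid
noise to the latent signal and is used for recovery and calibration studies
(it matches the Gaussian-error model actually fitted to z-scored counts);
Poisson-log-link mode emits integer counts for realism. Spike-history
feedback in generation is off by default (fitting includes the history
kernel regardless). Default noise (σ = 1 for calibration populations,
0.4–0.8 for recovery and decoding populations) and gain scales (0.5–0.6 on
composite-value variables, 2.0 on the lower-variance reward-only values)
were chosen so corrected ΔR² falls in the ~0–0.05 range and peak corrected
decoding R² in the ~0.1–0.5 range reported for striatal populations; this
is a convenience for realism, not a claim about any recorded neuron.

Synthetic wheel traces embed a half-cosine displacement ramp at each
trial's movement time — the speed profile crosses the 0.2 cm/s precise
threshold within a few milliseconds of the true onset, so detector accuracy
can be asserted at ±20 ms. Position noise defaults to zero because a rotary
encoder reports quantized positions; white position noise at 1 kHz would
alias into cm/s-scale speed noise that no real rig produces.

## Encoding model

Spiking is binned at 10 ms on a per-trial grid aligned to the go cue
(default −0.5 s to +3.5 s; the studies use +3.2 s, which still covers every
kernel window), z-scored over kernel-covered bins only, and fitted over
those covered bins. Event kernels use one raised cosine per 25 ms of span
(go 0–1 s → 40; movement −0.5–0.5 s → 40; CS+/stimulation/CS− 0–2 s → 80),
tiling the span as a partition of unity; the parameterization (centers
linspaced over the span, half-support twice the spacing) is exposed as
config since only the tiling property is specified. The history basis is 10
raised cosines log-spaced over 10 ms–1 s, lagged ≥ 1 bin so the current bin
never predicts itself; convolutions are confined within trials and
truncated at grid edges. Event times snap to the nearest bin edge, exact
ties toward the earlier bin.

The kernel stage is a lasso over the sparse event design plus dense history
columns; the gain stage is a ridge over 18 predictors (6 kernels × (offset
+ 2 value variables)) with the intercept and history contribution entering
as fixed offsets. Both penalties are selected by 5-fold cross-validation
(folds stratified by block side × choice × outcome, remainder round-robin)
over a log-spaced grid from 1e−5 to 1e5 — 251 values by default, 17–51 at
desk scale — on the first iteration and then frozen; kernels are
renormalized to unit Euclidean norm each iteration (the scale moves into
the gains), and the loop stops when every coefficient changes ≤ 0.001 for
three consecutive iterations, or at 100 iterations. The ridge penalty path
is computed by eigendecomposition of the per-fold Gram matrix — numerically
identical to refitting sklearn's Ridge at every penalty (asserted in
tests) but cheap enough to re-select the penalty inside every null refit.

Nested-model significance uses `F = (ΔSSE/ΔDOF) / MSE_full` computed on
pooled 5-fold held-out predictions (per-fold vs pooled residuals is
unspecified; pooled is implemented); held-out F can be negative and is
reported as-is. Event-kernel tests compare against 200 circular shifts of
the binned activity, drawn uniformly from [L/10, 9L/10] bins to exclude
near-zero shifts, with penalties frozen at the real fit's values.
Value-gain tests compare against pseudosession surrogates: contiguous
chunks from a pool of other sessions' value series, detrended like the real
series, shared across neurons, with the ridge penalty re-selected
independently for every full and reduced model — real or null.

Three conditions must hold for the pseudosession test to calibrate, and
each failed measurably before being fixed:

1. *Kernel freezing.* If the comparison stage freezes the kernels from the
   *final* bilinear iteration, the test is severely anticonservative
   (≈ 50% of value-blind neurons flagged at the 1% level in our studies):
   across iterations the kernels absorb noise-gain structure aligned with
   the real value series, so a gains-only refit favors the real series
   over any null. The comparison stage therefore freezes the
   *iteration-1* kernels, which are fitted with all gains at 1 and have
   never seen the value series; real and null refits are then
   exchangeable by construction. The converged kernels and gains remain
   the reported estimates; `stage="final"` reproduces the final-kernel
   comparison. The fully symmetric alternative — refitting the entire
   bilinear model for every null — would also be exchangeable but costs
   two hundred full fits per neuron.
2. *Extraction order.* Value trajectories are extracted by running the
   model over the full session and then restricting to analyzed trials.
   Extracting from an already edge-filtered session re-initializes values
   at zero, giving every real series an early-learning transient that
   mid-stream pseudosession chunks do not have — a distributional
   asymmetry that inflates the false-positive rate. Pool sessions get the
   identical treatment.
3. *Pool size.* The pool must be large relative to chunk length × null
   count. With a 4-session pool, 100 chunks of a 60-trial session overlap
   almost completely; the effective null ensemble is a handful of
   segments, the tail of the null F distribution is under-sampled, and
   strict thresholds fire too often. The packaged studies build pools
   from 60 simulated sessions.

With all three in place, a 100-neuron rank-uniformity study gives exactly
the nominal rates (1% at p ≤ 0.01, 5% at p ≤ 0.05, uniform p histogram)
and mean corrected ΔR² ≈ 0. One further property matters for
interpretation: all neurons of one session share its value series and null
draws, so their flags are correlated and a single-session study's
false-positive count is over-dispersed relative to binomial; the
calibration study therefore spreads its neurons over several independent
sessions. The empirical p is the plain fraction of null F above the real
F, so with N nulls its smallest achievable level is conservative-free at
(k+1)/(N+1) — at 100–200 nulls the expected rate at the 0.01 threshold is
1.5–2%, not 1%.

The learning/forgetting-rate sweep recomputes reward-only action values on
a 40-point grid over [0.025, 1], detrends them, refits gains with kernels
frozen (penalty re-selected per grid value), and reports corrected ΔR²
curves; pseudosession chunks share their start positions across the grid,
with the pool's series recomputed at each grid value. Because detrending
removes most of the variance of very slow value series, the recovered
curve is mildly skewed toward rates above the generative one; replicate
averaging keeps the peak within the tested ±0.15 of the truth.

## Decoding

A separate lasso decoder is trained per 100 ms bin (state value: −0.5 to
+2 s around outcome on rewarded trials; relative/action values: ±0.5 s
around the go cue on contralateral — or ipsilateral for the ipsi action
value — choice trials; targets are always pre-update values). Nested
stratified 5×5 cross-validation stratifies trials by Freedman–Diaconis bins
of the target (width `2·IQR·n^(−1/3)`, bins with fewer trials than folds
merged with their nearest neighbor; zero IQR collapses to plain shuffled
folds); the inner loop selects the penalty from the 8-point grid
{1e−6…1e1}. Reported R² is raw minus the mean over pseudosession-target
decoders; negative values are reported, not clipped. Null decoding runs
default to 20 surrogates at desk scale (each is a full nested-CV run); the
reference protocol's 200 is a parameter away.

## Problem sizes and runtime choices

The packaged studies run end-to-end on one CPU: calibration uses 40–45
task-modulated neurons on an 80-trial session (60 after edge exclusions)
with 100 shared pseudosession nulls; gain recovery uses 12 value-coding
neurons; the timescale sweep averages 30 replicates of 130-trial sessions
(forgetting-rate sweeps reuse the first 10 replicates' sessions and
neurons for a matched flatness comparison); behavioral recovery uses 40
sessions of 500 trials; confusion uses 10 sessions per generator of 500
trials. Desk-scale encoding fits use the same penalty ranges with coarser
grids (13–51 points per penalty) and a capped coordinate-descent budget;
the full 251-point grids remain the configured default.

## What the synthetic studies do and do not show

The generator emulates the task's block logic, on-policy choice behavior,
and bilinear value-gain spiking with stationary Gaussian noise. It does not
emulate electrode drift, non-Poisson bursting, correlated population noise,
multi-neuron latent dynamics, session-boundary nonstationarity, or any
relationship between real striatal subregions and value coding. Passing
tests therefore demonstrate that the pipeline is correct and calibrated on
data satisfying its own assumptions — they do not certify effect sizes or
regional percentages in recorded tissue. Known limitations: MAP fits shrink
extreme weights (visible as κ bias above); the desk-scale ensemble MCMC is
a contract-compatible stand-in for long-chain gradient-based sampling; and
the confusion analysis' tie-splitting threshold (α = 0.05) is a
conventional choice, not derived from the task.
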