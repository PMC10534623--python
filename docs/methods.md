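# Methods

This note documents the model implemented by `birdtrack`, the assumptions it
makes, the parameters that matter, and the design choices taken where the
design was genuinely open.

## Problem setting and state-space model

A single bird flies in the horizontal plane and is observed by a scanning
sensor at a fixed interval Δt ∈ [0.1, 5] s.  Altitude is ignored: bird flight
changes slowly in the vertical and only horizontal tracking suffers from the
low refresh rate.  Each scan yields one or more candidate points; at most one
is the target, the rest are false alarms caused by background noise, occurring
in at most a few percent of scans (rate `p_fa ≤ 5 %`).

The state is `X = [x, vx, y, vy]` (metres, m/s; this ordering matches the
block structure of the CV/CT transition matrices).  The sensor measures
position only; observed velocity is the backward difference of successive
observed positions divided by Δt.  The measurement is therefore the full
4-vector with `H = I`, but its velocity components are deterministic functions
of the position noise — which is why densities are evaluated on the position
marginal by default (below).

Position noise per axis is `N(0, 4 δl²)` with `δl` the sensor's range
resolution (0.5–3 m regime, default 1 m).  `δl` in reality depends on the
target-sensor distance; no geometry is modelled, so it is held constant per
run and configurable.

## GRU motion models

Each motion model is a stacked bidirectional GRU regressor:

* input: `L = 7` rows of `concat(X̂_k, Z_k)` (8 features), oldest to newest;
* hidden: `M = 2` stacked bidirectional layers, 32 units, forward/backward
  features combined per step by element-wise sum (the combined per-step
  features feed the next layer); dropout 0.1 between stacked layers only;
* head: the **last** time-step's top-layer feature through affine + tanh.
  (Pooling the whole sequence into the head is a reasonable alternative;
  seq-to-one with the last step is the convention adopted.)

Feeding both the estimate and the raw measurement lets the network weigh a
possibly contaminated measurement against the filtered history.

The networks, backpropagation through time and the optimiser are written
directly on NumPy arrays in float64.  Gradients are verified against central
finite differences in the test suite.  All initialisation, shuffling and
dropout draw from a seeded generator, so training is bit-reproducible.

### Normalization

The network never sees absolute coordinates.  Within a window, positions are
displacements from the newest estimated position divided by
`pos_scale = v_max · L · Δt_max`, and velocities are divided by
`vel_scale = v_max`, with `v_max = 30 m/s` a generous bird-speed bound and
`Δt_max` the model's interval-bin ceiling.  Targets are normalized
identically.  This makes the model translation invariant and keeps all inputs
and targets well inside the tanh head's (−1, 1) range (one-step displacements
are at most `1/L` after scaling).  The scheme is invertible given the
reference state, which is how absolute predictions are recovered.

### Training protocol

The interval range [0.1, 5] s is partitioned into contiguous bins on the
0.1 s grid — five bins give {[0.1, 1], [1.1, 2], [2.1, 3], [3.1, 4],
[4.1, 5]} — and one model is trained per bin on windows cut from trajectories
downsampled to every interval in the bin.  Δt itself is never an input
feature; specialisation comes entirely from the data.  Model 1 (smallest
intervals) learns the slowest motion change per step, model 5 the fastest.

Teacher forcing: during training the estimate channel holds ground-truth
states *at scan scale* (i.e. with differenced velocities, the only velocity a
tracker ever has) and the measurement channel holds the noisy observation; the
target is the next true state.  Closed-loop estimates appear only at tracking
time.  Training adds no false alarms — association is the tracker's job, and
contaminating the regression targets would teach the models to hedge.

Optimisation: MSE loss, batch 256, Adam at learning rate 0.01 under a cosine
annealing schedule restarting every 5 epochs, early stopping when the
validation loss has not improved for 20 epochs, returning the
best-validation weights.  Weight decay is decoupled (AdamW-style) with
default `1e-2`.  A much larger decay coefficient is incompatible with this
normalization: targets have magnitude ~0.1, so MSE gradients are small and an
aggressive decay term dominates them, pinning the weights near the origin
(measured: decay 0.5 yields a model several times worse than the analytic CV
predictor, in either the decoupled or the coupled-L2 convention).

Windows start at the second resampled sample of a track, because the first
sample's differenced velocity is fabricated (copied from its successor).

## The tracking cycle

Per scan, with interval `T` since the previous scan:

1. **Prediction.**  Every model predicts from its *own* estimate history and
   the *shared* measurement history (each model's window reflects its own past
   predictions; the selected measurements are common).
2. **Stand-in transition.**  A point prediction supports no covariance
   propagation, so the transition is approximated by the convex blend
   `F = α F_CV + (1−α) F_CT(Ω)`, with α minimising `‖F X̂ − X_pred‖²` in
   closed form on [0, 1].  Degenerate case `F_CV X̂ = F_CT X̂` (stationary
   target or Ω = 0): α = 1, the simpler model wins the tie.  Ω is estimated
   from the wrapped heading change of the model's last two estimates
   (near-zero speeds carry no heading: Ω = 0); a joint grid search over
   (α, Ω) would be the alternative, at more cost for little benefit in
   testing.  Then `S_pred = F S F^T + Q`, symmetrised.
3. **Gating.**  Candidate points are scored under the predictive mixture
   `Σ_j μ^j N(z; H X^j_pred, H S^j_pred H^T + R)` and the argmax wins (ties to
   the lowest point index).  Two deliberate deviations from the bare
   formulation: the spread uses the standard innovation covariance
   `H S H^T + R` (using the state covariance alone would ignore measurement
   noise; adding R only widens gates, which is safer), and the density is the
   2-D position marginal — differenced velocities are deterministic functions
   of the position noise, so a 4-D density with a diagonal R would count the
   same noise twice.  Full 4-D evaluation is a config switch (`gate_4d`).
4. **Update.**  Standard Kalman correction per model; singular innovation
   covariances are regularised with `1e-9·I` and logged.
5. **Re-weighting.**  `μ' ∝ likelihood · μ` with the *predictive* likelihood
   `N(z; H X_pred^j, H S_pred^j H^T + R)`.  (Centring the likelihood on the
   posterior with the posterior covariance is circular — the measurement
   produced the posterior — and is not done.)  A probability floor
   (default `1e-3`, applied after normalisation, then renormalised) keeps
   every model recoverable; floor 0 lets the Bayes product saturate to
   machine precision, which is the configuration used for the single-regime
   saturation experiment.  If every likelihood underflows to zero the weights
   pass through unchanged.  No Markov model-transition mixing is applied
   between steps (the update is pure Bayes); a mixing matrix exists but is
   off by default.
6. **Combination.**  Combined prediction `Σ μ_k^j X^j_{k+1/k}` (weights
   *before* seeing the new measurement, matching its role as a prior
   forecast) and combined estimate `Σ μ_{k+1}^j X̂^j_{k+1}`.

**Warm start.**  The recurrent models need `L` history pairs, so the first
`L + 1` frames are consumed single-point by a CV Kalman filter initialised
from the first point with covariance R.  Its estimates fill every model's
history; initial weights are uniform.  All metrics exclude these warm-up
steps for every method.

**Degenerate frames.**  A frame with no admissible measurement carries the
combined prediction forward as a pseudo-measurement with R inflated 10×,
logged.  (The simulator always emits at least one point, so this path guards
against upstream filtering only.)

### Noise covariances

`R = 4 I` matches the ~2 m position noise of the default `δl = 1 m`.
`Q = 16 I` deliberately distrusts the process model so the filter re-converges
quickly after unmodelled manoeuvres — the cost is wider gates, not bias.

## Back-tracking correction

A false alarm that wins the gate contaminates the next `L − 1` windows.  The
correction keeps up to `D' = 2` association hypotheses alive for exactly one
scan: every (hypothesis × gated candidate) pair advances one full tracker
step, children are scored by the sum of log gate densities over the last two
steps (older terms are shared by all live hypotheses and cancel in
comparisons; summing them anyway would only drift the score scale on long
tracks), the best child becomes the primary — possibly descending from an
alternative, which revises the previous association — and the beam refills
with the primary's siblings, so live hypotheses always agree on everything
older than one step.  Look-back deeper than one step would chase events of
probability below `p_fa²` (≤ 0.25 % at the 5 % ceiling) and is not done.

**Gate threshold η.**  Points are kept while their mixture density is ≥ η
(keeping *high*-density points is the only direction consistent with the
mechanism: a large η must reduce, not enlarge, the candidate set), at most
`D'` of them; if none passes, the constraint is relaxed to the single argmax.
η lives on the same scale as the gating density (m⁻² for the position
marginal).  On this package's scale, typical *true-point* densities are
median 3·10⁻³ at Δt = 1 s down to 2·10⁻⁶ at Δt = 5 s under the default Q and
R — so a threshold as high as 10⁻² would never pass any point, the relaxation
would fire every step, and the correction would silently degenerate to the
plain tracker (exactly the "large η" failure mode).  The default is
`η = 10⁻⁶`: alternatives within roughly 3–5 innovation σ of the prediction
survive, remote false alarms do not.  With it, at Δt = 3 s and 5 % false
alarms, the correction cuts the false-detection ratio by an order of
magnitude and lowers estimation RMSE on matched seeds (both verified by
paired tests in the suite).

## Baselines

All baselines consume the same frames, use the same warm-up exclusion and a
simple nearest-to-prediction gate, and never use the back-tracking correction.

* **UKF** — Merwe sigma points, spread (1e-3, 2, 0); default dynamics is a
  coordinated turn with the turn rate augmented into the state
  (`[x, vx, y, vy, ω]`, ω a random walk of intensity `q_ω = 10⁻² rad²/s³`).
  A linear CV configuration exists; the unscented transform is exact there,
  which the suite exploits to check the UKF against a Kalman filter.
* **IMM-UKF** — model set {CV, CT(+0.2), CT(−0.2) rad/s} with Markov
  self-transition 0.9: standard interaction (mixing), per-model filtering,
  likelihood re-weighting.  The model set and transition matrix are free
  parameters of the comparison, not prescribed by anything.
* **PF** — bootstrap filter, 1000 particles by default, CT dynamics with
  random-walk turn rate, Gaussian measurement likelihood with R, systematic
  resampling when the effective sample size drops below half; weight
  degeneracy re-initialises around the last measurement, logged.
* **GRU-EKF** — structurally the bank tracker with a single larger model
  (8 layers, hidden 128) trained on the full 0.1–5 s range; its weight trace
  is constant at 1.

## Synthetic data: what it does and does not emulate

The generator produces piecewise CV/CT/CA trajectories with exact closed-form
kinematics, continuous position and heading across joins.  Defaults mimic
pigeon-like flight: speeds 10–20 m/s, |turn rate| ≤ 0.5 rad/s, segment
durations 5–60 s, 0.1 s base sampling.  Observation reproduces the scanning
sensor: downsampling to Δt, `N(0, 4δl²)` position noise, differenced
velocities (first frame copies the second — no backward difference exists),
and with probability `p_fa` one false point, uniform in a disc (default
radius 100 m) around the true position — near enough to confuse association.
A false point's velocity channel is differenced against the previous frame's
noisy true position, since the simulator cannot know which point a tracker
selected; no false alarm is injected at frame 0.

Not emulated: altitude, flocking interaction (each run tracks one bird),
photon-level sensor physics, terrain, range-dependent δl, and real pigeon
idiosyncrasies (thermalling, landing approaches, speed-turn coupling).
Passing tests therefore demonstrate the *mechanism* — regime identification,
gating, correction, degradation with Δt — under controlled kinematics, not
performance on any particular real dataset.

## Numerical choices

* Densities: Cholesky-based Gaussian evaluation; singular covariances get
  `1e-9·I`, logged.  Log-densities floor the argument at 1e-300.
* Covariances are symmetrised (`(A+Aᵀ)/2`) after every propagation/update.
* Ties in gating break to the lowest point index; candidate ranking is
  stable under equal densities.
* `ct_matrix` switches to the analytic CV limit for |Ω| < 1e-8.
* Seeds: every stochastic component takes a `numpy` Generator or integer
  seed; experiment replicates spawn from a single `SeedSequence`.

## Problem sizes

The suite trains its shared five-model bank on 8 synthetic trajectories of
240 s (≤ 1200 windows per bin, epochs capped at 120) — small enough for a
laptop-scale run while preserving every qualitative property; the acceptance
script trains at 2000 windows per bin with a 200-epoch cap.  Monte-Carlo
comparisons use 120–200 matched-seed replicates (50 per interval for the
degradation curve); reported differences carry paired tests or standard
errors.  Larger runs (the 500-replicate grids) are exposed through
`ExperimentSpec` but are not the defaults.

## Known limitations

* The bank's quality, and every comparison involving it, depends on the
  synthetic training distribution; no claim transfers to real telemetry
  without retraining.
* The approximate transition blends only CV and CT; constant-acceleration
  motion exists in the simulator but deliberately not in the tracker's
  stand-in family.
* Multi-target association, track initiation/termination, and arbitrary-depth
  multi-hypothesis trees are out of scope.
* The η threshold is an absolute density and therefore scale-dependent; a
  Mahalanobis-level gate would be scale-free but is not what the mechanism
  specifies.
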