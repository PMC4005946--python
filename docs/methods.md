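# Methods

This note documents the model as implemented: its equations, the choices
made where the design was open, the numerical machinery, and what the
synthetic tasks do and do not establish.

## Rate units and maps

All populations are locally-projected leaky integrators: the Euler update
`x(t+dt) = clip(x(t) + dt/τ (I(t) − x(t)), 0, max)` (dt = 1 ms throughout)
keeps every activity inside its box for arbitrary bounded inputs and makes
trajectories contracting, which the test-suite verifies directly. Visual
structures are 70×70 sheets per hemifield (36×36 in the desk-scale
preset) under the complex-log mapping of the macaque colliculus,
`u = Bx ln(√(R² + 2AR cosθ + A²)/A)`, `v = By atan2(R sinθ, R cosθ + A)`
with A = 3°, Bx = 1.4, By = 1.8 scaled onto the grid (the cited mapping
names the constants' roles; the values are the standard macaque fit and
are configurable). Stimuli are Gaussian blobs (σ = 1.9 cells, ~100 units
above 1 % of peak on the reference grid). The blob width is fixed in grid
cells, not degrees, so the coarse-channel geometry that the selection
circuit sees is the same at both resolutions.

Sensory delays are pure transport delays: 41 ms to the superficial
colliculus, 91 ms to FEF, 122 ms to the colour pathway. Because stimuli
are piecewise constant within a trial, the task runner implements the
delay by indexing the scene schedule at `t − latency`; an explicit
`DelayLine` with identical semantics is provided and tested.

## Selection circuit

One basal-ganglia circuit instance competes N channels (648 coarse spatial
channels = 2×18×18, or 3 colour channels). Populations: D1 and D2
striatum (per-channel), a fast-spiking interneuron pool (diffuse,
saturating), STN (per-channel, diffusely projecting), GPe, and GPi|SNr.
Focused striatal D1 inhibition pulls the winner's GPi below its tonic rest
level; summed STN excitation holds every other channel at or above rest.
With no input the circuit relaxes to `GPi_rest` on all channels.

All internal gains are free parameters of this implementation; they were
tuned by randomized search against a behavioural contract, mirroring the
hand-tuning procedure such selection circuits are normally calibrated
with: a lone Gaussian target of amplitude 0.6–1.0 is selected, amplitude
0.1 is not, distractors ≤ 0.85 do not disturb a full winner, and
1.0-vs-0.95 (the perceptual-noise contrast) resolves to the winner only,
at the 648-channel, 162-channel and 3-channel instantiations alike. Two
deviations from a textbook reading were necessary:

* **Diffuse normalisation.** Scaling the STN one-to-all gains by 1/N
  makes the surround vanish for blob inputs (mass ~5 channels out of
  648). Instead the diffuse drive uses straight sums with a
  resolution-calibration multiplier (`diffuse_norm`) such that the drive
  per standard stimulus is grid-independent, and the colour circuit
  carries its own diffuse gains (its "stimulus" is one channel of mass 1).
* **Diffuse saturation.** The summed STN drive is capped (`stn_sum_max`)
  so that pathological all-out co-activation cannot push the output
  nuclei into a global collapse; the cap sits above every legitimate
  competition regime.

Selection latency is made salience-dependent by a cortico-striatal input
stage: the circuit tracks a low-pass filtered salience (τ = 30 ms;
52 ms in the reduced preset as a resolution calibration, 20 ms for the
three-channel colour input). Strong salience collapses GPi within
~10–20 ms, marginal salience takes 60–100 ms — the substrate of the
express/regular latency contrast.

## Loops

The colour loop sums each V4 colour map into one channel (normalised so a
full blob ≈ 1), competes the three channels, and amplifies the winner
through an IT↔thalamus loop whose gain exceeds unity only under
disinhibition; the cortical output is loop-dominated (feedforward gain
0.25), so an unselected colour passes only weakly. The selected colour is
projected back by scaling each max-normalised input map with its channel
output. The colour-striatal input is divisively normalised by its peak
(when > 1), so the circuit always competes relative saliences in its
calibrated range no matter how large the learned weights grow.

The FEF loop is the retinotopic version of the same motif. Its input map
(91 ms luminance) and the collicular thalamus map are pyramid-reduced
(two stages of normalised 5×5 binomial smoothing + 2×2 mean binning;
70 → 72 by zero padding → 18), rescaled so a standard blob keeps a coarse
peak of ~1, thresholded at 0.05 (tonic baselines carry no salience or
eligibility), concatenated, actor-weighted, merged by the steep sigmoid
`f(x) = 1/(1 + e^{15(0.95−x)})`, and fed to the shared spatial circuit
together with a weak raw copy of the reduced FEF input (so an untrained
model still selects). The same pallidal release gates both the FEF and
the collicular thalamo-cortical gains — the shared circuit is what lets
subcortical selection ignite frontal activity before the frontal visual
volley arrives.

The deep colliculus sums its three afferents (retinal 0.65, FEF output
0.8, colour-selected V4 1.8 — the heavy V4 weight makes the late colour
volley the decisive event for an untrained selection) under a
multiplicative release gate (base 0.3 + 2.0 × disinhibition). The
expanded release map (pyramid transpose: 2×2 replication + smoothing,
rescaled to preserve the coarse selection amplitude, widened ×1.4 so the
gated motor footprint covers the stimulus blob) also gates the motor
projection via the nigral term (gain 2.0 ≈ 1/rest: at rest the motor
path is fully closed).

## Motor stage

Motor-map drive = SCi × (1 − 2.0·SNr) × (1 − Sat) − 0.6·OPN − 3·Sat².
The omnipause unit is a latch: tonically 1, strongly inhibited by summed
motor activity, so a supra-threshold burst unlocks itself. Eye velocity is
the motor-activity-weighted sum of per-unit displacement vectors (inverse
complex-log mapping), scaled by `burst_cal·sat_rate/blob_mass`; the
saturating terminator integrates total motor activity and both chokes the
burst multiplicatively and kills it subtractively once engaged. This
makes total displacement track the population vector independently of
burst vigour: amplitude error is < 1 % for imposed activity from 2° to
30° at both grid scales, and < 10 % in closed loop. `burst_cal` was
calibrated once against closed-loop trials. Saturation is exported as the
saccade-execution signal that (partially) gates every visual input —
partial (0.5) on the collicular side, so the burst is not choked by its
own gating; full on the cortical side.

## Learning

Per 1-ms step: `V_t = clip(w·û_t, 0, 1)` with `û` the peak-normalised
input (both guards keep the value calibrated as learning amplifies the
raw input); `δ = R + γV_t − V_{t−1}` with γ = 1 (the undiscounted return
of a trial is its single terminal reward; with near-static inputs a
linear value cannot represent an exponentially discounted ramp, and any
discount then leaks a systematic negative error that erodes learned
behaviour); critic traces `E ← λE + û_{t−1}`, λ = 0.99 — large enough to
bridge the delay from selection to reward. The actor applies `A = W·u`
(identity start, diagonal floored at 0.6, off-diagonals ≥ 0, ceiling 8)
and accumulates `E_W ← αE_W + credit_{t−1} ⊗ u_{t−1}`, α = λ. The credit
vector is the clamped pallidal release `1 − GPi/GPi_rest`, rescaled so
that only substantially released channels (> 0.5) carry credit; taken
literally as raw pallidal output, credit would flow to the channels that
were *not* selected, which cannot produce the observed learned maps (the
literal variant remains available behind `credit="gpi"`).

Updates run every step until the choice is detected (eye leaves the
2.5° circle); the outcome's reinforcement then applies, as a terminal
error `δ = R − V`, to the eligibility accumulated up to the choice. The
saccadic tail is excluded: during it the gated inputs collapse, and
crediting that collapse systematically punishes successful choices.
Traces reset between trials. For efficiency the actor's per-step
recursion is committed once per trial by an exact backward pass
(`TrialAccumulator`); the equivalence with the per-step loop is tested.

Rates: spatial actor 2·10⁻³, colour actor 1·10⁻³, spatial critic 1·10⁻⁴,
colour critic 3·10⁻⁴. Their ratios set where learning equilibrates (the
actor grows while the value still under-predicts reward): they were
chosen so the spatial task converges within the first quarter of a run
and its weights settle near a collicular-portion column-sum peak of ~5,
and so colour preference saturates at a level where the colour loop wins
most—but not all—races against an intense spatial distractor. The huge
difference in weight counts between the modules (≈1.7 M spatial vs 9
colour) is what motivates separate per-module rates at all.

## Tasks and protocol

Timeline per trial: 50 ms black, 800 ms central fixation (luminance-only,
intensity 0.7 — it drives the retinal and frontal maps but no colour
map), a 150–250 ms uniform random gap, then two cues at ±10°, one red and
one green (sides randomised), intensities 1.0/0.95 (assignment
randomised), for at most 600 ms. A saccade is the first eye excursion
beyond 2.5°; the simulation continues 80 ms so the burst finishes, the
landing point is classified against the cues and the centre circle
(radius 2.5°), reward follows the task rule, and all dynamic state is
reset for the next trial (a fresh fixation; thalamic maps start at their
tonic fixed point so trials do not open with a map-wide transient).
Classification is exhaustive and mutually exclusive: correct /
spatial error (good colour, wrong side) / colour error (good side, wrong
colour) / good or bad average (landing or staying within the centre
circle) / bad saccade / no saccade. In the conjunction-present case a
saccade to the double-wrong cue counts as a spatial error if it has the
rewarded colour, otherwise as a colour error.

The only random quantities are the gap duration, the cue layout, the
noise assignment and the critic initialisation; experiments are
bit-reproducible given a seed.

## Problem sizes

The full protocol is 40 sessions of 12 trials; learning converges well
inside it. The desk-scale preset (36×36 maps, 9×9 coarse channels)
reproduces the behavioural results at about a third of the cost. The
acceptance script uses: 3 seeded desk-scale runs per task (28 sessions
for the colour task, whose asymptote is slower; 14 and 20 for the spatial
and conjunction tasks), one 15-session full-resolution spatial run for
the reaction-time structure and weight summary, a 14-trial frozen-weight
probe pair for the inactivation effect, and 14 untrained full-resolution
trials for the pre-learning reaction-time mode.

## What the synthetic tasks show — and what they do not

The tasks exercise exactly the structural claims: latency-ordered
pathways, shared spatial selection, colour selection in a non-spatial
channel space, reward-driven re-weighting at the BG input. They do not
emulate realistic visual scenes (two isolated Gaussian cues only), eye
movements during fixation are not gaze-contingent (the retinal picture is
not re-rendered after the saccade; trials end right after it), and
burst kinematics are schematic (durations in the tens of ms, no main
sequence). Conclusions about *relative* latencies, dominance between
loops, and learned-weight structure transfer; absolute millisecond values
depend on the free time constants, which were tuned to place the
untrained and trained reaction-time modes near 200 and 88 ms.

## Known limitations

* Learning converges to the spatial rule faster than over half the
  protocol, so early-experiment reaction times blend regular and
  intermediate latencies rather than holding a clean 200 ms mode until
  midway.
* In the conjunction task the spatial side-bias develops more weakly
  than the colour preference (the spatial circuit commits last, so its
  credit window at the choice is the shortest); side errors therefore do
  not vanish entirely in the no-conjunction case.
* The frontal portion of the learning input also gains weight during
  spatial learning (peak ~2 vs the collicular ~5), a milder contrast
  than the idealised one.
* Averaging saccades between simultaneously selected targets are
  weighted towards the stronger stream rather than landing midway.
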