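# saccadebg

A rate-coded model of saccade target selection through concurrent
cortical and subcortical basal-ganglia loops, with actor-critic
reinforcement learning at the basal-ganglia input.

## The science

Primates choose saccade targets through several parallel circuits that all
pass through the basal ganglia (BG). This package implements three of
them and studies how their structure shapes learning:

* a **subcortical loop** (retina → superficial superior colliculus →
  deep colliculus ↔ thalamus ↔ BG), spatial only, fast (41 ms input
  latency);
* a **cortical spatial loop** through the frontal eye fields (FEF,
  91 ms), sharing its BG circuit with the subcortical loop;
* a **cortical feature loop** through V4/IT (122 ms) that selects a
  *colour* rather than a place, and projects the selected colour's
  locations back onto the collicular map.

Every structure is a field of bounded leaky rate units
`x(t+dt) = clip(x + dt/τ·(I − x), 0, max)` on 70×70 complex-log
retinotopic maps per hemifield. The BG circuit (D1/D2/FS striatum, STN,
GPe, GPi|SNr) selects among coarse map channels (Gaussian-pyramid reduced,
factor 4 per dimension) by *disinhibition*: a winning channel's GPi|SNr
output collapses below its tonic level, releasing thalamo-cortical
amplification and, ultimately, the collicular motor map. A burst-generator
stage converts the motor-map place code into eye displacement (the
spatio-temporal transformation), with an omnipause veto and an
integrate-saturate burst terminator.

Learning is classical actor-critic TD(λ): a critic learns the value of
the BG input vector; an actor re-weights that input (`A = W·u`,
initialized at the identity), with eligibility traces and the per-channel
disinhibition as credit signal. The spatial learner operates on the
concatenated (collicular-thalamus, FEF-input) channel vector; the colour
learner on the three colour channels. Exploration comes only from
perceptual noise: of two cues, one has amplitude 1.0 and the other 0.95,
randomly assigned.

Trained on a two-cue choice protocol (50 ms black, 800 ms fixation,
150–250 ms gap, cues up to 600 ms, reward at trial end), the model

* learns a **spatial rule** (go right, any colour) to ~100% and develops
  **express saccades**: the reaction-time mode drops from ≈200 ms to
  ≈85 ms as the learned weights let the direct retino-collicular volley
  trigger the saccade before cortex sees the cues;
* learns a **colour rule** (go red, any side) only to ≈75%: the faster
  spatial circuitry keeps winning when the wrong-coloured cue is the more
  intense one;
* in a **conjunction task** (red-and-right, or withhold), performs the
  conjunction case well but fails to withhold, erring towards the correct
  *side* — the spatial system dominates.

Clamping FEF output to zero in a trained model lengthens express saccades
by ≈15 ms but does not abolish them.

## Worked example

```python
import numpy as np
from saccadebg import ModelConfig, ExperimentConfig
from saccadebg.tasks import TaskSpec, run_experiment, weight_map_summary

exp = ExperimentConfig(runs=1, sessions=20, trials_per_session=12,
                       scale="reduced")
df, models = run_experiment(exp, TaskSpec("spatial"), seed=1,
                            keep_models=True)
late = df[df.session >= 15]
print("final performance:", round(late.reward.mean(), 2))
print("median SRT, first vs last 5 sessions: %.0f -> %.0f ms"
      % (df[df.session < 5].srt.median(), late.srt.median()))
maps = weight_map_summary(models[0].actor_spatial, models[0].m)
print("summed input weights, SC portion peak: %.2f, FEF portion peak: %.2f"
      % (maps["sc"].max(), maps["fef"].max()))
```

Output (desk-scale preset, seed 1):

```
final performance: 1.0
median SRT, first vs last 5 sessions: 203 -> 169 ms
summed input weights, SC portion peak: 1.26, FEF portion peak: 1.07
```

The model reaches perfect side-choice, its reaction times begin to
shorten, and the learned weights favour the collicular half of the
learning input at the rewarded location. The full express-saccade
transition (reaction-time mode dropping to ~90 ms, collicular weight
peaks near 5) develops at full map resolution, where the learning rates
are larger per the per-weight normalisation; `scripts/acceptance.py`
runs that protocol.

The same experiments are available from the shell:

```bash
saccadebg run --task spatial --scale reduced --sessions 20 --seed 1 --out results/spatial
saccadebg analyze --log results/spatial --report srt
```

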