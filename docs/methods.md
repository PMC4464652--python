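# Methods

## The model

A fully interactive network with three peripheral layers — a retinotopic
input layer (4200 units), a visual image layer (4200 units), and a verbal
layer (6 units) — connected bidirectionally through a single 20-unit hidden
layer. There are no direct peripheral-peripheral or hidden-hidden
connections. Unit dynamics use a time-averaged net input with integration
rate r = 0.1 and a logistic activation:

    s_i(t) = s_i(t-1) + r * ( Σ_j w_ji a_j(t-1) + b_i − s_i(t-1) )
    a_i(t) = σ(s_i(t))

so under a constant summed input x the net input approaches x geometrically
with ratio 1 − r per cycle. Trials start from s = 0 (a = 0.5); state
persists across the phases of a trial (this carry-over is the mechanism by
which a verbalization phase biases the subsequent recognition phase) and is
reset between trials.

External inputs constrain a layer in one of two ways:

* **hard clamp** — activations pinned to the external values (used for the
  retinotopic input for the whole of its phase);
* **soft clamp** — the internally computed output is blended with the
  external value by a fixed gain g = 0.5, `a ← a + g·(ext − a)` (used for
  all external input to the verbal layer).

Peripheral units whose external input / target value never varies across
the stimulus set are disconnected from the hidden layer; with the default
glyph bank this keeps ~500 visual and ~900 retinotopic units of the 8400
image units, plus all 6 verbal units.

## Stimuli

64 faces from a 4 × 4 × 4 factorial of eye, nose, and lip subordinate
types on a 70 × 60 binary canvas (1 = black). Each feature carries two
verbal labels (drooping/slanted eyes, long/button nose, thick/downturned
lips); each label covers two subordinate glyph variants (big/small), so
every verbal label triple is shared by exactly 8 faces. The glyph bank is
parametric (filled rotated ellipses and parabolic strokes in three disjoint
row bands); within a label the small variant is a concentric shrink of the
big one, which gives label-sharing faces heavy pixel overlap — the graded
visual-similarity structure that recognition, generalization, and the
verbalization effects all depend on. Retinotopic inputs are the binary
images smoothed by a normalized 2-D Gaussian (SD 0.2 px, reflect padding,
clipped to [0, 1]); at this width the degradation is mild and the
parameter is exposed for stronger filtering. A seeded uniform draw marks
32 faces as trained ("old") and 32 as untrained ("new").

The generator emulates the structure of face stimuli, not their appearance:
real faces carry far richer, less nested pixel statistics. Two consequences
observed at this scale are that the model generalizes to untrained faces
more aggressively than with naturalistic stimuli (untrained items polarize
quickly with continued training) and that the useful training window is
shorter (see *Training length* below). Passing tests therefore certify the
mechanism — attractor dynamics, familiarity separation, verbal recoding —
not photograph-level face recognition.

## Tasks and training

Three tasks, all 10-cycle trials: visual recognition (retinotopic hard
clamp → visual image target), verbalization (retinotopic hard clamp →
3-of-6 verbal target), and mental imagery (full 6-bit verbal pattern
soft-clamped → visual image target, no retinotopic input). Imagery is
one-to-many — 8 faces share every verbal triple — so item-exact imagery
accuracy is structurally capped below 100%.

Training is backpropagation through time on cross-entropy error, learning
rate 0.05, weight decay 1e-8, momentum 0, batch size 1, with Gaussian noise
(SD 0.2) added to the hidden layer's summed input during training only.
Units within the zero-error radius 0.1 of their target contribute no
gradient. A trial phase ends early once every target-layer unit is within
0.5 of its target; the test is floored at the phase's third cycle, because
external input reaches the output layers only after two cycles
(input → hidden → output) and an earlier stop would judge input-independent
activity (`early_stop_min_cycle`, exposed). The curriculum pre-trains
visual recognition until nearest-neighbour accuracy on the trained items
exceeds 50% (checked every `eval_interval` epochs, noise disabled), then
interleaves all three tasks as one fully shuffled deck with a fixed number
of repetitions per item per task.

**Error schedule.** Where along a phase the error is injected is a genuine
design choice. Injecting it at every cycle from cycle 1 asks the network to
produce item-specific outputs before the input has propagated through the
hidden layer, which collapses training entirely at full scale (trained
accuracy ~10%). Skipping the update whenever a trial early-stops is stable
but removes all pressure toward polarized outputs (mean polarity ~0.05,
versus the ~0.9 regime the familiarity judgment needs). The default
injects error only at the phase's stop cycle — the 10th cycle, or earlier
when the early-stop test passes — which both trains stable attractors and
keeps deepening them; the alternatives remain available via
`NetworkParams(error_schedule=...)`.

**Training length.** The full profile uses 3000 repetitions per item per
task. The reduced profile (1500 repetitions) is the package default for the
simulations and the test-suite: it is the point where the
training-performance metrics plateau with this glyph bank (trained
nearest-neighbour accuracy at ceiling, verbalization near ceiling).
Training substantially past that point makes untrained faces as polarized
as trained ones — the old/new familiarity separation that the recognition
judgment rests on washes out, an overgeneralization artifact of the
synthetic faces' nested pixel structure rather than of the model.

## Recognition judgment

Familiarity of an item is the mean *polarity* of the connected visual
image units at the 10th cycle after retinotopic onset, noise disabled and
early stopping ignored, where polarity(a) = a·log2 a + (1−a)·log2(1−a) + 1
is one minus the binary entropy (0 at a = 0.5, 1 at the asymptotes). The
average runs over connected units only: disconnected units sit at a
constant bias-free 0.5 and would only dilute every item equally (a
whole-layer mode is available).

The old/new criterion is placed infinitesimally below the minimum
trained-item polarity of the control condition — hits are 100% by
construction, correct rejections emergent — fitted per model instance and
then frozen across every verbalization condition of that instance.
Accuracy is the unweighted mean of hit and correct-rejection rates.
Nearest-neighbour classification (smallest Euclidean distance to the 64
visual targets on connected units, ties to the lowest item id) scores the
recognition, verbalization, and imagery tasks.

## Verbalization conditions

A verbalization phase soft-clamps the selected verbal units to 1.0 for 10
cycles with no retinotopic input (non-selected units free-run, matching a
describer who asserts some features and says nothing about the rest), then
recognition proceeds with the external verbal input maintained or removed:

| condition  | old items      | new items      | during recognition |
|------------|----------------|----------------|--------------------|
| control    | —              | —              | —                  |
| similar    | consistent     | consistent     | maintained         |
| dissimilar | consistent     | inconsistent   | maintained         |
| irrelevant | inconsistent   | inconsistent   | removed            |
| graded k   | k of 3 correct | k of 3 correct | maintained         |

"Inconsistent" selects the within-pair opposite label for every feature.
For graded k, which k features are described correctly is drawn per item
from a logged seed. The graded comparisons pair the old-item distribution
at one k with the new-item distribution at another (old k=2 vs new k=1,
old k=1 vs new k=0), judged with the frozen control criterion.

Conditions are compared to control with a two-sided paired t-test across
the model instances (df = n_models − 1 = 4); zero-variance differences are
reported as signed infinity. The single-trial lineup draws one old item
and N distractors from a model's per-item polarity samples and scores the
trial correct iff the old item's polarity is strictly maximal (ties are
failures); with N = 7 it emulates the eight-alternative forced-choice test,
and under exchangeable old/new samples the proportion converges to
1/(N+1).

## Numerical choices

* Initial weights i.i.d. uniform in ±0.1; biases on hidden and connected
  peripheral units, trained like weights.
* An epsilon guard of 1e-7 inside the cross-entropy logarithms.
* The old/new threshold margin is 1e-9 below the minimum old polarity.
* Classical (Torgerson) MDS with deterministic eigenvalue ordering and
  sign-fixed eigenvectors; fewer than 3 positive eigenvalues truncates the
  embedding with a warning.
* Hidden-noise draws come from the run's logged generator; evaluation is
  fully deterministic (noise off), so identical configurations reproduce
  bit-identical outputs.

## Problem sizes used by the test-suite and the acceptance pipeline

The desk-scale checks use a 4-item subset (two verbal-triple pairs, smoke
profile: 300 repetitions) and micro-networks of 2–5 units for
finite-difference gradient verification. The simulation-level checks train
5 model instances on the full 64-face bank at the reduced profile (1500
repetitions per item per task); the full 3000-repetition profile is
available via `--profile full` / `PROFILES["full"]`.

## Known limitations

* The glyph bank is a structural stand-in; point accuracies depend
  strongly on its similarity statistics. Alternative banks explored during
  development (non-nested offset variants; shared label shapes with small
  detail marks) trained strictly worse — within-label discrimination
  resting on a few dozen pixels is unlearnable at 20 hidden units, and
  larger within-label differences inflate the one-to-many imagery conflict.
* Full-scale training is metastable: outcomes differ substantially across
  initialization seeds and trial orderings under identical configurations,
  so the five instances do not converge uniformly and the condition-level
  point accuracies carry wide error bars. The desk-scale instances and all
  mechanism-level properties are robust.
* With nested synthetic glyphs the model overgeneralizes when trained far
  past the reduced profile, eroding the old/new separation (see *Training
  length*).
* Verbal facilitation, attention/Navon effects, free multi-feature
  description, and non-metric MDS are out of scope.
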