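# overshadow

A recurrent connectionist model of **verbal overshadowing** in face
recognition — the finding that verbally describing a face (or even an
unrelated face) during retention impairs subsequent recognition of it.

The package is for computational cognitive scientists who want a working,
fully inspectable instantiation of the *recoding interference hypothesis*:
verbalization re-codes the distributed internal representation of a face,
and recognition then runs on that recoded representation. The rival
*transfer-inappropriate processing shift* account (separate operation-
specific representations) is deliberately **not** implemented; the point of
the model is that one interactive system reproduces the phenomena without
it.

## The model

Three peripheral layers — retinotopic input (4200 units), visual image
(4200 units), verbal labels (6 units) — interact bidirectionally through a
20-unit hidden layer. Unit *i* integrates a time-averaged net input and
passes it through a logistic:

    s_i(t) = s_i(t−1) + 0.1 · ( Σ_j w_ji a_j(t) − s_i(t−1) )
    a_i(t) = 1 / (1 + exp(−s_i(t)))

External verbal input soft-clamps a unit halfway to its external value,
`a ← a + 0.5·(ext − a)`; the retinotopic input is hard-clamped. The model
is trained by backpropagation through time on three tasks over a factorial
bank of 64 synthetic faces (4 eye × 4 nose × 4 lip types, two subordinate
types per verbal label): visual recognition, verbalization, and mental
imagery. Half the faces are trained ("old"), half held out ("new").

Familiarity of a probe face is read out as the mean **polarity** of the
visual image layer at the 10th settling cycle,

    polarity(a) = a·log₂a + (1−a)·log₂(1−a) + 1 ,

one minus the binary entropy of a unit's activation: confident (near 0/1)
responses mark trained, familiar items. An old/new criterion placed just
below the minimum trained-item polarity turns the polarity distributions
into a recognition judgment, and a set of verbalization conditions
(consistent vs. within-pair-opposite verbal input, maintained vs. removed
at recognition, graded description accuracy) reproduces the verbal
overshadowing pattern. See `docs/methods.md` for the full account.

## Worked example

Train one desk-scale model on a 4-item subset and score the three tasks:

```python
import overshadow as ov

stimuli = ov.make_micro_instance("four_item_stimuli", seed=1)
params = ov.NetworkParams()
weights, log = ov.train_model(stimuli, params, ov.PROFILES["smoke"], seed=0)

items = range(stimuli.n_items)
print("visual recognition:", ov.visual_accuracy(weights, stimuli, items))
print("verbalization:     ", ov.verbal_accuracy(weights, stimuli, items))
print("mental imagery:    ", ov.imagery_accuracy(weights, stimuli, items))
```

```
visual recognition: 1.0
verbalization:      1.0
mental imagery:     0.25
```

Recognition and naming reach ceiling. Imagery cannot: the four faces form
two pairs sharing a verbal label triple, so the verbal-to-face mapping is
one-to-many — identical verbal input cannot yield two different faces, and
the network lands on one member of each pair (here 1 of 4 items exactly
right). The same structural cap holds at full scale, where every verbal
triple is shared by 8 faces.

The full experiment — 64 faces, five model instances, control and
verbalization conditions, paired statistics — runs from the shell:

```bash
overshadow simulate --stimulus-seed 1 --n-models 5 --profile reduced --out runs/demo
overshadow generate-stimuli --seed 1 --out stimuli/   # inspect the faces as PGM images
```

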