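# floorgait

Gait-based user identification from a binary floor-sensor grid.

`floorgait` re-implements, as a tested Python library and command-line
tool, a floor-sensor gait biometric for small cohorts (a home with up to
~10 enrolled users walking barefoot).  The sensing surface is a 3.6 m x
0.6 m corridor of wooden tiles carrying 1536 photo-interrupter sensors in
a 96 x 16 grid at 3.75 cm pitch; each sensor reports only *pressed* /
*released*, so a walk is a stream of timestamped binary events.  Because
no public dataset exists for this kind of floor, the package includes a
statistical gait simulator that generates event streams with per-user
stable gait parameters, so every stage of the method is testable
end-to-end.

## Method

Two complementary feature families are extracted from each walk:

* **Walking pattern** — variation *across* footsteps.  The event stream
  is segmented into footsteps by spatio-temporal connected components
  (sensors join a footstep iff grid-adjacent and overlapping in time).
  Each footstep's footprint is summarised by an 8 x 4 binary *footprint
  model* anchored at the *seed sensor* (the backmost activated sensor),
  and yields seven features: the seed's physical coordinates (FX, FY),
  the footprint-model centroid (com_FX, com_FY), the pressed-sensor
  count (nSensor), and heel-strike / toe-off times (fStart, fEnd).
  Sequences over the first five footsteps, selected by a feature-set
  case (case 4 = com_FX, com_FY, fStart, fEnd → a 20-vector), are
  min-max normalised to [-1, 1].

* **Stepping pattern** — variation *within* a footstep.  The footprint
  model's instantaneous state is sampled every `dt` seconds from
  heel-strike over a 0.8 s horizon (`floor(0.8/dt)` frames; 20 at
  dt = 0.04 s) and scanned into ±1 values, 32 per frame.  Four footsteps
  at dt = 0.04 s give 32 x 20 x 4 = 2560 inputs, optionally reduced to
  248 PCA coefficients.

Each modality feeds a three-layer MLP (logistic-sigmoid hidden layer of
30 nodes, tanh output, one output per enrolled user) trained one-vs-rest
with ±1 targets by full-batch conjugate gradient until a mean-squared-
error goal (1e-3 within 800 iterations for walking; 1e-5 within 115 for
stepping).  Identification is `argmax_i O_i` over the per-user scores;
the two classifiers are fused at the matching-score level,

    O_G(i) = W_W * O_W(i) + W_S * O_S(i),

with non-negative weights selected by grid search on held-out validation
data.  Evaluation is repeated stratified 10-fold cross-validation with
confusion matrices aggregated over repetitions.

## Worked example

Simulate a 4-user cohort (12 walks each), cross-validate identification,
then train an identifier and identify a single walk:

```sh
$ floorgait simulate --users 4 --samples 12 --seed 42 --out demo
wrote 48 event logs and manifest.tsv to demo (seed=42)

$ floorgait evaluate --manifest demo/manifest.tsv --folds 4 --reps 1 --seed 7
# floorgait-eval v1
# folds=4 repetitions=1 seed=7
# modality=both pca=248
# classes: user00 user01 user02 user03
accuracy	walking	91.67	+-6.80
accuracy	stepping	93.75	+-4.17
accuracy	fused	93.75	+-4.17
confusion	walking
12	0	0	0
1	11	0	0
0	0	11	1
1	0	1	10
...

$ floorgait train --manifest demo/manifest.tsv --out demo/model.json
trained on 48 walks of 4 users; fusion weights (0.02, 0.02); saved to demo/model.json

$ floorgait identify --model demo/model.json --sample demo/user02_walk005.events
identified: user02
  user00	-0.0400
  user01	-0.0398
  user02	+0.0399
  user03	-0.0400
```

The accuracy lines are percent of held-out walks identified correctly
per modality (walking, stepping, and their score-level fusion); each
confusion row is a true user, each column the predicted user.  The
identify scores are fused per-user matching scores — the enrolled user
with the largest score is the decision.  At the default study scale
(10 users x 50 walks, 10-fold x 3 repetitions) the same pipeline reaches
roughly 96% walking, 96% stepping and 98% fused accuracy on the
synthetic cohort.

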