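# henrec — laying-hen behavior recognition from body-mounted inertial sensors

`henrec` implements a complete supervised pipeline for recognizing the
daily behaviors of laying hens from a back-mounted IMU (3-axis
accelerometer, ±2 g, in m/s², and 3-axis gyroscope, ±500 deg/s). It is
aimed at researchers in computational ethology and precision livestock
farming who want a reproducible, testable reference implementation of the
classic feature-engineering approach: decimation across sampling
frequencies, 50 %-overlapped fixed windows, a 97-dimension time/frequency
feature bank, optional training-set balancing, nested cross-validated
classifier training, and an evaluation layer that separates average
performance from robustness to individual differences.

## The method

Recordings are segmented per labeled behavior interval into windows of
WS ∈ {64, 128, 256, 512, 1024} samples, related to the window length by
WL = WS / SF (1.28 s at 128 samples / 100 Hz), slid with 50 % overlap, and
discarded if they would cross an interval boundary. Each window yields 97
features: 13 statistics — MIN, MAX, MEAN, SD, SKEW, KURT, IQR, MAD, MedAD,
mean crossings, spectral energy, frequency entropy, dominant frequency —
on 7 axes (acc x/y/z, the orientation-independent magnitude m = ‖acc‖₂,
gyr x/y/z), plus Pearson correlations of the 3 acc and 3 gyr axis pairs.

Twelve behavior classes are used throughout, in fixed order
MV, ET, DK, PR, BS, HS, TF, ST, RS, DB, LS, OT (moving, eating, drinking,
preening, body shaking, head scratching, tail flapping, standing still,
resting, dust-bathing, litter scratching, others).

Seven classifier families (NB, kNN, DT, RF, LGBM, SVM, MLP) are trained
under nested cross-validation: an inner stratified 5-fold CV picks
hyperparameters from the family's candidate grid by macro-F1, the outer
CV measures performance. Two outer schemes are supported:

* **stratified 10-fold** — average performance when training and test
  individuals mix;
* **LOHO** (leave-one-hen-out) — one fold per animal; the test hen never
  appears in training *or* tuning.

From the fold-averaged confusion matrix M (rows = true class k), the
package computes per-class precision_k = Ncorrect_k / Npredicted_k,
recall_k = Ncorrect_k / Ntested_k, F1_k = harmonic mean, and the
unweighted macro average over the 12 classes. The **individual
independence ratio**

    IIR = metric(LOHO-CV) / metric(10-fold-CV)

quantifies how much performance depends on having seen the test
individual (1 = fully individual-independent), and ΔM_{a,b} = M_a − M_b
localizes which confusions a condition changes. SMOTE and SMOTE+ENN
balancing can be applied inside every training partition; synthetic
instances never reach validation or test folds.

Because real flock recordings are rarely shareable, the package ships a
seeded synthetic generator (`henrec.synthetic`) producing multi-hen
sessions with class-specific motifs (impulse bursts, spectrally distinct
oscillations, tilt-separated quiet postures), per-class duration and
occurrence imbalance, and per-hen orientation/gain/rate effects that make
LOHO measurably harder than 10-fold CV.

## Worked example

```python
from henrec import (SyntheticConfig, WindowingSpec, ClassifierSpec,
                    LabeledFeatureSet, segment, nested_cv,
                    average_confusion, compute_metrics, compute_iir)
from henrec.synthetic import generate
from henrec.features import feature_matrix

cfg = SyntheticConfig(sampling_frequency=100.0, seed=101)  # 8 hens, 240 s each
recs, labels = generate(cfg)
spec = WindowingSpec(ws=128, sf=100.0)                     # WL = 1.28 s
windows = []
for hen_id, rec in recs.items():
    windows += segment(rec, [l for l in labels if l.hen_id == hen_id], spec)
ds = LabeledFeatureSet.from_frame(feature_matrix(windows, 100.0, "ALL"))

knn = ClassifierSpec("kNN")
ten = compute_metrics(average_confusion(nested_cv(ds, knn, "stratified-10-fold", seed=11)))
loho = compute_metrics(average_confusion(nested_cv(ds, knn, "loho", seed=11)))
print(f"10-fold macro-F1 {ten.macro_f1:.3f}")
print(f"LOHO    macro-F1 {loho.macro_f1:.3f}")
print(f"IIR              {compute_iir(loho.macro_f1, ten.macro_f1).value:.3f}")
```

Output:

```
10-fold macro-F1 0.961
LOHO    macro-F1 0.949
IIR              0.988
```

That is: on this well-separated synthetic flock with mild individual
effects, kNN classifies nearly every window correctly under 10-fold CV
(macro-F1 0.961); leaving each hen out in turn costs about a point
(0.949), so the IIR of 0.988 says performance is only weakly
individual-dependent.
Raising the generator's per-hen effect scales drives the IIR down.

The same pipeline is available from the shell:

```
henrec simulate  --config config.yaml
henrec prepare   --config config.yaml
henrec featurize --config config.yaml
henrec evaluate  --config config.yaml
henrec report    --config config.yaml
```

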