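# shadowfeat

**Shadow features for sensor-based human activity recognition: Hurst-driven
adaptive smoothing as a streaming feature-engineering step.**

Activity classifiers built on raw motion streams — tri-axial accelerometer
traces, skeletal joint coordinates — see only the *instantaneous* position
of the body. Two activities with similar postures but different movement
dynamics (climbing stairs up vs. down, sitting vs. standing) then produce
heavily overlapping feature values, and accuracy collapses as soon as the
classifier faces a stream from an unseen subject or sensor position.

A *shadow feature* is a companion time series appended (not substituted)
per original feature: a trailing smoother that exposes the underlying
momentum of the motion. For feature value $r_i$ at position $i$ with
sliding-window length $w_i$,

$$r_i^{\text{shadow}} = \frac{(\varphi_i + 1)\,r_i + r_{i-1} + \dots + r_{i-(w_i-1)}}{w_i}$$

(uniform weighting; a linearly weighted variant with weights $w_i,\dots,1$
is also provided). The boost factor $\varphi_i = (|H_i| - 0.5)/0.5 \in
[-1, 1]$ and the window length $w_i$ are both driven by the Hurst exponent
$H$ of the signal, estimated by rescaled-range (R/S) analysis:

$$\mathbb{E}\!\left[\frac{\mathcal{R}(Y)}{\sigma(Y)}\right] = C\,|Y|^{H},$$

where $\mathcal{R}$ is the range of the cumulative mean-deviation series
and $\sigma$ the population standard deviation. A calibration pass over
the initial samples fits $H^{\text{start}}$ and $\log C$ per feature,
characterizes the series (stationarity, trend, random walk) to select a
smoother, and maps the *continuity-intensity grade* of $H$ (ten bands
from very weak to very strong persistence, $\pm1\dots\pm5$) to a base
window length. During generation, a dynamic in-window estimate
$H_i^{\text{dynamic}} = (\log(R/S)_{w_i} - \log C)/\log w_i$ re-grades the
window each step: the stronger the long-range memory, the longer the
window. The update is one-pass and constant-memory per feature, so shadow
values stream alongside the raw data with no look-ahead — the same code
path serves batch tables and live streams, bit-identically.

The package also ships seeded generators (exact fractional Gaussian noise
by circulant embedding; labeled accelerometer-like and skeletal-like
activity streams) and a benchmark harness comparing original features, a
Haar-wavelet transformation baseline, and shadow augmentation across
batch learners (decision tree, SVM, neural network) and incremental
learners (naive Bayes, 1-NN, Hoeffding tree) in *full training* and
*train-then-test* modes.

## Worked example

```python
import shadowfeat as sf

series = sf.simulate_activity_stream(seed=0)      # 14 000 x 3, 7 activities, 50 Hz
calib = sf.calibrate(series)
for name, fc in calib.features.items():
    print(f"{name}: H_start={fc.H_start:.3f} grade={fc.grade:+d} "
          f"({fc.intensity}) base_window={fc.base_window} smoother={fc.smoother}")

shadow = sf.generate_shadow_batch(series, calib, sf.ShadowConfig())
aug = sf.augment_dataset(series, shadow, policy="drop")
print("augmented table:", aug.predictors.shape)
```

```
x: H_start=0.761 grade=+4 (Strong) base_window=64 smoother=moving_average
y: H_start=0.708 grade=+3 (Normal strong) base_window=32 smoother=moving_average
z: H_start=0.702 grade=+3 (Normal strong) base_window=32 smoother=moving_average
augmented table: (13937, 6)
```

Each axis is stationary with persistent memory (H around 0.7), so the
moving-average branch is selected and windows of 32–64 samples
(0.6–1.3 s at 50 Hz) are assigned; the table gains one `_shadow` column
per axis, with the 63 warm-up rows dropped. Training a decision tree on
this stream and testing on an independently generated one:

```python
test = sf.simulate_activity_stream(seed=10000)
from shadowfeat.evaluate import prepare_strategy, train_eval
tr, te = prepare_strategy("shadow", series, test)
rep = train_eval(tr, "decision_tree", "train_then_test", te)
```

```
decision tree on unseen stream: accuracy=0.754 kappa=0.713 (general) macro_f=0.743
original features only:         accuracy=0.549 kappa=0.473 (general) macro_f=0.543
```

The raw features confuse activities that share a posture but differ in
cadence; the shadows recover the smoothed momentum level and lift unseen-
stream accuracy by about twenty points, moving kappa toward the upper
credibility band.

## Command line

```sh
shadowfeat simulate  --seed 1 --output stream.csv
shadowfeat calibrate --input stream.csv --output calib.yaml
shadowfeat augment   --input stream.csv --calibration calib.yaml --policy drop --output aug.csv
shadowfeat evaluate  --seed 1 --output comparison.csv
```

All commands take `--config config.yaml` to override defaults (window
bounds, grade→length mapping, weighting, test levels, learners); unknown
cells are serialized as `?`.

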