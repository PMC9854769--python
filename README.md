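# eegmusic

Parametric (MUSIC) spectral feature extraction and classification for
multichannel EEG emotion recognition.

EEG emotion classifiers are usually fed band-power features from
non-parametric spectral estimates (Welch periodograms).  This package
implements the parametric alternative: the MUltiple SIgnal Classification
(MUSIC) pseudospectrum, computed from the eigen-decomposition of each
window's autocorrelation matrix, with Pisarenko harmonic decomposition to
recover per-component sinusoid powers, plus everything around it needed to
run the approach end to end — amplitude-based corrupt-channel screening,
powerline notch and 8-40 Hz FIR filtering, per-lobe PCA channel reduction,
fixed-size feature tensors from 50%-overlapping windows, a bilayer
neural-network 5-fold cross-validation protocol, and a Welch baseline for
both accuracy and runtime comparison.

It is aimed at researchers working with multichannel scalp EEG (e.g.
62-channel, 200 Hz emotion corpora) who want a tested, scriptable
implementation of the subspace feature-extraction chain and its evaluation
protocol.  A synthetic-data module generates labeled trials with known
spectral ground truth, so the whole pipeline is testable without licensed
recordings.

## The model

A windowed channel `y(n)` is modeled as `p` sinusoids in white noise.  With
`R` the `L x L` Toeplitz matrix of biased autocorrelation lags
`g(k) = (1/N) Σ_n y(n) y(n+k)` and `v_{d+1} … v_L` its noise-subspace
eigenvectors, the MUSIC pseudospectrum at angular frequency `ω = 2πf/fs` is

    P_MUSIC(ω) = 1 / Σ_{k>d} |s(ω)^H v_k|²,   s(ω) = [1, e^{jω}, …, e^{j(L−1)ω}]

whose peaks estimate the component frequencies.  Powers follow from the
Pisarenko system `Σ_i cos(k ω_i) P_i = g(k)`, `k = 1…p`.  Details, defaults
and design choices are in [docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from eegmusic import (SyntheticSpec, simulate_dataset, preprocess_trial,
                      build_dataset, FeatureConfig, TrainConfig, cross_validate)

# 45 labeled trials (15 per emotional state), 62 channels at 200 Hz
spec = SyntheticSpec(seed=1)
trials = [preprocess_trial(t, "all62") for t in simulate_dataset(spec, 15)]

tensor = build_dataset(trials, "music", FeatureConfig())
print(tensor.shape)

report = cross_validate(tensor, TrainConfig(seed=1))
print(round(report.mean_accuracy, 3), [round(a, 2) for a in report.fold_accuracies])
print(np.round(report.per_class_metrics["f1"], 3))
```

prints

```
(45, 62, 124)
1.0 [1.0, 1.0, 1.0, 1.0, 1.0]
[1. 1. 1.]
```

i.e. a 45-trial × 62-channel × 124-bin MUSIC feature tensor on which the
bilayer network separates the three synthetic emotional states perfectly
under stratified 5-fold cross-validation (per-class F1 = 1.0).  The states
differ in alpha/beta/gamma band power, which is exactly what the spectral
features encode; a label-permutation control on the same tensor falls to
chance (~0.27).

The same pipeline is scriptable from the shell:

```sh
eegmusic simulate --out data/ --trials-per-state 15 --seed 1
eegmusic qc data/manifest.csv --threshold-uv 500 --out qc.json
eegmusic features data/manifest.csv --estimator music --out feats.npz
eegmusic train feats.npz --out report.json
eegmusic bench --reps 3 --out bench.csv   # MUSIC vs Welch runtime
```

or end to end with `eegmusic run --config pipeline.yaml --out rundir/`.

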