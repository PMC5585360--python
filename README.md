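# tvcgnet

Inter-patient ECG heartbeat classification built on the **temporal
vectorcardiogram (TVCG)**: a 3-D representation of a two-lead heartbeat in
which the two leads and time span the axes, so the trajectory of the cardiac
vector is not collapsed onto itself as in a conventional vectorcardiogram.
Shape features are extracted from the TVCG with complex networks, combined
with classical morphological/interval and Haar-wavelet features, and fed to
a class-weighted SVM.  Three particle-swarm stages tune the pipeline:
the network thresholds, the per-class SVM weights, and a binary-PSO wrapper
feature selection.

The package targets the **inter-patient paradigm** (training and test sets
contain disjoint patients, the de Chazal DS1/DS2 protocol on MIT-BIH with
AAMI superclasses N/S/V), which is the evaluation setting that resembles
clinical reality.

## Method in brief

For a beat window, the subsampled point set `V = [p_1, ..., p_{n_v}]`,
`p_i = (x_i, y_i, z_i)` (lead A, lead B, time; each axis min-max normalized
to [0, 1]) defines a complete graph with normalized Euclidean edge weights

    w_ij = sqrt((x_i - x_j)^2 + (y_i - y_j)^2 + (z_i - z_j)^2) / max w

A dynamic threshold evolution sweeps a limit

    T_l = T_0 + l (T_Q - T_0) / (m - 1),    l = 0 .. m-1

keeping at each step only the edges with `w_ij <= T_l`, and extracts five
degree-based descriptors per step (mean/max connectivity degree, joint
degree entropy, joint degree energy, mean joint degree) — an `m x 5` TVCG
feature block.  With the reference blocks (148 morphology samples, 13
interval features, 7 wavelet/autocorrelation features) and the default
`m = 2`, the assembled vector has 178 dimensions.

Classification uses an RBF C-SVC (`C = 1`, `gamma = 1/n_features`,
one-against-one) with per-class penalty weights `(w1, w2, w3)` for N, S, V.
The optimization fitness is the mean per-class F-score,
`F = 2 Se (+P) / (Se + (+P))`, measured on a validation split whose
patients are disjoint from training.

## Worked example

Evaluate the shipped benchmark confusion matrix (inter-patient MIT-BIH test
set, common filter) with the AAMI metric scheme:

```bash
$ tvcgnet evaluate --benchmark
{
  "Acc": 92.4,
  "Se_N": 94.0,
  "+P_N": 98.0,
  "FPR_N": 17.4,
  "Se_S": 62.0,
  "+P_S": 53.0,
  "FPR_S": 2.1,
  "Se_V": 87.3,
  "+P_V": 59.4,
  "FPR_V": 4.1
}
```

Per class these are sensitivity (recall), positive predictivity (precision)
and false-positive rate, in percent; `Acc` is overall accuracy.  The same
numbers are available from the library:

```python
from tvcgnet import aami_metrics, ConfusionMatrix, BENCHMARK_CONFUSION_COMMON
metrics = aami_metrics(ConfusionMatrix(BENCHMARK_CONFUSION_COMMON))
print(metrics.rounded_percent())
```

An end-to-end run on a synthetic six-patient corpus (three patients train,
three test, inter-patient guard enforced):

```bash
$ tvcgnet evaluate --seed 1
...
  "mean_f_score": 1.0
```

The synthetic classes are well separated by design, so the held-out mean
F-score is near 1; see `docs/methods.md` for what this does and does not
demonstrate.  `tvcgnet synth`, `tvcgnet optimize-cn`, `tvcgnet
optimize-weights` and `tvcgnet select-features` generate a corpus and run
the three tuning stages on it.

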