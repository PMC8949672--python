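# arrhythmianet

Classification of ECG beats into cardiac-arrhythmia classes (normal sinus
rhythm plus sixteen arrhythmias such as AFIB, PVC, LBBBB, VFL) from
single-lead recordings, for researchers who want every stage of a
scalogram-based deep feature pipeline available as tested, seedable library
code — including a synthetic beat generator, so nothing requires access to
clinical databases.

## The method

The pipeline has four blocks:

1. **Segmentation.** Each record is cut into consecutive one-second windows
   (no R-peak alignment); beats are z-scored per beat.
2. **Scalogram.** Each beat is mapped to a time–frequency magnitude image by
   the continuous wavelet transform with an analytic Morlet mother wavelet,

   `W(a, b) = a^{-1/2} ∫ s(t) Ψ̄((t − b)/a) dt`,

   on a logarithmic scale grid (12 voices/octave over 0.5–40 Hz by default),
   rendered as a square min–max-normalised image.
3. **ArrhythmiaNet features.** A small CNN — three 3×3 conv layers with
   ReLU, one 2×2 max-pool, and a self-attention gate whose 1×1-convolution
   feature spaces f, g, h produce attention weights
   `A_ij = softmax_j f(x_i)ᵀ g(x_j)` that re-weight the pooled map — trained
   with SGD (momentum 0.9, lr 0.001, batch 32, cross-entropy). The flattened
   final conv map is the **spatial feature vector** (SFV); at the reference
   geometry (256×256 input, channels 32/64/128) it has 2,097,152 features
   and the network ~36 M trainable parameters.
4. **Clump of features + classifier.** The SFV is reshaped into
   per-spatial-position descriptors; a k-means vocabulary (elbow-selected k,
   silhouette-validated) fitted on training descriptors only turns each beat
   into a k-bin **reduced feature vector** (RFV) histogram, classified by an
   SVM (or kNN). Reports: accuracy, macro sensitivity/specificity, the
   SE/SP-harmonic F1, Cohen's kappa, error.

The CNN (including backprop through the attention softmax) is implemented
directly on NumPy arrays and verified against finite differences in the
test-suite.

## Worked example

```python
from arrhythmianet import BeatClassificationModel, PipelineConfig
from arrhythmianet.classify import ClassifierSpec
from arrhythmianet.cwt import WaveletConfig
from arrhythmianet.net import NetConfig, TrainConfig
from arrhythmianet.synth import well_separated_suite

data = well_separated_suite(4, 50, seed=1)   # 4 classes x 50 synthetic beats
config = PipelineConfig(
    seed=1,
    wavelet=WaveletConfig(output_side=64),
    net=NetConfig(input_side=64, conv_channels=(8, 16, 32), n_classes=4),
    train=TrainConfig(epochs=5, seed=1),
    cof_k="auto",
    classifier=ClassifierSpec(kind="svm", kernel="rbf"),
)
results = BeatClassificationModel(data, config).fit()
print(results.summary())
```

prints

```
Beat classification results
==============================================
Classes                                      4
Evaluated beats                             60
Vocabulary size k                            5
Attention gate                              on
----------------------------------------------
Accuracy (%)                            100.00
Sensitivity (%)                         100.00
Specificity (%)                         100.00
Error (%)                                 0.00
F1-score                                 1.000
Cohen kappa                              1.000
==============================================
```

The 200 beats are split 70/30 stratified; the held-out 60 beats are all
classified correctly (the four synthetic morphologies are well separated by
construction). The elbow analysis chose a 5-word vocabulary, and the
training loss fell monotonically (1.39 → 0.19 over five epochs,
`results.loss_trace`).

The same run from a shell:

```
arrhythmianet run-all --classes 4 --per-class 50 --seed 1 --out runs/demo
```

Other subcommands (`simulate`, `train-net`, `extract`, `cof-fit`,
`cof-encode`, `classify-fit`, `classify-predict`, `kernel-sweep`,
`evaluate`, and `--no-attention` for the ablation path) expose each stage
separately; see `arrhythmianet --help`.

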