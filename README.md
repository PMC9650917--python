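# sonovid

Video-level classification of breast-ultrasound cine sequences as **benign**
or **malignant**, for researchers in medical image analysis who want a fully
reproducible, CPU-scale reference implementation of a
contrastive-learning-guided attention video classifier — together with a
seeded synthetic ultrasound-video generator so every stage can be run and
tested without access to clinical data.

## The model

A clip V = {v_t | t = 1..T} of grayscale frames is classified in three
stages:

1. **Frame encoding** — f_t = Θ(v_t): a ResNet-18-style backbone with
   group normalization in place of batch normalization and non-local
   self-attention blocks in stages 3 and 4, ending in global average
   pooling (feature width m = 8·base_width).
2. **Multi-meta attention aggregation** — a cascade of shared
   fully-connected layers with Tanh activations scores every frame feature,
   E_l^t = σ(W_l E_{l−1}^t + b_l); a softmax **across frames, per feature
   dimension** yields attention weights A_i^t with Σ_t A_i^t = 1, and the
   video feature is F̄_i = Σ_t A_i^t F_i^t. With equal weights this is
   exactly average pooling; it handles any T and ignores frame order.
3. **Linear classification** — softmax over two classes; the malignant
   probability is the reported score.

The encoder can be initialized by SimCLR-style contrastive pretraining:
two augmentations (flip, crop, scale, brightness, contrast, elastic) of a
sampled frame form a positive pair, f̄ = MLP(Θ(τ(v))) is L2-normalized, and
the NT-Xent loss is minimized with LARS under cosine annealing.

Because no deep-learning framework is assumed, the package ships its own
compact reverse-mode autograd over NumPy (`sonovid.nn`) with tested
gradients for every operation.

## Worked example

```bash
sonovid synth --n-benign 100 --n-malignant 100 --clip-length 8 \
              --test-fraction 0.4 --seed 11 --out data/
sonovid train --preset tiny --data data/ --seed 1 --out run/
sonovid eval  --data data/ --checkpoint run/model_checkpoint.npz --out run/eval
```

`synth` writes 200 clips (PNG frames + `index.csv` + `splits.json`) with
smooth-bordered benign and spiculated malignant lesions on speckle
backgrounds; `train` fits the tiny preset (encoder width 16, T = 8,
20 epochs) on the 120 training clips and evaluates on the 80 test clips.
A run with the seeds above prints:

```
test metrics: accuracy=0.9375, average_precision=0.9928, sensitivity=0.8750,
              specificity=1.0000, f1=0.9333, auc=0.9919
final train loss 0.0001 (initial 1.1492)
```

i.e. the attention classifier separates the two lesion morphologies almost
perfectly on held-out synthetic clips, with sensitivity (malignant recall)
0.875 and specificity 1.00 at the 0.5 threshold. `eval` re-emits the metrics JSON plus the ROC
points (`roc.csv`); `sonovid predict --clip-dir data/malignant_0003
--checkpoint run/model_checkpoint.npz` prints the label and malignant
score for one clip.

Library use mirrors the CLI: `synthio.generate_dataset` /
`read_dataset`, `encoder.Encoder`, `pretext.pretrain`,
`trainer.train_classifier` / `predict` / `compute_metrics`.

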