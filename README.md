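# motiongrade

Automated motion-artifact quality grading for high-resolution peripheral
quantitative CT (HR-pQCT) volumes with a compact 3D convolutional
classifier.

Patient motion smears HR-pQCT reconstructions and biases bone
microarchitecture measurements. Scans are therefore graded on a
five-level ordinal visual scale — grade 1 (no visible artifacts) to
grade 5 (severe artifacts: cortical disruption, trabecular smearing) —
traditionally by human observers, slowly and with only fair-to-moderate
inter-observer agreement. `motiongrade` replaces this with a ~100k
parameter 3D CNN that maps a volume to five sigmoid scores, one per
grade, taking the argmax (ties toward the better grade) as the
prediction.

The central idea is that motion corruption is well approximated by
convolution with an anisotropic, randomly oriented 3D Gaussian kernel
whose width grows with severity. That model supplies unlimited
exactly-labeled training data: clean volumes are synthetically degraded
at five distortion levels to **pre-train** the network, whose weights are
then **fine-tuned** on observer-graded data (transfer learning). Stacks
are graded by the most-severe rule — a stack's grade is the maximum grade
within it — and observer labels are reduced to the median of three
independent gradings.

The package ships a synthetic scaphoid-like bone phantom generator
(ellipsoid + thin cortical shell + thresholded-noise trabecular lattice),
so the full pipeline is runnable and testable without any scanner data.
See `docs/methods.md` for the model, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from motiongrade import (
    PhantomConfig, make_graded_dataset, NetworkConfig, build_network,
    count_parameters, TrainingConfig, split_dataset, make_pretraining_set,
    pretrain, finetune, predict_grade, evaluate, normalize_intensity,
)

# 50 phantoms, 10 per distortion level, with exact ground-truth grades
rng = np.random.default_rng(0)
data = make_graded_dataset(
    [PhantomConfig(shape=(16, 24, 24))], {g: 10 for g in range(1, 6)}, rng
)
for g in data:
    g.volume = normalize_intensity(g.volume)

model = build_network(NetworkConfig(input_shape=(16, 24, 24)))
print(count_parameters(model).n_parameters)   # 102582

cfg = TrainingConfig(epochs_pretrain=2, epochs_finetune=2, seed=0)
split = split_dataset(data, cfg)
train = [g for g in data if g.uid in split.train_ids]
test = [g for g in data if g.uid in split.test_ids]

clean = [g for g in train if g.grade <= 2]
pre = pretrain(model, make_pretraining_set(clean, 10, rng), cfg)
fin = finetune(model, pre.weights, train, cfg)
model.set_weights(fin.weights)

preds = [predict_grade(model, g.volume) for g in test]
report = evaluate(preds, [g.grade for g in test])
print(round(report.accuracy, 2), round(report.roc_auc, 2))
```

This miniature run prints the parameter count `102582` (the architecture
realizes ~100k trainable weights regardless of input shape, thanks to the
global average pool) and then the held-out accuracy and macro one-vs-rest
ROC-AUC of the briefly trained grader: `0.5 0.95` after two epochs per
phase at toy scale — well above the 0.2 / 0.5 chance levels, with the
near-ceiling AUC showing the five scores already rank severity correctly;
accuracy keeps rising with the training budget (see the benchmark below).

A CLI covers the same workflow from the shell:

```sh
motiongrade simulate --n-per-level 10 --out-dir data/   # phantoms + labels.csv
motiongrade summary                                     # per-layer parameter table
motiongrade pretrain --labels data/labels.csv --out pre.npz
motiongrade finetune --labels data/labels.csv --weights pre.npz --out final.npz
motiongrade grade scan.nii.gz --weights final.npz --out report.csv
motiongrade evaluate --report report.csv --truth truth.csv
```

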