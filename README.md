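# risunet

2.5D liver-tumor segmentation for abdominal CT with a Res-Inception-SE
U-Net, plus the full pipeline around it: HU preprocessing, a hybrid
Dice+BCE objective, a five-metric evaluation suite, and a seeded phantom
generator so everything runs end-to-end without any external dataset.

## The problem

Liver tumors in contrast CT are small, variably sized, and barely brighter
or darker than the surrounding parenchyma. Pure 2D networks see one slice
at a time and miss through-plane context; full 3D networks recover it at a
large cost in parameters and training time. The 2.5D compromise feeds a
stack of `n` adjacent slices (n odd, default 3) as input *channels* to a 2D
network that predicts the mask of the center slice:

```
X_t = [I_{t-⌊n/2⌋}, …, I_t, …, I_{t+⌊n/2⌋}],   zero planes off either end.
```

## The model

`RISUNet` is a five-level U-Net whose double-convolutions are replaced by
**Res-Inception-SE blocks**. Each block splits the input into four scales —
a 1×1 convolution F1, a 3×3 convolution F2, two further 3×3 convolutions
F3 (three stacked 3×3 kernels ≡ one 7×7 receptive field at far fewer
weights), and a pool+convolution branch F4 on top of F3 — concatenates
them, fuses with a 1×1 convolution, applies squeeze-and-excitation channel
attention, and adds a residual 1×1 projection of the block input:

```
F_cat   = Conv1x1(concat(F1, F2, F3, F4))
output  = SE(F_cat) + Conv1x1(x)
```

The default channel plan (77, 154, 308, 616, 1226) is calibrated so the
default 2.5D model carries **15.02 M** trainable parameters. Training uses
`L = α·L_Dice + β·L_BCE` (α = β = 1), Adam at lr 0.003, batch size 8, seed
39. Evaluation reports Dice per case (DPC), volumetric overlap error
(VOE), relative absolute volume difference (RAVD), and the average and
root-mean-square symmetric surface distances (ASSD, RMSD) in mm.

The network, its autodiff and Adam run on a compact NumPy reverse-mode
engine (`risunet.nn`) — float64, gradient-checked, fully deterministic
under a seed — so the package has no deep-learning framework dependency.

## Worked example

```python
from risunet import ModelConfig, RISUNet, count_parameters
from risunet.engine import TrainConfig, train, predict_volume
from risunet.metrics import evaluate_case
from risunet.phantoms import PhantomConfig, generate_dataset
from risunet.preprocess import PreprocessConfig, preprocess_case

print(count_parameters(ModelConfig()))   # -> 15.02   (millions)

# 12 low-contrast phantoms, split 8:2:2, fully determined by the seed
cases, manifest = generate_dataset(12, PhantomConfig(), master_seed=39)
pre = PreprocessConfig(crop_size=64)
train_data, val_data = [], []
for c in cases:
    if c.split != "test":
        pairs = preprocess_case(c.volume, c.tumor, pre)
        (train_data if c.split == "train" else val_data).extend(pairs)

model = RISUNet(ModelConfig.with_base(8), seed=39)     # tiny demo model
cfg = TrainConfig(max_steps=200, epochs=1000, log_stream=False)
history = train(model, train_data, val_data, cfg)

for c in (c for c in cases if c.split == "test"):
    pred = predict_volume(model, c.volume, pre)
    report = evaluate_case(c.tumor, pred, spacing=c.volume.spacing)
    print(c.case_id, {k: round(v, 3) for k, v in report.as_dict().items()
                      if isinstance(v, float)})
```

Running this (about two minutes on one CPU) prints the parameter budget and
then per-case metrics for the two held-out phantoms; with the seeds above:

```
case_008 {'dpc': 0.687, 'voe': 0.476, 'ravd': 0.036, 'assd': 1.632, 'rmsd': 2.87}
case_011 {'dpc': 0.768, 'voe': 0.377, 'ravd': 0.042, 'assd': 0.935, 'rmsd': 1.69}
```

i.e. after only 200 optimizer steps the tiny model already recovers ~70%
Dice on unseen phantoms, with sub-2 mm average surface error.

The same pipeline is scriptable from the shell:

```sh
risunet synth --n-cases 12 --shape 64 64 24 --seed 39 --out data/
risunet preprocess --images data/images --masks data/masks --out stacks/ --crop 64
risunet train --stacks stacks/ --base-channels 8 --checkpoint model.npz
risunet predict --checkpoint model.npz --images data/images --out preds/ --crop 64
risunet eval --gt data/masks --pred preds/ --out metrics.csv
risunet grid --n-cases 12 --out grid.csv      # slice-count experiment (n = 1,3,5,7)
```

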