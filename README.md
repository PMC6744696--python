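# micronet

Pixel-to-pixel nucleus detection in H&E-stained microscopy images by fully
convolutional proximity-map regression.

Detecting individual nuclei is the entry point for most quantitative
pathology: counting, morphology, tracking and downstream statistics all
start from "where are the nuclei?".  Classifying every pixel with a
sliding window is slow and ignores spatial structure, so this package
takes the regression route: point annotations of nucleus centers are
encoded as dense **proximity maps**

    y(u,v) = scale * (e^{α(1 − D/d)} − 1) / (e^α − 1)   if D ≤ d,   else 0,

where D is the Euclidean distance from pixel (u, v) to its nearest
annotated center (defaults α = 3, d = 15 px, scale = 5).  A residual
U-Net-like fully convolutional network — downsampling and upsampling paths
of residual blocks, concatenation skips, and a multi-context aggregation
path that sums upsampled feature maps from every depth — maps an H×W×3
image to an identical-sized predicted map in one forward pass.  Training
minimizes a **weighted MSE**

    L = 1/2 Σ_{u,v} (y_uv + λ ȳ) (o_uv − y_uv)²,      λ = 5,

whose per-image mean-proximity weight ȳ prevents the all-zero collapse
that plain MSE invites on background-dominated targets.  At test time,
pixels below ξ·max(map) are suppressed and the remaining local maxima are
the detected centers; detections are scored against annotations by
Hungarian matching within a 16-pixel gold-standard radius (precision,
recall, F1, mean Euclidean distance), with ξ chosen to maximize validation
F1.  Mixed-source training (a target "organ" plus pooled auxiliary data)
balances the two with a γ-weighted loss, γ·L_target + L_aux, and blocks
1–10 of the network can be frozen for fine-tuning/transfer experiments.

Everything runs on synthetic H&E-like corpora with exactly known centers
(elliptical hematoxylin-dark nuclei, eosin background, non-annotated
distractor clutter, configurable "organ styles"), generated from seeds by
`micronet.synthetic` — so the whole pipeline is testable without any
external data.  The network and its training run on a small NumPy
reverse-mode autodiff engine included in the package; no GPU framework is
required.

## Worked example

```python
from micronet import (
    SynthStyle, generate_dataset, NetworkSpec, build_network,
    DataSource, desk_profile, train, select_xi, predict_batch, detect, match,
)
from micronet.evaluation import pooled_metrics

corpus = generate_dataset(SynthStyle(), 210, 64, 64, seed=1)
train_set, val_set, test_set = corpus[:150], corpus[150:180], corpus[180:]

config = desk_profile(seed=1)                      # 64x64 tiles, 600 iterations
network = build_network(NetworkSpec(base_width=8), seed=1)
network, history = train(network, DataSource(train_set),
                         config=config, validation=val_set)

xi = select_xi(network, val_set, config.xi_grid)   # validation-selected threshold
maps = predict_batch(network, [s.image for s in test_set])
reports = [match(detect(m, xi), s.centers) for m, s in zip(maps, test_set)]
m = pooled_metrics(reports)
print(f"xi={xi}  P={m.precision:.3f}  R={m.recall:.3f}  "
      f"F1={m.f1:.3f}  ED={m.mean_ed:.2f}px")
```

On this seed the run prints

```
xi=0.6  P=1.000  R=0.976  F1=0.988  ED=0.52px
```

i.e. at the validation-selected suppression threshold ξ = 0.6, every
detection on the 30 held-out tiles is a true nucleus, 97.6% of the
annotated nuclei are found, and matched detections land half a pixel from
the true centers on average.

The same experiment is available from the shell:

```bash
micronet synth --n-per-style 10 --size 64x64 --seed 1 --out corpus/
micronet run   --config examples/desk.yaml --seed 1 --out results/desk
micronet detect --model results/checkpoint.npz --images corpus/styleA \
                --xi 0.5 --out detections.csv
micronet evaluate --detections detections.csv \
                  --annotations corpus/styleA/centers.csv --out report.json
```

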