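# parnet

Skeleton-based human physical activity recognition with a dual-stream
CNN + echo-state-network classifier (PAR-Net), a zoo of solo and
stacked-hybrid baselines, a windowing/ablation harness, and a seeded
synthetic skeleton-data generator.

## Who this is for

Researchers in human movement analytics and digital health who classify
activities from per-frame body-joint coordinates — Kinect-style 25-joint
(x, y) recordings or MediaPipe-style 33-landmark recordings stored as CSV
(one row per frame, the activity label in the last column) — and who want a
reference implementation of the dual-stream architecture together with the
standard baselines, metrics and significance-testing protocol it is
compared against. Everything runs on CPU in NumPy; no deep-learning
framework is required.

## The model

A window of `L` consecutive frames with `F` joint coordinates is classified
by two parallel streams over the same input:

* **Spatial stream** — 1-D convolutions along time (64 filters of kernel 3,
  then 128 of kernel 1, ReLU), a per-timestep dense layer of 128 units, and
  a flatten.
* **Temporal stream** — a 32-unit echo state network: input weights `W_in`
  and recurrent weights `W` are drawn once at random and frozen, with `W`
  rescaled to spectral radius ρ < 1 so the reservoir has fading memory
  (the echo state property). The state update is the leaky tanh cell

      h(t) = ((1 − a) h(t−1) + a · tanh(α (W_in [1; x(t)] + W h(t−1)))) / (1 + ε)

  with leak `a`, gain `α` and stabiliser `ε` (defaults 1, 1, 0 reduce it to
  the plain tanh recurrence). The stream summarises the trajectory by its
  moments `[mean_t h(t); mean_t h(t)²]`.

The stream outputs are concatenated, reweighted by a self-attention
feature-selection module (per-position scores, softmax-normalised, applied
multiplicatively), then classified by a 64-unit ReLU dense layer and a
softmax output. Training uses Adam at learning rate 1e-4, categorical
cross-entropy, batch size 32.

Used standalone, the ESN is trained in closed form instead: reservoir
states are collected into a matrix `H` and the readout solves the ridge
problem `W_out = (HᵀH + βI)⁻¹ Hᵀ y*`.

Baselines behind the same interface: `MLP`, `CNN`, `LSTM`, `BiLSTM`, `ESN`,
`GRU`, `BiGRU`, `CNN-GRU`, `CNN-LSTM`, `CNN-ESN`, `DualStream-NoAttention`.

All neural layers are implemented in NumPy with hand-written
backpropagation, verified against central-difference numerical gradients in
the test suite; runs are bit-for-bit reproducible from a seed.

## Worked example

`examples/train_parnet.py` generates five synthetic activity classes (two
recognisable from a single pose, two only from movement dynamics, one from
both; 100 recordings per class, 30-frame windows), trains PAR-Net for 30
epochs and evaluates on the held-out split:

```
windows: 400 train / 50 val / 50 test
parameters by component: {'cnn_stream': 34496, 'esn_stream': 0,
                          'attention': 7296, 'head': 233861, 'total': 275653}
epoch 1 -> 30: train loss 1.636 -> 0.025
test accuracy 100.0%  macro precision 100.0%  recall 100.0%  F1 100.0%
```

The reservoir stream reports 0 trainable parameters — its weights are fixed
by construction; only the convolutional stream, the attention scores and
the head train.

`examples/stream_specialization.py` shows why the temporal stream matters:

```
spatial pair : single-frame probe 1.00  shuffled-frame logistic 1.00  reservoir readout 1.00
temporal pair: single-frame probe 0.45  shuffled-frame logistic 0.50  reservoir readout 0.93
```

The temporal pair differs only in arm–leg coordination: every classifier
that ignores frame order sits at chance, while the reservoir's trajectory
moments separate the classes.

Other examples: `generate_dataset.py` (write a dataset CSV),
`esn_standalone.py` (closed-form ESN training and the echo state property),
`ablation_grid.py` (model × window-length grid with the paired t-test).

A thin CLI wraps the same library calls for scripted runs:

```bash
parnet generate --config exp.yaml --output runs/data
parnet train    --config exp.yaml --model PAR-Net --length 30 --output runs/m1
parnet ablate   --config exp.yaml --output runs/grid
```

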