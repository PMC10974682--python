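"""Probe what each stream can see: pose geometry vs movement dynamics.

Two diagnostic class pairs are generated: a *spatial* pair (same movements,
different static pose) and a *temporal* pair (same poses, different
arm-leg coordination).  Order-blind probes — a logistic model on shuffled
frames and a single-frame probe — are compared with the order-aware
reservoir readout.
"""

from sklearn.linear_model import LogisticRegression

from parnet import (ESNClassifier, ReservoirConfig, SynthSpec,
                    generate_activity_dataset, make_windows,
                    normalize_windows, shuffle_window_frames, split_dataset)


def probes(signal_mix, seed):
    spec = SynthSpec(2, 100, 30, signal_mix=signal_mix, seed=seed)
    table, _ = generate_activity_dataset(spec)
    ws = make_windows(table, 30)
    train, _, test = split_dataset(ws, (0.7, 0.1, 0.2), seed=0)

    frame_probe = LogisticRegression(max_iter=3000).fit(
        train.data[:, 0, :], train.labels)
    single = frame_probe.score(test.data[:, 0, :], test.labels)

    tr_s = shuffle_window_frames(train, 1)
    te_s = shuffle_window_frames(test, 2)
    shuffled = LogisticRegression(max_iter=3000).fit(
        tr_s.data.reshape(tr_s.n_windows, -1), tr_s.labels).score(
        te_s.data.reshape(te_s.n_windows, -1), te_s.labels)

    trn, stats = normalize_windows(train, "zscore")
    ten, _ = normalize_windows(test, "zscore", stats=stats)
    esn = ESNClassifier(ReservoirConfig(n_units=32, input_dim=50, seed=5))
    esn.fit(trn.data, trn.labels)
    reservoir = esn.score(ten.data, ten.labels)
    return single, shuffled, reservoir


for name, mix, seed in (("spatial pair ", ("spatial", "spatial"), 12),
                        ("temporal pair", ("temporal", "temporal"), 11)):
    single, shuffled, reservoir = probes(mix, seed)
    print(f"{name}: single-frame probe {single:.2f}  "
          f"shuffled-frame logistic {shuffled:.2f}  "
          f"reservoir readout {reservoir:.2f}")
# Spatial classes: every probe succeeds (a single pose gives them away).
# Temporal classes: both order-blind probes sit at chance (~0.5) while the
# reservoir separates them — the information is only in the frame ORDER.
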