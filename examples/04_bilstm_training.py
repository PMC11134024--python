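"""Train the bidirectional LSTM on windowed synthetic gaze features.

Windows carry per-step event labels; the model is supervised at every time
step and evaluated at each window's center sample.
"""

import numpy as np

from gazetune import Hyperparameters, generate_gaze
from gazetune.bilstm import BiLSTMClassifier
from gazetune.pipeline import featurize, make_windows, split_data, _standardizer

seq = generate_gaze(n_events=200, rate_hz=500.0, noise_sd=0.05, seed=0)
F, y = featurize(seq)
Xw, yw, Yw = make_windows(F, y, window=32, stride=32, return_step_labels=True)
print(f"{len(Xw)} windows of {Xw.shape[1]} samples, "
      f"class counts {np.bincount(yw)} (fixation/saccade/PSO)")

Xtr, Xte, ytr, yte = split_data(Xw, yw, fraction=0.7, seed=0)
_, _, Ytr, _ = split_data(Yw, yw, fraction=0.7, seed=0)
scale = _standardizer(Xtr)

hp = Hyperparameters(dropout=0.1, learning_rate=0.05, l2=0.003, max_epoch=15)
model = BiLSTMClassifier(input_dim=F.shape[1], hidden=32, n_classes=3, seed=0)
history = model.train(scale(Xtr), Ytr, hp, seed=0, batch_size=16)

_, pred = model.predict(scale(Xte))
acc = float(np.mean(pred == yte))
print(f"loss {history[0]['loss']:.3f} -> {history[-1]['loss']:.3f} "
      f"over {hp.max_epoch} epochs; test accuracy {acc:.3f}")
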