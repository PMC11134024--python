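"""The full pipeline: simulate -> augment -> extract -> tune -> train ->
evaluate, with the LICRSA-tuned hyperparameters.

Expect a few minutes of runtime: every optimizer fitness evaluation trains
a BiLSTM on the internal validation split.
"""

import json

from gazetune.pipeline import RunConfig, run_pipeline

cfg = RunConfig(seed=0)
cfg.dataset.n_events = 300          # shorter recording than the full runs
cfg.dataset.noise_sd = 0.02
cfg.fda.enabled = False
cfg.eval.bootstrap_B = 300

report = run_pipeline(cfg, out_dir="pipeline_out")
m = report["metrics"]
print(f"windows: {report['n_windows']} "
      f"({report['n_train']} train / {report['n_test']} test)")
print(f"chosen hyperparameters: {report['hyperparameters']}")
print(f"test macro-F1 {report['macro_f1']:.3f}, "
      f"accuracy {m['accuracy']:.2f}%, "
      f"macro AUROC {m['auroc_macro']:.3f}, "
      f"bootstrap AP median {m['ap_quantiles'][0.5]:.3f}")
print("full report: pipeline_out/report.json")
print(json.dumps(report["tuning"], indent=1)[:300])
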