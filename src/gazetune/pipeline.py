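"""End-to-end orchestration: simulate -> augment -> extract -> tune/train ->
evaluate.

A run takes a :class:`RunConfig`, generates (or loads) a gaze recording,
cuts it into fixed-length windows of per-sample kinematic features, splits
the windows into stratified 70:30 train/test partitions, optionally applies
fuzzy data augmentation to the *training partition only*, optionally renders
per-window eye images and concatenates their backbone features onto each
time step, tunes the BiLSTM hyperparameters with LICRSA on an internal
validation split (the test partition never enters any training or tuning
step — a hash guard asserts this), trains the final model, and evaluates on
the held-out partition.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.model_selection import train_test_split

from . import evaluation, fda, licrsa
from .bilstm import BiLSTMClassifier, Hyperparameters, midpoint_hyperparameters
from .features import BackboneConfig, build_backbone, extract_features
from .synthetic import CLASSES, GazeSequence, generate_eye_images, generate_gaze

log = logging.getLogger("gazetune")

__all__ = [
    "RunConfig",
    "featurize",
    "make_windows",
    "split_data",
    "run_pipeline",
]


def featurize(seq: GazeSequence) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample kinematic features plus integer labels.

    Columns: [x, y, vx, vy, speed, ax, ay, |a|] — position (degrees),
    velocity (deg/s) and acceleration (deg/s^2). Velocity separates saccades
    from fixations; acceleration exposes the oscillatory signature of
    post-saccadic oscillations.
    """
    vx = np.gradient(seq.x) * seq.rate_hz
    vy = np.gradient(seq.y) * seq.rate_hz
    ax = np.gradient(vx) * seq.rate_hz
    ay = np.gradient(vy) * seq.rate_hz
    F = np.column_stack(
        [seq.x, seq.y, vx, vy, np.hypot(vx, vy), ax, ay, np.hypot(ax, ay)]
    )
    label_idx = {c: i for i, c in enumerate(CLASSES)}
    y = np.array([label_idx[l] for l in seq.labels])
    return F, y


def make_windows(
    F: np.ndarray,
    y: np.ndarray,
    window: int = 64,
    stride: int = 32,
    return_step_labels: bool = False,
):
    """Cut a feature stream into fixed windows; window label = center-sample
    label. With ``return_step_labels`` the per-step label matrix is appended
    to the return tuple (every gaze sample carries a true event label)."""
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be positive")
    if len(F) < window:
        raise ValueError(f"stream shorter ({len(F)}) than one window ({window})")
    starts = np.arange(0, len(F) - window + 1, stride)
    X = np.stack([F[s : s + window] for s in starts])
    yw = y[starts + window // 2]
    if return_step_labels:
        Y = np.stack([y[s : s + window] for s in starts])
        return X, yw, Y
    return X, yw


def split_data(
    X: np.ndarray, y: np.ndarray, fraction: float = 0.70, seed: int = 0
):
    """Stratified train/test split with the training fraction first."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    vals, counts = np.unique(y, return_counts=True)
    if (counts < 2).any():
        small = vals[counts < 2]
        raise ValueError(f"class(es) {small.tolist()} have < 2 members")
    return train_test_split(
        X, y, train_size=fraction, random_state=seed, stratify=y
    )


# ---------------------------------------------------------------------------
# configuration blocks


@dataclass
class DatasetConfig:
    n_events: int = 600
    rate_hz: float = 500.0
    noise_sd: float = 0.05
    gaze_csv: str | None = None  # load instead of simulate


@dataclass
class FDAConfig:
    enabled: bool = True
    c: int = 3
    m: float = 2.0
    alpha: float = 0.25
    # trial-and-error alpha selection: candidate alpha-cuts scored by the
    # validation accuracy of a quick fit (1.0 = no augmentation retained)
    grid_alphas: list | None = None


@dataclass
class FeatureBlockConfig:
    enabled: bool = True
    variant: str = "tiny"
    input_size: int = 32
    feature_dim: int = 8
    image_noise_sd: float = 0.01


@dataclass
class ModelConfig:
    hidden: int = 32
    window: int = 32  # 64 ms at 500 Hz; desk-scale default
    stride: int = 32
    combine: str = "sum"
    batch_size: int = 16


@dataclass
class TuningConfig:
    enabled: bool = True
    N: int = 4
    Tmax: int = 4
    seed_offset: int = 1000
    max_fit_windows: int | None = None  # None: tune on the full fit fold


@dataclass
class EvalConfig:
    bootstrap_B: int = 1000


@dataclass
class RunConfig:
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    fda: FDAConfig = field(default_factory=FDAConfig)
    features: FeatureBlockConfig = field(default_factory=FeatureBlockConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    tuning: TuningConfig = field(default_factory=TuningConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    split: float = 0.70
    seed: int = 0
    hyperparameters: dict | None = None  # fixed hp when tuning is disabled

    def __post_init__(self):
        if not 0 < self.split < 1:
            raise ValueError("split must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        kwargs = {}
        blocks = {
            "dataset": DatasetConfig,
            "fda": FDAConfig,
            "features": FeatureBlockConfig,
            "model": ModelConfig,
            "tuning": TuningConfig,
            "eval": EvalConfig,
        }
        for key, val in raw.items():
            if key in blocks:
                kwargs[key] = blocks[key](**(val or {}))
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _array_hash(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()


class _Scaler:
    """Per-feature standardization fitted on training windows."""

    def __init__(self, X: np.ndarray):
        self.mu = X.mean(axis=(0, 1))
        self.sd = X.std(axis=(0, 1))
        self.sd[self.sd < 1e-12] = 1.0

    def __call__(self, A: np.ndarray) -> np.ndarray:
        return (A - self.mu) / self.sd

    def inverse(self, A: np.ndarray) -> np.ndarray:
        return A * self.sd + self.mu


def _standardizer(X: np.ndarray) -> _Scaler:
    """Fit per-feature mean/sd on training windows; return the transform."""
    return _Scaler(X)


def _image_features(
    X: np.ndarray, cfg: FeatureBlockConfig, seed: int
) -> np.ndarray:
    """Per-window eye-image backbone features.

    Each window is rendered as one eye image whose pupil offset encodes the
    window's gaze *displacement* vector (end minus start position): a
    fixation window yields a centered pupil, a saccade window a large offset.
    """
    displacement = X[:, -1, :2] - X[:, 0, :2]  # columns 0,1 are x,y in degrees
    images = generate_eye_images(
        n=len(X),
        size=cfg.input_size,
        seed=seed,
        noise_sd=cfg.image_noise_sd,
        gaze_targets=displacement,
    )
    bc = (
        BackboneConfig.tiny(input_size=cfg.input_size, feature_dim=cfg.feature_dim)
        if cfg.variant == "tiny"
        else BackboneConfig(variant="vgg19", input_size=cfg.input_size)
    )
    extractor = build_backbone(bc, seed=seed)
    F = extract_features(extractor, images).F
    sd = F.std(axis=0)
    sd[sd < 1e-12] = 1.0
    return (F - F.mean(axis=0)) / sd


def _augment_train(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Ytr: np.ndarray,
    cfg: FDAConfig,
    seed: int,
    alpha: float | None = None,
):
    """FDA on flattened (standardized) training windows.

    Retained cluster-center rows are reshaped back into windows; each
    augmented prototype window carries its cluster's majority window label,
    broadcast across time steps for per-step supervision.
    """
    n, T, d = Xtr.shape
    if alpha is None:
        alpha = cfg.alpha
    flat = Xtr.reshape(n, T * d)
    part = fda.fcm_fit(flat, c=cfg.c, m=cfg.m, seed=seed)
    aug = fda.augment_table(flat, part, alpha, ytr)
    X_out = aug.rows.reshape(len(aug.rows), T, d)
    n_aug = len(aug.rows) - n
    Y_out = np.vstack([Ytr, np.repeat(aug.labels[n:, None], T, axis=1)]) if n_aug else Ytr
    return X_out, aug.labels, Y_out, aug.report()


def _select_alpha(Xtr_n, ytr, Ytr, cfg: RunConfig) -> float:
    """The trial-and-error alpha-cut selection: score each candidate alpha by
    the validation accuracy of a quick fit on an internal split of the
    training partition (1.0 retains nothing, i.e. no augmentation)."""
    from sklearn.model_selection import train_test_split as _tts

    Xf, Xv, yf, yv, Yf, _ = _tts(
        Xtr_n, ytr, Ytr, train_size=0.8, random_state=cfg.seed, stratify=ytr
    )
    hp = (
        Hyperparameters(**cfg.hyperparameters)
        if cfg.hyperparameters
        else midpoint_hyperparameters()
    )

    def score(alpha: float) -> float:
        Xa, _, Ya, _ = _augment_train(Xf, yf, Yf, cfg.fda, cfg.seed, alpha=alpha)
        model = BiLSTMClassifier(
            input_dim=Xa.shape[2], hidden=cfg.model.hidden,
            n_classes=len(CLASSES), seed=cfg.seed,
        )
        model.train(Xa, Ya, hp, seed=cfg.seed, batch_size=cfg.model.batch_size)
        _, pred = model.predict(Xv)
        return float(np.mean(pred == yv))

    best, _scores = fda.alpha_grid_search(cfg.fda.grid_alphas, score)
    return best


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            report.setdefault("stage_seconds", {})[name] = round(dt, 3)
            if exc_type is not None:
                log.error("stage %s: failed after %.2fs", name, dt)
                raise RuntimeError(f"pipeline stage {name!r} failed") from exc
            log.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Timer()


def run_pipeline(cfg: RunConfig, out_dir=None, ablate_fda: bool = False) -> dict:
    """Execute the full pipeline; returns the run report dict.

    With ``ablate_fda=True`` the classifier is additionally trained without
    augmentation (same seed and hyperparameters) and both accuracies are
    reported.
    """
    report: dict = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "config": cfg.to_dict(),
    }
    out = pathlib.Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    with _stage(report, "simulate"):
        if cfg.dataset.gaze_csv:
            seq = GazeSequence.from_csv(cfg.dataset.gaze_csv)
        else:
            seq = generate_gaze(
                n_events=cfg.dataset.n_events,
                rate_hz=cfg.dataset.rate_hz,
                noise_sd=cfg.dataset.noise_sd,
                seed=cfg.seed,
            )
        if out is not None:
            seq.to_csv(out / "gaze.csv")
        F, y = featurize(seq)
        Xw, yw, Yw = make_windows(
            F, y, cfg.model.window, cfg.model.stride, return_step_labels=True
        )
        report["n_samples"] = len(seq)
        report["n_windows"] = len(Xw)

    with _stage(report, "split"):
        Xtr, Xte, ytr, yte, Ytr, Yte = train_test_split(
            Xw, yw, Yw, train_size=cfg.split, random_state=cfg.seed, stratify=yw
        )
        test_hash = _array_hash(Xte, yte)
        report["n_train"] = len(Xtr)
        report["n_test"] = len(Xte)

    scale = _standardizer(Xtr)
    Xtr_n, Xte_n = scale(Xtr), scale(Xte)

    with _stage(report, "augment"):
        if cfg.fda.enabled:
            if cfg.fda.grid_alphas:
                alpha = _select_alpha(Xtr_n, ytr, Ytr, cfg)
            else:
                alpha = cfg.fda.alpha
            Xtr_s, ytr_aug, Ytr_aug, fda_report = _augment_train(
                Xtr_n, ytr, Ytr, cfg.fda, cfg.seed, alpha=alpha
            )
        else:
            Xtr_s, ytr_aug, Ytr_aug, fda_report = Xtr_n, ytr, Ytr, {"enabled": False}
        report["fda"] = fda_report

    with _stage(report, "extract"):
        if cfg.features.enabled:
            img_tr = _image_features(
                scale.inverse(Xtr_s), cfg.features, cfg.seed
            )
            img_te = _image_features(Xte, cfg.features, cfg.seed)
            T = Xtr_s.shape[1]
            Xtr_s = np.concatenate(
                [Xtr_s, np.repeat(img_tr[:, None, :], T, axis=1)], axis=2
            )
            Xte_s = np.concatenate(
                [Xte_n, np.repeat(img_te[:, None, :], T, axis=1)], axis=2
            )
        else:
            Xte_s = Xte_n
        report["feature_width"] = int(Xtr_s.shape[2])

    with _stage(report, "tune"):
        if cfg.tuning.enabled:
            fitness = licrsa.make_bilstm_fitness(
                Xtr_s,
                ytr_aug,
                Y_steps=Ytr_aug,
                hidden=cfg.model.hidden,
                seed=cfg.seed,
                max_windows=cfg.tuning.max_fit_windows,
                batch_size=cfg.model.batch_size,
            )
            ocfg = licrsa.LICRSAConfig(
                N=cfg.tuning.N,
                Tmax=cfg.tuning.Tmax,
                seed=cfg.seed + cfg.tuning.seed_offset,
            )
            result = licrsa.optimize(fitness, licrsa.default_space(), ocfg)
            hp = Hyperparameters(**result.best.decoded)
            report["tuning"] = {
                "best_fitness": result.best.fitness,
                "n_evaluations": result.n_evaluations,
                "trace": result.trace,
            }
        elif cfg.hyperparameters is not None:
            hp = Hyperparameters(**cfg.hyperparameters)
            report["tuning"] = {"enabled": False}
        else:
            hp = midpoint_hyperparameters()
            report["tuning"] = {"enabled": False}
        report["hyperparameters"] = dataclasses.asdict(hp)

    with _stage(report, "train"):
        model = BiLSTMClassifier(
            input_dim=Xtr_s.shape[2],
            hidden=cfg.model.hidden,
            n_classes=len(CLASSES),
            seed=cfg.seed,
            combine=cfg.model.combine,
        )
        model.train(Xtr_s, Ytr_aug, hp, seed=cfg.seed,
                    batch_size=cfg.model.batch_size)
        if out is not None:
            model.save(out / "model.npz", hp=hp)

    with _stage(report, "evaluate"):
        assert _array_hash(Xte, yte) == test_hash, "test partition was modified"
        probs, pred = model.predict(Xte_s)
        counts = evaluation.confusion(yte, pred, classes=range(len(CLASSES)))
        rep = evaluation.metrics(counts)
        rep.auroc_macro = evaluation.macro_auc(yte, probs, range(len(CLASSES)), "roc")
        rep.auprc_macro = evaluation.macro_auc(yte, probs, range(len(CLASSES)), "pr")
        rep.ap_quantiles = evaluation.bootstrap_ap(
            yte, probs, range(len(CLASSES)), B=cfg.eval.bootstrap_B, seed=cfg.seed
        )
        report["metrics"] = rep.to_dict()
        report["macro_f1"] = rep.f1 / 100.0
        report["confusion"] = counts.matrix().to_dict()

    if ablate_fda:
        with _stage(report, "ablation"):
            model0 = BiLSTMClassifier(
                input_dim=Xtr_s.shape[2],
                hidden=cfg.model.hidden,
                n_classes=len(CLASSES),
                seed=cfg.seed,
                combine=cfg.model.combine,
            )
            # without augmentation: original training windows only
            n0 = len(Xtr)
            model0.train(Xtr_s[:n0], Ytr_aug[:n0], hp, seed=cfg.seed,
                         batch_size=cfg.model.batch_size)
            _, pred0 = model0.predict(Xte_s)
            c0 = evaluation.confusion(yte, pred0, classes=range(len(CLASSES)))
            r0 = evaluation.metrics(c0)
            report["ablation"] = {
                "with_fda_accuracy": report["metrics"]["accuracy"],
                "without_fda_accuracy": r0.accuracy,
                "with_fda_f1": report["metrics"]["f1"],
                "without_fda_f1": r0.f1,
            }

    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
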