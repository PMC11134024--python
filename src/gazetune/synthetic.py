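"""Synthetic gaze recordings and eye images.

Generates labeled gaze-position time series with the three oculomotor event
classes the classifier targets — fixations, saccades and post-saccadic
oscillations (PSOs) — plus low-resolution synthetic eye images (sclera, iris,
pupil) with 3-element head-pose vectors. All randomness flows through a
single :class:`numpy.random.Generator` so a fixed seed reproduces every
sample bit for bit.

The generative model is deliberately simple but velocity-faithful:

* fixations hold a stationary position (plus measurement noise),
* saccades follow a sigmoidal ballistic displacement profile,
* each saccade lands into an exponentially damped sinusoid (the PSO).

Durations and amplitudes default to standard oculomotor ranges and are all
exposed on :class:`GazeConfig`.
"""

from __future__ import annotations

import dataclasses
import enum
import io
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image


class EventClass(str, enum.Enum):
    """The three gaze-event classes."""

    FIXATION = "FIXATION"
    SACCADE = "SACCADE"
    PSO = "PSO"


CLASSES: tuple[str, ...] = tuple(c.value for c in EventClass)


@dataclass(frozen=True)
class GazeConfig:
    """Event-schedule parameters (durations in seconds, amplitudes in degrees)."""

    fixation_duration: tuple[float, float] = (0.100, 0.400)
    saccade_duration: tuple[float, float] = (0.020, 0.080)
    pso_duration: tuple[float, float] = (0.010, 0.040)
    saccade_amplitude: tuple[float, float] = (2.0, 20.0)
    pso_amplitude: tuple[float, float] = (0.3, 1.0)
    pso_frequency_hz: float = 80.0
    field_limit_deg: float = 25.0
    include_pso: bool = True


@dataclass(frozen=True)
class GazeSample:
    """One gaze sample: time (s), position (degrees of visual angle), label."""

    t: float
    x: float
    y: float
    label: str


@dataclass
class GazeSequence:
    """A uniformly sampled, labeled gaze recording."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray  # array of str tokens from CLASSES
    rate_hz: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if len(self.t) < 1:
            raise ValueError("a GazeSequence needs at least one sample")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        bad = set(np.unique(self.labels)) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown event labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def samples(self) -> list[GazeSample]:
        return [
            GazeSample(float(t), float(x), float(y), str(l))
            for t, x, y, l in zip(self.t, self.x, self.y, self.labels)
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.t, "x": self.x, "y": self.y, "label": self.labels}
        )

    def to_csv(self, path: str | pathlib.Path | io.IOBase) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.6f")

    @classmethod
    def from_csv(cls, path, rate_hz: float | None = None) -> "GazeSequence":
        df = pd.read_csv(path)
        if rate_hz is None:
            dt = np.diff(df["t"].to_numpy())
            rate_hz = float(1.0 / np.median(dt)) if len(dt) else 1.0
        return cls(
            t=df["t"].to_numpy(float),
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            labels=df["label"].to_numpy(str),
            rate_hz=rate_hz,
        )


@dataclass
class SyntheticEyeImage:
    """A rendered low-resolution eye image with head pose and gaze target.

    ``pixels`` is a 2-D (grayscale) or 3-D (RGB) float array in [0, 1];
    ``head_pose`` is (roll, pitch, yaw) in degrees; ``gaze_target`` is the
    on-screen (x, y) position in degrees the eye is looking at.
    """

    pixels: np.ndarray
    head_pose: np.ndarray
    gaze_target: tuple[float, float]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.head_pose = np.asarray(self.head_pose, dtype=float)
        if self.head_pose.shape != (3,):
            raise ValueError("head_pose must have exactly 3 elements")
        if self.pixels.size == 0:
            raise ValueError("empty image")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel intensities must lie in [0, 1]")

    def to_png(self, path: str | pathlib.Path) -> None:
        arr = (np.clip(self.pixels, 0, 1) * 255).astype(np.uint8)
        Image.fromarray(arr).save(path)


def _sigmoid_profile(n: int, steepness: float = 10.0) -> np.ndarray:
    """Ballistic displacement profile on [0, 1], exactly 0 at start, 1 at end."""
    tau = np.linspace(0.0, 1.0, n)
    s = 1.0 / (1.0 + np.exp(-steepness * (tau - 0.5)))
    return (s - s[0]) / (s[-1] - s[0])


def generate_gaze(
    n_events: int,
    rate_hz: float = 500.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    config: GazeConfig | None = None,
) -> GazeSequence:
    """Generate a labeled synthetic gaze sequence.

    Events alternate fixation -> saccade -> PSO -> fixation -> ...; ``n_events``
    counts emitted events. ``noise_sd`` (degrees) is additive Gaussian
    measurement noise applied to every sample.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if rate_hz <= 0:
        raise ValueError("rate_hz must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    cfg = config or GazeConfig()
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz

    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    labels: list[np.ndarray] = []

    pos = rng.uniform(-5.0, 5.0, size=2)
    cycle = (
        [EventClass.FIXATION, EventClass.SACCADE, EventClass.PSO]
        if cfg.include_pso
        else [EventClass.FIXATION, EventClass.SACCADE]
    )
    pending_pso_dir = np.zeros(2)

    for k in range(n_events):
        kind = cycle[k % len(cycle)]
        if kind is EventClass.FIXATION:
            dur = rng.uniform(*cfg.fixation_duration)
            n = max(1, int(round(dur * rate_hz)))
            xs.append(np.full(n, pos[0]))
            ys.append(np.full(n, pos[1]))
            labels.append(np.full(n, EventClass.FIXATION.value, dtype=object))
        elif kind is EventClass.SACCADE:
            dur = rng.uniform(*cfg.saccade_duration)
            n = max(2, int(round(dur * rate_hz)))
            amp = rng.uniform(*cfg.saccade_amplitude)
            angle = rng.uniform(0.0, 2 * np.pi)
            disp = amp * np.array([np.cos(angle), np.sin(angle)])
            # keep the trajectory inside the visual field: reflect components
            # that would overshoot the limit
            for d in range(2):
                if abs(pos[d] + disp[d]) > cfg.field_limit_deg:
                    disp[d] = -disp[d]
            prof = _sigmoid_profile(n)
            xs.append(pos[0] + disp[0] * prof)
            ys.append(pos[1] + disp[1] * prof)
            labels.append(np.full(n, EventClass.SACCADE.value, dtype=object))
            pos = pos + disp
            nrm = np.linalg.norm(disp)
            pending_pso_dir = disp / nrm if nrm > 0 else np.array([1.0, 0.0])
        else:  # PSO appended to the saccade landing
            dur = rng.uniform(*cfg.pso_duration)
            n = max(2, int(round(dur * rate_hz)))
            amp = rng.uniform(*cfg.pso_amplitude)
            tt = np.arange(1, n + 1) * dt
            damping = dur / 3.0
            wave = amp * np.exp(-tt / damping) * np.sin(
                2 * np.pi * cfg.pso_frequency_hz * tt
            )
            xs.append(pos[0] + wave * pending_pso_dir[0])
            ys.append(pos[1] + wave * pending_pso_dir[1])
            labels.append(np.full(n, EventClass.PSO.value, dtype=object))

    x = np.concatenate(xs)
    y = np.concatenate(ys)
    lab = np.concatenate(labels).astype(str)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, size=len(x))
        y = y + rng.normal(0.0, noise_sd, size=len(y))
    t = np.arange(len(x)) * dt
    return GazeSequence(t=t, x=x, y=y, labels=lab, rate_hz=rate_hz, seed=seed)


def sample_speeds(seq: GazeSequence) -> np.ndarray:
    """Sample-to-sample speed (deg/s); first sample repeats the second."""
    v = np.hypot(np.diff(seq.x), np.diff(seq.y)) * seq.rate_hz
    return np.concatenate([[v[0] if len(v) else 0.0], v])


# ---------------------------------------------------------------------------
# eye-image rendering


def _render_eye(
    size: int,
    gaze_target: tuple[float, float],
    head_pose: np.ndarray,
    noise_sd: float,
    rng: np.random.Generator,
    rgb: bool = False,
) -> SyntheticEyeImage:
    """Render sclera ellipse + iris disc + pupil disc.

    The pupil (and iris) center is displaced from the image center by a
    deterministic linear function of the gaze target and the head pose's
    pitch/yaw, emulating how gaze direction shifts the pupil in a camera frame.
    """
    h = w = size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0

    # pixels per degree of displacement; keep the pupil inside the frame
    gain = size / 64.0
    dx = gain * (gaze_target[0] + 0.5 * head_pose[2])  # yaw shifts horizontally
    dy = gain * (gaze_target[1] + 0.5 * head_pose[1])  # pitch shifts vertically
    lim = size / 4.0
    dx, dy = float(np.clip(dx, -lim, lim)), float(np.clip(dy, -lim, lim))

    img = np.full((h, w), 0.90)  # sclera fills the frame
    iris_r = size * 0.28
    pupil_r = size * 0.12
    d2 = (xx - (cx + dx)) ** 2 + (yy - (cy + dy)) ** 2
    img[d2 <= iris_r**2] = 0.45
    img[d2 <= pupil_r**2] = 0.10
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, 1.0)
    if rgb:
        img = np.stack([img, img * 0.97, img * 0.95], axis=-1)
        img = np.clip(img, 0.0, 1.0)
    return SyntheticEyeImage(pixels=img, head_pose=head_pose, gaze_target=gaze_target)


def generate_eye_images(
    n: int,
    size: int = 32,
    seed: int = 0,
    noise_sd: float = 0.0,
    rgb: bool = False,
    gaze_targets: np.ndarray | None = None,
    head_poses: np.ndarray | None = None,
) -> list[SyntheticEyeImage]:
    """Render ``n`` synthetic low-resolution eye images.

    Gaze targets (degrees) and head poses (roll, pitch, yaw in degrees) are
    drawn from the generator unless supplied explicitly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if size < 16:
        raise ValueError("size must be >= 16")
    rng = np.random.default_rng(seed)
    if gaze_targets is None:
        gaze_targets = rng.uniform(-20.0, 20.0, size=(n, 2))
    if head_poses is None:
        head_poses = rng.uniform(-15.0, 15.0, size=(n, 3))
    gaze_targets = np.asarray(gaze_targets, float).reshape(n, 2)
    head_poses = np.asarray(head_poses, float).reshape(n, 3)
    return [
        _render_eye(size, (float(g[0]), float(g[1])), p, noise_sd, rng, rgb=rgb)
        for g, p in zip(gaze_targets, head_poses)
    ]


def save_eye_images(
    images: list[SyntheticEyeImage], out_dir: str | pathlib.Path
) -> pd.DataFrame:
    """Write PNGs plus the sidecar CSV ``image,roll,pitch,yaw,gx,gy``."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, im in enumerate(images):
        name = f"eye_{i:05d}.png"
        im.to_png(out / name)
        rows.append(
            {
                "image": name,
                "roll": im.head_pose[0],
                "pitch": im.head_pose[1],
                "yaw": im.head_pose[2],
                "gx": im.gaze_target[0],
                "gy": im.gaze_target[1],
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out / "images.csv", index=False, float_format="%.6f")
    return df
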