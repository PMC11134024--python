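"""Reptile search algorithm with Lévy flight and interactive crossover (LICRSA).

A population ("crocodiles") of candidate positions in the normalized unit
cube is evolved through four iteration-quartile phases — high walking and
belly walking (encircling / exploration), then hunting coordination and
cooperation (exploitation) — with Lévy-flight step lengths (Mantegna method),
followed each iteration by an interactive crossover that recombines two
random half-populations toward the best solution, and a greedy elimination
that keeps the better of each crocodile's old and candidate position.

Auxiliary coefficients follow the base reptile-search-algorithm definitions:
hunting operator ``phi = y* . P``, reduce function
``RF = (y* - y_r1) / (y* + eps)``, evolutionary sense
``ES(l) = 2 r3 (1 - l/Tmax)`` with ``r3 ~ U(-1, 1)``, and percentage
difference ``P = a + (y - mean(y)) / (y* + eps)`` with ``a = 0.1`` (unit
cube, so UB - LB = 1). The crossover control ``CF(l) = (1 - l/Tmax)^(2 l/Tmax)``
decays from 1 to 0 over the run.

The default search space is the four BiLSTM training hyperparameters:
dropout in [0.1, 0.4], learning rate in [0.003, 0.1], L2 in [0.003, 0.1],
and max-epoch in {5, 10, 15, 20}.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .bilstm import BiLSTMClassifier, Hyperparameters

__all__ = [
    "Dimension",
    "SearchSpace",
    "LICRSAConfig",
    "Crocodile",
    "levy_step",
    "cf_schedule",
    "encircle_update",
    "hunt_update",
    "interactive_crossover",
    "eliminate",
    "optimize",
    "random_search",
    "default_space",
    "make_bilstm_fitness",
]


@dataclass(frozen=True)
class Dimension:
    """One search dimension: continuous with bounds, or categorical choices."""

    name: str
    kind: str  # 'continuous' | 'categorical'
    bounds: tuple[float, float] | None = None
    choices: tuple | None = None

    def __post_init__(self):
        if self.kind == "continuous":
            if self.bounds is None or not np.isfinite(self.bounds).all():
                raise ValueError(f"{self.name}: continuous dims need finite bounds")
            if self.bounds[0] >= self.bounds[1]:
                raise ValueError(f"{self.name}: lower bound must be < upper bound")
        elif self.kind == "categorical":
            if not self.choices:
                raise ValueError(f"{self.name}: categorical dims need choices")
        else:
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")

    def decode(self, v: float):
        """Map a unit-interval coordinate to the dimension's native value."""
        v = float(np.clip(v, 0.0, 1.0))
        if self.kind == "continuous":
            lo, hi = self.bounds
            return lo + v * (hi - lo)
        k = len(self.choices)
        return self.choices[min(int(v * k), k - 1)]


@dataclass(frozen=True)
class SearchSpace:
    """An ordered list of dimensions; optimization runs in [0, 1]^d."""

    dims: tuple[Dimension, ...]

    @property
    def d(self) -> int:
        return len(self.dims)

    def decode(self, position: np.ndarray) -> dict:
        position = np.asarray(position, dtype=float)
        if (position < -1e-12).any() or (position > 1 + 1e-12).any():
            warnings.warn("position outside the unit cube; clipping", stacklevel=2)
        return {dim.name: dim.decode(v) for dim, v in zip(self.dims, position)}


def default_space() -> SearchSpace:
    """The 4-dimensional BiLSTM hyperparameter domain."""
    return SearchSpace(
        dims=(
            Dimension("dropout", "continuous", bounds=(0.1, 0.4)),
            Dimension("learning_rate", "continuous", bounds=(0.003, 0.1)),
            Dimension("l2", "continuous", bounds=(0.003, 0.1)),
            Dimension("max_epoch", "categorical", choices=(5, 10, 15, 20)),
        )
    )


def continuous_space(bounds: list[tuple[float, float]], prefix: str = "x") -> SearchSpace:
    """Helper for plain continuous test problems."""
    return SearchSpace(
        dims=tuple(
            Dimension(f"{prefix}{i}", "continuous", bounds=tuple(b))
            for i, b in enumerate(bounds)
        )
    )


def decode_hyperparameters(params: dict) -> Hyperparameters:
    return Hyperparameters(**params)


@dataclass(frozen=True)
class LICRSAConfig:
    """Optimizer configuration.

    ``mu`` and ``lam`` are the search-accuracy and scale handles (both fixed
    at 0.1); ``gamma`` is the Lévy exponent (0 < gamma <= 2); ``epsilon``
    guards divisions. ``crossover=False`` together with ``levy=False`` gives
    the plain-RSA ablation mode (uniform steps, no recombination).
    """

    N: int = 20
    Tmax: int = 40
    mu: float = 0.1
    lam: float = 0.1
    gamma: float = 1.5
    epsilon: float = 1e-10
    seed: int = 0
    crossover: bool = True
    levy: bool = True
    bernoulli_c: bool = False

    def __post_init__(self):
        if self.N < 4:
            raise ValueError("population size N must be >= 4")
        if self.N % 2:
            raise ValueError("population size N must be even (crossover halves)")
        if self.Tmax < 4:
            raise ValueError("Tmax must be >= 4 (four phases)")
        if not 0 < self.gamma <= 2:
            raise ValueError("gamma must lie in (0, 2]")


@dataclass
class Crocodile:
    """One candidate: normalized position, fitness, decoded parameters."""

    y: np.ndarray
    fitness: float = math.inf
    decoded: dict | None = None


def levy_step(
    gamma: float, dim: int, rng: np.random.Generator
) -> np.ndarray:
    """Heavy-tailed Lévy-flight steps by the Mantegna method."""
    if not 0 < gamma <= 2:
        raise ValueError("gamma must lie in (0, 2]")
    num = math.gamma(1 + gamma) * math.sin(math.pi * gamma / 2)
    den = math.gamma((1 + gamma) / 2) * gamma * 2 ** ((gamma - 1) / 2)
    sigma_u = (num / den) ** (1 / gamma)
    u = rng.normal(0.0, sigma_u, size=dim)
    v = rng.normal(0.0, 1.0, size=dim)
    return u / np.abs(v) ** (1.0 / gamma)


def cf_schedule(l: int, Tmax: int) -> float:
    """Crossover control CF = (1 - l/Tmax)^(2 l/Tmax); 1 at l=0, 0 at l=Tmax."""
    if l < 0 or l > Tmax:
        raise ValueError("iteration l must lie in [0, Tmax]")
    base = 1.0 - l / Tmax
    return float(base ** (2.0 * l / Tmax))


def _steps(cfg: LICRSAConfig, d: int, rng: np.random.Generator) -> np.ndarray:
    """Lévy steps, or U(0,1) draws in plain-RSA mode."""
    if cfg.levy:
        return levy_step(cfg.gamma, d, rng)
    return rng.random(d)


def _auxiliaries(y, best, pop, cfg, l, rng):
    """RF, ES, P, phi for one crocodile (vectorized over dimensions)."""
    r1 = rng.integers(0, len(pop))
    RF = (best - pop[r1].y) / (best + cfg.epsilon)
    r3 = rng.uniform(-1.0, 1.0)
    ES = 2.0 * r3 * (1.0 - l / cfg.Tmax)
    P = 0.1 + (y - y.mean()) / (best + cfg.epsilon)  # UB - LB = 1 in unit cube
    phi = best * P
    return RF, ES, P, phi, r1


def encircle_update(
    croc: Crocodile,
    best: np.ndarray,
    pop: list[Crocodile],
    l: int,
    cfg: LICRSAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exploration phases: high walking (first quartile), then belly walking."""
    if l >= 2 * cfg.Tmax / 4:
        raise ValueError("encircling applies only to the first two quartiles")
    d = len(croc.y)
    RF, ES, P, phi, r1 = _auxiliaries(croc.y, best, pop, cfg, l, rng)
    lev = _steps(cfg, d, rng)
    if l <= cfg.Tmax / 4:  # high walking
        y_new = best * (-phi) * cfg.mu - RF * cfg.lam * lev
    else:  # belly walking
        y_new = best * pop[r1].y * ES * cfg.lam * lev
    return np.clip(y_new, 0.0, 1.0)


def hunt_update(
    croc: Crocodile,
    best: np.ndarray,
    pop: list[Crocodile],
    l: int,
    cfg: LICRSAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Exploitation phases: hunting coordination, then cooperation."""
    if l < 2 * cfg.Tmax / 4:
        raise ValueError("hunting applies only to the last two quartiles")
    d = len(croc.y)
    RF, ES, P, phi, _ = _auxiliaries(croc.y, best, pop, cfg, l, rng)
    lev = _steps(cfg, d, rng)
    if l < 3 * cfg.Tmax / 4:  # hunting coordination
        y_new = best * P * cfg.lam * lev
    else:  # hunting cooperation
        y_new = best - phi * cfg.epsilon - RF * cfg.lam * lev
    return np.clip(y_new, 0.0, 1.0)


def interactive_crossover(
    positions: np.ndarray,
    best: np.ndarray,
    l: int,
    cfg: LICRSAConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recombine two random half-populations toward the best solution.

    For paired crocodiles k1, k2:
        y_k1 <- y_k1 + CF (y* - y_k1) + c1 (y_k1 - y_k2)
        y_k2 <- y_k2 + CF (y* - y_k2) + c2 (y_k2 - y_k1)
    with c1, c2 ~ U(0, 1) (or Bernoulli draws when ``bernoulli_c``).
    """
    n = len(positions)
    if n % 2:
        raise ValueError("population must be even for crossover")
    cf = cf_schedule(l, cfg.Tmax)
    perm = rng.permutation(n)
    k1, k2 = perm[: n // 2], perm[n // 2:]
    if cfg.bernoulli_c:
        c1 = rng.integers(0, 2, size=(n // 2, 1)).astype(float)
        c2 = rng.integers(0, 2, size=(n // 2, 1)).astype(float)
    else:
        c1 = rng.random((n // 2, 1))
        c2 = rng.random((n // 2, 1))
    out = positions.copy()
    a, b = positions[k1], positions[k2]
    out[k1] = a + cf * (best - a) + c1 * (a - b)
    out[k2] = b + cf * (best - b) + c2 * (b - a)
    return np.clip(out, 0.0, 1.0)


def eliminate(old: Crocodile, candidate: Crocodile) -> Crocodile:
    """Greedy survivor selection; exact ties keep the old position."""
    if not math.isfinite(old.fitness) and not math.isfinite(candidate.fitness):
        return old
    for c in (old, candidate):
        if c.fitness is None:
            raise ValueError("both crocodiles must carry an evaluated fitness")
    return candidate if candidate.fitness < old.fitness else old


def _evaluate(f, space, y, cache):
    decoded = space.decode(y)
    key = tuple(
        round(v, 9) if isinstance(v, float) else v for v in decoded.values()
    )
    if cache is not None and key in cache:
        return cache[key], decoded
    try:
        val = float(f(decoded))
    except FloatingPointError:
        val = math.inf
    if not math.isfinite(val):
        warnings.warn("fitness returned a non-finite value; penalizing", stacklevel=2)
        val = math.inf
    if cache is not None:
        cache[key] = val
    return val, decoded


@dataclass
class OptimizeResult:
    """Best crocodile plus the best-so-far convergence trace."""

    best: Crocodile
    trace: list[float]
    n_evaluations: int
    config: LICRSAConfig

    def log_rows(self) -> list[dict]:
        return [{"iteration": i, "best_fitness": v} for i, v in enumerate(self.trace)]


def optimize(
    f,
    space: SearchSpace,
    cfg: LICRSAConfig,
    use_cache: bool = True,
) -> OptimizeResult:
    """Minimize ``f(decoded_params)`` over the search space.

    Each iteration runs the quartile-scheduled phase update (with greedy
    elimination of each candidate against its crocodile), then — unless
    disabled — the interactive crossover of the surviving population's
    current locations (again followed by elimination), then the best-solution
    update. The returned trace of best-so-far fitness has exactly ``Tmax``
    entries and is non-increasing.
    """
    rng = np.random.default_rng(cfg.seed)
    d = space.d
    cache: dict | None = {} if use_cache else None
    n_eval = 0

    pop = [Crocodile(y=rng.random(d)) for _ in range(cfg.N)]
    for c in pop:
        c.fitness, c.decoded = _evaluate(f, space, c.y, cache)
        n_eval += 1
    best = min(pop, key=lambda c: c.fitness)
    best = Crocodile(y=best.y.copy(), fitness=best.fitness, decoded=best.decoded)

    def _select(cand: np.ndarray) -> Crocodile:
        nonlocal best, n_eval
        for i, c in enumerate(pop):
            fit, decoded = _evaluate(f, space, cand[i], cache)
            n_eval += 1
            survivor = eliminate(c, Crocodile(y=cand[i], fitness=fit, decoded=decoded))
            pop[i] = survivor
            if survivor.fitness < best.fitness:
                best = Crocodile(
                    y=survivor.y.copy(),
                    fitness=survivor.fitness,
                    decoded=survivor.decoded,
                )
        return best

    trace: list[float] = []
    for l in range(1, cfg.Tmax + 1):
        if l < 2 * cfg.Tmax / 4:
            cand = np.array(
                [encircle_update(c, best.y, pop, l, cfg, rng) for c in pop]
            )
        else:
            cand = np.array(
                [hunt_update(c, best.y, pop, l, cfg, rng) for c in pop]
            )
        _select(cand)
        if cfg.crossover:
            positions = np.array([c.y for c in pop])
            _select(interactive_crossover(positions, best.y, l, cfg, rng))
        trace.append(best.fitness)
    return OptimizeResult(best=best, trace=trace, n_evaluations=n_eval, config=cfg)


def random_search(
    f, space: SearchSpace, n_evaluations: int, seed: int = 0
) -> OptimizeResult:
    """Uniform random sampling baseline with the same evaluation budget."""
    rng = np.random.default_rng(seed)
    best = None
    trace = []
    for _ in range(n_evaluations):
        y = rng.random(space.d)
        fit, decoded = _evaluate(f, space, y, None)
        if best is None or fit < best.fitness:
            best = Crocodile(y=y, fitness=fit, decoded=decoded)
        trace.append(best.fitness)
    cfg = LICRSAConfig(N=4, Tmax=max(4, n_evaluations), seed=seed)
    return OptimizeResult(best=best, trace=trace, n_evaluations=n_evaluations, config=cfg)


def make_bilstm_fitness(
    X: np.ndarray,
    y: np.ndarray,
    Y_steps: np.ndarray | None = None,
    hidden: int = 32,
    seed: int = 0,
    val_fraction: float = 0.2,
    max_windows: int | None = None,
    batch_size: int = 16,
):
    """Fitness = 1 - validation accuracy of a BiLSTM trained with the candidate.

    The training partition is split internally (stratified on the window
    labels ``y``) into fit and validation folds; the held-out test partition
    never enters here. ``Y_steps`` supplies per-step labels for training when
    available; validation accuracy is always on the window (center) labels.
    ``max_windows`` subsamples the fit fold to bound the cost of one fitness
    evaluation.
    """
    from sklearn.model_selection import train_test_split

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if Y_steps is None:
        Xf, Xv, yf, yv = train_test_split(
            X, y, test_size=val_fraction, random_state=seed, stratify=y
        )
        Yf = yf
    else:
        Xf, Xv, yf, yv, Yf, _ = train_test_split(
            X, y, np.asarray(Y_steps, dtype=int),
            test_size=val_fraction, random_state=seed, stratify=y,
        )
    if max_windows is not None and len(Xf) > max_windows:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(Xf), size=max_windows, replace=False)
        Xf, Yf = Xf[idx], Yf[idx]
    n_classes = int(y.max()) + 1

    def fitness(params: dict) -> float:
        hp = Hyperparameters(**params)
        model = BiLSTMClassifier(
            input_dim=X.shape[2], hidden=hidden, n_classes=n_classes, seed=seed
        )
        model.train(Xf, Yf, hp, seed=seed, batch_size=batch_size)
        _, pred = model.predict(Xv)
        return 1.0 - float(np.mean(pred == yv))

    return fitness
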