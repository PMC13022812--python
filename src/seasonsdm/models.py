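"""MLP presence-background classifiers and the three training regimes.

All three model families share one architecture: a multilayer perceptron with
two hidden layers of 40 rectified-linear units and a single sigmoid output
giving the occurrence probability.  They differ in their inputs and training:

* M0 (time-static): one network on annual-mean predictors.
* M1 (seasonal independent): four networks, one per season, each on the
  season's three monthly predictor values, trained independently.
* M2 (seasonal concatenated): four networks whose inputs additionally carry
  the previous season's predicted probability and a chain-start flag; trained
  sequentially — each epoch draws a random starting season, takes a training
  step there with the neutral chain state (prev 0.5, flag 0), then walks the
  remaining three seasons in cyclic order, inferring the previous-season
  probabilities with the current weights (no gradient through the chain)
  before each step (flag 1).

Training is full-batch binary cross-entropy with Adam (lr 0.01, at most 250
epochs) and early stopping on validation loss; for M2 the stopping criterion
is the global validation loss, the sum over seasons of each season's summed
loss divided by that season's sample size, so that small seasons count as
much as large ones.  Everything is plain NumPy and bit-deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import chained_schema, seasonal_schema, static_schema
from .grid_climate import ClimateStack, cell_of
from .occurrences import SEASONS
from . import features as F

CHAIN_LENGTH = 4  # a prediction chain spans the target season and its 3 predecessors

_EPS = 1e-12


class TrainingError(ValueError):
    pass


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    max_epochs: int = 250
    seed: int = 0
    hidden: tuple[int, int] = (40, 40)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


class MLP:
    """Two-hidden-layer ReLU perceptron with sigmoid output, plain NumPy."""

    def __init__(self, params: list[np.ndarray]):
        self.W1, self.b1, self.W2, self.b2, self.W3, self.b3 = params

    @classmethod
    def init(cls, input_dim: int, hidden: tuple[int, int] = (40, 40), seed: int = 0) -> "MLP":
        """Uniform fan-in initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
        rng = np.random.default_rng(seed)
        h1, h2 = hidden

        def u(fan_in, shape):
            b = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-b, b, shape)

        return cls([
            u(input_dim, (input_dim, h1)), u(input_dim, (h1,)),
            u(h1, (h1, h2)), u(h1, (h2,)),
            u(h2, (h2, 1)), u(h2, (1,)),
        ])

    @property
    def params(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    @property
    def input_dim(self) -> int:
        return self.W1.shape[0]

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params)

    def copy(self) -> "MLP":
        return MLP([p.copy() for p in self.params])

    def forward(self, X: np.ndarray, cache: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        a1 = np.maximum(X @ self.W1 + self.b1, 0.0)
        a2 = np.maximum(a1 @ self.W2 + self.b2, 0.0)
        z3 = (a2 @ self.W3 + self.b3)[:, 0]
        p = 1.0 / (1.0 + np.exp(-z3))
        if cache:
            return p, (X, a1, a2)
        return p

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray):
        """Mean binary cross-entropy and gradients for one full batch."""
        p, (X, a1, a2) = self.forward(X, cache=True)
        y = np.asarray(y, dtype=float)
        n = len(y)
        pc = np.clip(p, _EPS, 1.0 - _EPS)
        loss = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
        dz3 = (p - y)[:, None] / n                      # sigmoid + BCE shortcut
        gW3 = a2.T @ dz3
        gb3 = dz3.sum(axis=0)
        da2 = dz3 @ self.W3.T
        dz2 = da2 * (a2 > 0)
        gW2 = a1.T @ dz2
        gb2 = dz2.sum(axis=0)
        da1 = dz2 @ self.W2.T
        dz1 = da1 * (a1 > 0)
        gW1 = X.T @ dz1
        gb1 = dz1.sum(axis=0)
        return loss, [gW1, gb1, gW2, gb2, gW3, gb3]


class Adam:
    """Adaptive-moment gradient descent (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def mean_bce(p: np.ndarray, y: np.ndarray) -> float:
    pc = np.clip(p, _EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=float)
    return float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))


@dataclass
class SeasonalModelSet:
    """A trained family: the network(s), standardizers, thresholds, history."""

    family: str                                   # "M0" | "M1" | "M2"
    models: dict[str, MLP]                        # {"static": ...} or per season
    standardizers: dict[str, object] = field(default_factory=dict)
    thresholds: dict[str, float] | None = None    # th_s, filled by evaluation
    history: dict[str, list] = field(default_factory=dict)
    best_epoch: dict[str, int] = field(default_factory=dict)

    def schema(self, variables, season: str | None = None) -> tuple:
        if self.family == "M0":
            return static_schema(variables)
        if self.family == "M1":
            return seasonal_schema(variables, season)
        return chained_schema(variables, season)


def _check_classes(y: np.ndarray, what: str) -> None:
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise TrainingError(f"{what} must contain both presence and background samples")


def _fit_single(X_train, y_train, X_val, y_val, cfg: TrainConfig, seed: int):
    """Full-batch Adam training of one MLP with early stopping on val loss."""
    _check_classes(y_train, "training set")
    _check_classes(y_val, "validation set")
    model = MLP.init(X_train.shape[1], cfg.hidden, seed=seed)
    opt = Adam(model.params, cfg.learning_rate)
    history = []
    best = (np.inf, None, -1)
    for epoch in range(1, cfg.max_epochs + 1):
        loss, grads = model.loss_and_grads(X_train, y_train)
        if not np.isfinite(loss):
            raise TrainingError(f"non-finite training loss at epoch {epoch}")
        opt.step(model.params, grads)
        val_loss = mean_bce(model.forward(X_val), y_val)
        history.append((loss, val_loss))
        if val_loss < best[0]:
            best = (val_loss, model.copy(), epoch)
    return best[1], history, best[2]


def train_static(X_train, y_train, X_val, y_val, cfg: TrainConfig) -> SeasonalModelSet:
    """Train the time-static family (M0): one network on annual features."""
    model, history, best = _fit_single(X_train, y_train, X_val, y_val, cfg, seed=cfg.seed)
    return SeasonalModelSet("M0", {"static": model},
                            history={"static": history}, best_epoch={"static": best})


def train_seasonal_independent(train: dict, val: dict, cfg: TrainConfig) -> SeasonalModelSet:
    """Train the seasonal independent family (M1): four networks, one per season.

    ``train`` and ``val`` map season -> (X, y).  Per-season early stopping; each
    season's initialization seed is derived from cfg.seed + season index, so the
    result is independent of training order.
    """
    models, history, best = {}, {}, {}
    for i, s in enumerate(SEASONS):
        if s not in train or len(train[s][1]) == 0:
            raise TrainingError(f"season {s!r} has no training samples")
        m, h, b = _fit_single(*train[s], *val[s], cfg, seed=cfg.seed + i)
        models[s], history[s], best[s] = m, h, b
    return SeasonalModelSet("M1", models, history=history, best_epoch=best)


@dataclass
class ChainedSeasonData:
    """Inputs for the concatenated family.

    For each target season s: labels ``y[s]`` for that season's samples and
    ``Z[s][t]`` — the standardized 3V-dim seasonal climate features of *every*
    season t evaluated at season-s sample locations (the chain walks through
    other seasons' models at the same locations).
    """

    y: dict[str, np.ndarray]
    Z: dict[str, dict[str, np.ndarray]]


def _chain_forward(models: dict[str, MLP], Z_at_points: dict[str, np.ndarray],
                   chain_seasons: list[str]) -> np.ndarray:
    """Run the model chain along ``chain_seasons`` at fixed sample locations.

    The first chain step uses the neutral state (prev 0.5, start flag 0); later
    steps feed the previous model's probabilities with the flag set to 1.
    Returns the final season's probabilities.
    """
    n = Z_at_points[chain_seasons[0]].shape[0]
    prev = np.full(n, 0.5)
    for j, t in enumerate(chain_seasons):
        d = 0.0 if j == 0 else 1.0
        Xin = np.column_stack([Z_at_points[t], prev, np.full(n, d)])
        prev = models[t].forward(Xin)
    return prev


def chain_seasons_for(target: str) -> list[str]:
    """The 4-season cyclic chain ending at ``target`` (starts 3 seasons back)."""
    i = SEASONS.index(target)
    return [SEASONS[(i + 1 + k) % 4] for k in range(CHAIN_LENGTH)]


def global_validation_loss(models: dict[str, MLP], val: ChainedSeasonData) -> float:
    """Sum over seasons of (summed seasonal loss / seasonal sample size).

    Equal to the sum of per-season mean losses: seasons weigh equally no matter
    their sample counts.  Chain states are the inference-time 3-step chaining.
    """
    total = 0.0
    for s in SEASONS:
        p = _chain_forward(models, val.Z[s], chain_seasons_for(s))
        total += mean_bce(p, val.y[s])
    return total


def train_concatenated(train: ChainedSeasonData, val: ChainedSeasonData,
                       cfg: TrainConfig) -> SeasonalModelSet:
    """Train the seasonal concatenated family (M2) sequentially.

    Per epoch: draw a starting season uniformly; one full-batch step on it with
    the neutral chain state; then for the next three seasons in cyclic order,
    infer the running chain probabilities at the season's sample locations with
    the current weights (treated as constants — no gradient flows through the
    chain) and take a full-batch step with the start flag at 1.  Early stopping
    saves the epoch minimizing the global validation loss, recomputed from the
    current weights every epoch.
    """
    for s in SEASONS:
        if s not in train.y or len(train.y[s]) == 0:
            raise TrainingError(f"season {s!r} has no training samples")
        _check_classes(train.y[s], f"training season {s!r}")
        _check_classes(val.y[s], f"validation season {s!r}")

    models = {s: MLP.init(train.Z[s][s].shape[1] + 2, cfg.hidden, seed=cfg.seed + i)
              for i, s in enumerate(SEASONS)}
    opts = {s: Adam(models[s].params, cfg.learning_rate) for s in SEASONS}
    start_rng = np.random.default_rng(cfg.seed)

    history = []
    best = (np.inf, None, -1)
    for epoch in range(1, cfg.max_epochs + 1):
        start = int(start_rng.integers(4))
        epoch_losses = {}
        for k in range(CHAIN_LENGTH):
            s = SEASONS[(start + k) % 4]
            n_s = len(train.y[s])
            if k == 0:
                prev = np.full(n_s, 0.5)
                d = 0.0
            else:
                chain = [SEASONS[(start + j) % 4] for j in range(k)]
                prev = _chain_forward(models, train.Z[s], chain)
                d = 1.0
            Xin = np.column_stack([train.Z[s][s], prev, np.full(n_s, d)])
            loss, grads = models[s].loss_and_grads(Xin, train.y[s])
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}, season {s}")
            opts[s].step(models[s].params, grads)
            epoch_losses[s] = loss
        val_loss = global_validation_loss(models, val)
        history.append((sum(epoch_losses.values()), val_loss))
        if val_loss < best[0]:
            best = (val_loss, {s: m.copy() for s, m in models.items()}, epoch)

    return SeasonalModelSet("M2", best[1], history={"global": history},
                            best_epoch={"global": best[2]})


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict_cells(model_set: SeasonalModelSet, stack: ClimateStack,
                  rows: np.ndarray, cols: np.ndarray) -> dict[str, np.ndarray]:
    """Per-season occurrence probabilities at the given grid cells.

    M0 returns the same (season-free) probability under each season key; M1
    applies each season's model; M2 starts each target season's chain three
    seasons back with the neutral state and propagates probabilities forward.
    """
    if not model_set.models:
        raise RuntimeError("model set has no trained models")
    std = model_set.standardizers
    if model_set.family == "M0":
        X = std["static"].transform(F.static_matrix(stack, rows, cols))
        p = model_set.models["static"].forward(X)
        return {s: p for s in SEASONS}
    Z = {t: std[t].transform(F.seasonal_matrix(stack, t, rows, cols)) for t in SEASONS}
    if model_set.family == "M1":
        return {s: model_set.models[s].forward(Z[s]) for s in SEASONS}
    return {s: _chain_forward(model_set.models, Z, chain_seasons_for(s)) for s in SEASONS}


def predict_points(model_set: SeasonalModelSet, points: np.ndarray,
                   stack: ClimateStack) -> dict[str, np.ndarray]:
    """Per-season probabilities at (lat, lon) points (see :func:`predict_cells`)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rows, cols = cell_of(pts[:, 0], pts[:, 1], stack.grid)
    return predict_cells(model_set, stack, np.atleast_1d(rows), np.atleast_1d(cols))


def mask_chain_inputs(model: MLP) -> MLP:
    """Copy of a chained-family model with the chain input weights zeroed.

    Zeroing the first-layer rows of the last two inputs (prev_prob, start flag)
    reduces an M2 season model exactly to a seasonal-only model on the 3V
    climate block — the reduction identity used in tests.
    """
    m = model.copy()
    m.W1[-2:, :] = 0.0
    return m


# ---------------------------------------------------------------------------
# Checkpoints: weights as npz + JSON manifest + history CSV
# ---------------------------------------------------------------------------

def save_model_set(model_set: SeasonalModelSet, directory) -> None:
    import json
    from pathlib import Path

    from .features import Standardizer  # noqa: F401  (type for manifest round-trip)

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for key, model in model_set.models.items():
        for i, p in enumerate(model.params):
            arrays[f"{key}__{i}"] = p
    np.savez(directory / "weights.npz", **arrays)
    manifest = {
        "family": model_set.family,
        "keys": list(model_set.models.keys()),
        "input_dims": {k: m.input_dim for k, m in model_set.models.items()},
        "hidden": [model_set.models[k].W2.shape[0] for k in model_set.models][:1],
        "thresholds": model_set.thresholds,
        "best_epoch": model_set.best_epoch,
        "standardizers": {k: s.to_dict() for k, s in model_set.standardizers.items()},
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    lines = ["key,epoch,train_loss,val_loss"]
    for key, hist in model_set.history.items():
        for e, (tr, va) in enumerate(hist, start=1):
            lines.append(f"{key},{e},{tr!r},{va!r}")
    (directory / "history.csv").write_text("\n".join(lines) + "\n")


def load_model_set(directory) -> SeasonalModelSet:
    import json
    from pathlib import Path

    from .features import Standardizer

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    models = {}
    with np.load(directory / "weights.npz") as npz:
        for key in manifest["keys"]:
            models[key] = MLP([npz[f"{key}__{i}"] for i in range(6)])
    stds = {k: Standardizer.from_dict(d)
            for k, d in manifest["standardizers"].items()}
    return SeasonalModelSet(manifest["family"], models, standardizers=stds,
                            thresholds=manifest["thresholds"],
                            best_epoch=manifest.get("best_epoch", {}))
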