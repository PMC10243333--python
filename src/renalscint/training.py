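"""Model training on short-time/full-time pairs and count-scale inference.

Protocol: MSE loss in standardized space, Adam with initial learning rate
1e-4, batch size 8, a fixed budget of 50 epochs (no early stopping), and
post-hoc selection of the epoch with minimum validation loss — the
returned model carries the best-validation checkpoint, not the final
weights.  Data order is reshuffled each epoch from the config seed, so a
run is exactly reproducible on one machine.

Each pair is standardized with the *input* image's mean/sd (see the
dataset module); validation loss is computed in the same standardized
space as the training objective.  ``predict`` runs the inverse path:
standardize -> forward (eval mode, frozen BN statistics) ->
inverse-standardize -> clip at zero, returning a count-scale image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataset import StandardizationParams, TrainingPair, inverse_standardize, standardize
from .nn import Adam, Module

__all__ = ["TrainConfig", "TrainHistory", "train", "predict"]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    max_epochs: int = 50
    batch_size: int = 8
    seed: int = 0
    device: str = "cpu"  # descriptor only; execution is NumPy on CPU


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = float("inf")


def _standardized_arrays(pairs: list[TrainingPair]) -> tuple[np.ndarray, np.ndarray]:
    """Stack pairs as (N, 1, H, W) arrays standardized by each input's stats."""
    xs, ts = [], []
    for p in pairs:
        xstd, params = standardize(p.short_time)
        tstd = (np.asarray(p.full_time, dtype=float) - params.mean) / params.sd
        xs.append(xstd[None])
        ts.append(tstd[None])
    return np.stack(xs), np.stack(ts)


def _epoch_loss(model: Module, x: np.ndarray, t: np.ndarray, batch_size: int) -> float:
    """Mean per-pixel MSE over a dataset, eval mode, no gradients."""
    total, n = 0.0, 0
    for i in range(0, len(x), batch_size):
        xb, tb = x[i : i + batch_size], t[i : i + batch_size]
        pred = model.forward(xb)
        total += float(np.sum((pred - tb) ** 2))
        n += tb.size
    return total / n


def train(
    model: Module,
    train_pairs: list[TrainingPair],
    val_pairs: list[TrainingPair],
    config: TrainConfig | None = None,
) -> tuple[Module, TrainHistory]:
    """Train ``model`` and return it loaded with the best-validation weights."""
    config = config or TrainConfig()
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must both be non-empty")
    xtr, ttr = _standardized_arrays(train_pairs)
    xva, tva = _standardized_arrays(val_pairs)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history = TrainHistory()
    best_state: dict[str, np.ndarray] | None = None

    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(len(xtr))
        running, seen = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, tb = xtr[idx], ttr[idx]
            optimizer.zero_grad()
            pred = model.forward(xb)
            diff = pred - tb
            loss = float(np.mean(diff**2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training aborted: non-finite loss {loss} at epoch {epoch}, batch {i // config.batch_size}"
                )
            model.backward(2.0 * diff / diff.size)
            optimizer.step()
            running += loss * len(idx)
            seen += len(idx)
        model.eval()
        val = _epoch_loss(model, xva, tva, config.batch_size)
        history.train_loss.append(running / seen)
        history.val_loss.append(val)
        if val < history.best_val_loss:
            history.best_val_loss = val
            history.best_epoch = epoch
            best_state = model.state_dict()
        log.info("epoch %d: train loss %.6f, val loss %.6f", epoch, history.train_loss[-1], val)

    assert best_state is not None
    model.load_state_dict(best_state)
    model.eval()
    return model, history


def predict(
    model: Module,
    short_time: np.ndarray,
    params: StandardizationParams | None = None,
) -> np.ndarray:
    """Count-scale full-time prediction for one short-time image.

    ``params`` defaults to the input image's own standardization
    parameters.  The output is clipped at zero: counts are non-negative.
    """
    image = np.asarray(short_time, dtype=float)
    if params is None:
        _, params = standardize(image)
    xstd = (image - params.mean) / params.sd
    model.eval()
    out = model.forward(xstd[None, None])[0, 0]
    return np.clip(inverse_standardize(out, params), 0.0, None)
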