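"""Training: objectives, Adadelta optimization and ensembles.

The regression objective is the mean squared error between the sigmoid
output and the normalized affinity target; a binary cross-entropy variant
serves classification datasets that provide binder labels instead of
quantitative affinities. An ensemble of T networks is trained from distinct
random initializations and predictions are averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import AffinityRecord, AlleleRegistry, encode_pair
from .model import (
    ModelConfig,
    backward_batch,
    forward_batch,
    init_params,
    pack_batch,
    trainable_keys,
)

_EPS = 1e-12


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults match the full-scale recipe: batch size 128, 20 epochs,
    Adadelta with learning rate 0.9 and weight decay 1e-4, ensembles of
    T = 20 models. ``rho`` and ``eps`` are Adadelta's accumulator decay and
    stabilizer.
    """

    objective: str = "mse"
    batch_size: int = 128
    epochs: int = 20
    learning_rate: float = 0.9
    weight_decay: float = 1e-4
    rho: float = 0.9
    eps: float = 1e-6
    ensemble_size: int = 20
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.objective not in ("mse", "cross_entropy"):
            raise ValueError(f"unknown objective {self.objective!r}")
        if self.ensemble_size < 1 or self.epochs < 1:
            raise ValueError("ensemble_size and epochs must be >= 1")


def loss(z_hat, target, objective: str = "mse"):
    """Per-example loss; arrays broadcast, scalars return floats.

    ``mse``: squared error on the [0, 1] affinity scale. ``cross_entropy``:
    binary cross-entropy, requiring 0/1 targets (binder labels).
    """
    z_hat = np.asarray(z_hat, dtype=float)
    target = np.asarray(target, dtype=float)
    if objective == "mse":
        out = (z_hat - target) ** 2
    elif objective == "cross_entropy":
        if not np.all((target == 0.0) | (target == 1.0)):
            raise ValueError("cross_entropy requires binary 0/1 targets")
        zc = np.clip(z_hat, _EPS, 1.0 - _EPS)
        out = -(target * np.log(zc) + (1.0 - target) * np.log(1.0 - zc))
    else:
        raise ValueError(f"unknown objective {objective!r}")
    return float(out) if out.ndim == 0 else out


def _loss_grad(z, target, objective: str) -> np.ndarray:
    """d(mean loss)/dz for a batch."""
    B = len(z)
    if objective == "mse":
        return 2.0 * (z - target) / B
    zc = np.clip(z, _EPS, 1.0 - _EPS)
    return (zc - target) / (zc * (1.0 - zc)) / B


class Adadelta:
    """Adadelta with decoupled learning-rate scaling and L2 weight decay."""

    def __init__(self, params: dict[str, np.ndarray], config: TrainConfig):
        self.keys = trainable_keys(params)
        self.lr = config.learning_rate
        self.rho = config.rho
        self.eps = config.eps
        self.weight_decay = config.weight_decay
        self._acc_g = {k: np.zeros_like(params[k]) for k in self.keys}
        self._acc_d = {k: np.zeros_like(params[k]) for k in self.keys}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        for k in self.keys:
            g = grads[k] + self.weight_decay * params[k]
            acc_g = self._acc_g[k]
            acc_d = self._acc_d[k]
            acc_g *= self.rho
            acc_g += (1.0 - self.rho) * g * g
            delta = -np.sqrt(acc_d + self.eps) / np.sqrt(acc_g + self.eps) * g
            acc_d *= self.rho
            acc_d += (1.0 - self.rho) * delta * delta
            params[k] += self.lr * delta


def _encode_all(records, registry):
    return [encode_pair(rec, registry) for rec in records]


def train_single(
    records: Sequence[AffinityRecord],
    registry: AlleleRegistry,
    model_config: ModelConfig,
    train_config: TrainConfig,
    seed: int,
) -> tuple[dict[str, np.ndarray], list[float]]:
    """Train one network; returns (params, per-epoch mean training loss).

    Fully deterministic for a given (records, configs, seed): the seed
    drives initialization, per-epoch shuffling and dropout.
    """
    if not records:
        raise ValueError("cannot train on an empty record list")
    if train_config.objective == "cross_entropy":
        targets_all = np.array([r.affinity for r in records])
        if not np.all((targets_all == 0.0) | (targets_all == 1.0)):
            raise ValueError("cross_entropy training requires 0/1 binder targets")
    rng = np.random.default_rng(seed)
    params = init_params(model_config, rng)
    opt = Adadelta(params, train_config)
    pairs = _encode_all(records, registry)
    order = np.arange(len(pairs))
    log: list[float] = []
    for _epoch in range(train_config.epochs):
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, len(order), train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            batch = [pairs[i] for i in idx]
            pep, pse, lengths, targets = pack_batch(batch)
            z, _, _, cache = forward_batch(
                params, model_config, pep, pse, lengths,
                training=True, rng=rng, return_cache=True,
            )
            batch_loss = loss(z, targets, train_config.objective)
            epoch_losses.append(float(np.mean(batch_loss)) * len(idx))
            dz = _loss_grad(z, targets, train_config.objective)
            grads = backward_batch(params, model_config, cache, dz)
            opt.step(params, grads)
        log.append(sum(epoch_losses) / len(order))
    return params, log


@dataclass
class Ensemble:
    """T independently initialized networks sharing one architecture."""

    members: list[dict[str, np.ndarray]]
    config: ModelConfig
    seeds: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.seeds and len(set(self.seeds)) != len(self.seeds):
            raise ValueError("member seeds must be distinct")

    @property
    def size(self) -> int:
        return len(self.members)


def train_ensemble(
    records: Sequence[AffinityRecord],
    registry: AlleleRegistry,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> Ensemble:
    """Train T models with seeds base_seed .. base_seed + T - 1, independently."""
    members, seeds = [], []
    for i in range(train_config.ensemble_size):
        seed = train_config.base_seed + i
        params, _log = train_single(records, registry, model_config, train_config, seed)
        members.append(params)
        seeds.append(seed)
    return Ensemble(members=members, config=model_config, seeds=seeds)
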