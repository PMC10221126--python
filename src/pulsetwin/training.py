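"""Balanced genuine/impostor pair sampling and the BCE training loop.

Every epoch draws as many fresh pairs as there are cycles in the training
pool — genuine (same subject) and impostor (different subjects) pairs each
with probability one half, so the heavily impostor-dominated pair universe
never biases the model — and steps an Adam optimizer on binary
cross-entropy in minibatches.  No early stopping, no schedules, no
validation-based selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._rng import substream
from .config import RunConfig
from .preprocess import ProcessedCycle
from .verifier import ModelConfig, SimilarityModel

_LOSS_EPS = 1e-7  # prediction clamp inside the loss; sigmoid saturation guard


@dataclass(frozen=True)
class PairSample:
    """Two cycles plus the genuine (1) / impostor (0) label."""

    first: ProcessedCycle
    second: ProcessedCycle
    label: int

    def __post_init__(self):
        same = self.first.subject_id == self.second.subject_id
        if bool(self.label) != same:
            raise ValueError("label inconsistent with subject ids")
        if self.first.record_id == self.second.record_id:
            raise ValueError("a cycle cannot be paired with itself")


@dataclass
class TrainState:
    """Model plus training bookkeeping."""

    model: SimilarityModel
    epoch: int = 0
    loss_history: list[float] = field(default_factory=list)
    total_exposures: int = 0


class _PairPool:
    """Index structures for O(1) balanced sampling from a labelled pool."""

    def __init__(self, cycles: list[ProcessedCycle]):
        self.cycles = list(cycles)
        by_subject: dict[str, list[int]] = {}
        for i, c in enumerate(self.cycles):
            by_subject.setdefault(c.subject_id, []).append(i)
        self.by_subject = by_subject
        self.subjects = sorted(by_subject)
        self.multi_subjects = [s for s in self.subjects if len(by_subject[s]) >= 2]
        # genuine pairs, enumerated once; uniform sampling is then exact
        self.genuine_pairs = [
            (a, b)
            for s in self.multi_subjects
            for k, a in enumerate(by_subject[s])
            for b in by_subject[s][k + 1:]
        ]

    @property
    def can_genuine(self) -> bool:
        return bool(self.genuine_pairs)

    @property
    def can_impostor(self) -> bool:
        return len(self.subjects) >= 2


def sample_balanced_pair(pool, rng: np.random.Generator) -> PairSample:
    """Draw one pair: genuine with probability 1/2, else impostor.

    Genuine pairs are uniform over all same-subject cycle pairs.  Impostor
    pairs are two-stage — a uniform unordered subject pair, then a uniform
    cycle from each — so subjects with many cycles do not dominate the
    impostor distribution.  Never pairs a cycle with itself.
    """
    if not isinstance(pool, _PairPool):
        pool = _PairPool(pool)
    if not pool.can_genuine:
        raise ValueError("no genuine pair possible: every subject has a single cycle")
    if not pool.can_impostor:
        raise ValueError("no impostor pair possible: pool has a single subject")
    if rng.random() < 0.5:
        a, b = pool.genuine_pairs[rng.integers(len(pool.genuine_pairs))]
        label = 1
    else:
        i, j = rng.choice(len(pool.subjects), size=2, replace=False)
        sa, sb = pool.subjects[i], pool.subjects[j]
        a = pool.by_subject[sa][rng.integers(len(pool.by_subject[sa]))]
        b = pool.by_subject[sb][rng.integers(len(pool.by_subject[sb]))]
        label = 0
    return PairSample(pool.cycles[a], pool.cycles[b], label)


def bce_loss(prediction: float, label: int) -> float:
    """Binary cross entropy −(y·ln ŷ + (1−y)·ln(1−ŷ)) with ε-clamping."""
    p = min(max(float(prediction), _LOSS_EPS), 1.0 - _LOSS_EPS)
    y = float(label)
    return -(y * math.log(p) + (1.0 - y) * math.log(1.0 - p))


def planned_exposures(pool_size: int, epochs: int) -> int:
    """Total pair exposures of a run: pool size × epochs (one pool-size
    batch of fresh pairs per epoch)."""
    if pool_size < 0 or epochs < 0:
        raise ValueError("pool_size and epochs must be non-negative")
    return pool_size * epochs


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def train(pool: list[ProcessedCycle], config: RunConfig,
          model: SimilarityModel | None = None,
          model_config: ModelConfig | None = None,
          loss_log_path=None) -> TrainState:
    """Train the similarity model on a pool of processed cycles.

    Per epoch, ``len(pool)`` fresh balanced pairs are drawn and consumed in
    minibatches of ``config.batch_size``; the mean epoch BCE loss is
    recorded.  Deterministic given ``config.random_seed``.  Aborts on a
    non-finite loss.
    """
    if model is None:
        if not pool:
            raise ValueError("empty training pool")
        cycle_len = len(pool[0])
        cfg = model_config or ModelConfig(input_length=cycle_len)
        model = SimilarityModel(cfg, seed=config.random_seed)
    indexed = _PairPool(pool)
    if not (indexed.can_genuine and indexed.can_impostor):
        raise ValueError("pool must allow both genuine and impostor pairs")
    rng = substream(config.random_seed, "pairs")
    optimizer = _Adam(model.params, config.learning_rate)
    state = TrainState(model)
    pool_size = len(pool)
    log_lines = ["epoch\tmean_loss"]

    for epoch in range(config.epochs):
        pairs = [sample_balanced_pair(indexed, rng) for _ in range(pool_size)]
        model.train_mode()
        loss_sum = 0.0
        for start in range(0, pool_size, config.batch_size):
            batch = pairs[start:start + config.batch_size]
            a = np.stack([p.first.values for p in batch])
            b = np.stack([p.second.values for p in batch])
            y = np.asarray([p.label for p in batch], dtype=float)
            p, cache = model.forward_pair_batch(a, b, return_cache=True)
            pc = np.clip(p, _LOSS_EPS, 1.0 - _LOSS_EPS)
            losses = -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
            if not np.all(np.isfinite(losses)):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            loss_sum += float(losses.sum())
            dz = (p - y) / len(batch)  # d(mean BCE)/d(logit) through the sigmoid
            grads = model.backward_pair_batch(dz, cache)
            optimizer.step(model.params, grads)
        state.epoch = epoch + 1
        state.total_exposures += pool_size
        mean_loss = loss_sum / pool_size
        state.loss_history.append(mean_loss)
        log_lines.append(f"{epoch + 1}\t{mean_loss:.6f}")

    model.eval_mode()
    if loss_log_path is not None:
        from pathlib import Path
        Path(loss_log_path).write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return state
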