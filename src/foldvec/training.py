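"""Twin-network training of the aggregator against TM-score labels.

Both structures of a pair pass through the same aggregator weights; the
loss is the mean squared error between the cosine similarity of the two
embeddings and the pair's maximum TM-score, rounded to the first decimal
(11 possible regression targets 0.0, 0.1, ..., 1.0).  Because the
distribution of TM-scores in an all-vs-all pair set is extremely skewed
toward dissimilar pairs, batches are drawn so that the non-empty
TM-score bins are sampled with equal quotas.

Optimization is Adam with a learning-rate schedule of linear warmup from
zero followed by cosine decay to a floor.  After every epoch the area
under the precision-recall curve (AUPRC, positives: tm_max >= 0.5,
scores: cosine) is computed on a bin-stratified held-out pair set, and
the weights with the best validation AUPRC (earliest epoch on ties) are
returned.  Training is single-process and float64, so a fixed master
seed reproduces the run exactly.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .evaluation import auprc_score
from .model import (AggregatorConfig, EncoderConfig, aggregate_tensor,
                    encode_residues, init_aggregator_weights, save_checkpoint)
from .nn import Adam, Tensor

BINS = tuple(round(b / 10, 1) for b in range(11))


def bin_tm(tm: float) -> float:
    """Round a TM-score to the first decimal, half up (0.05 -> 0.1)."""
    if not 0.0 <= tm <= 1.0:
        raise ValueError(f"TM-score {tm} outside [0, 1]")
    return min(1.0, math.floor(tm * 10 + 0.5) / 10.0)


@dataclass(frozen=True)
class PairSample:
    """One training pair: two structure ids and the oracle tm_max."""

    id1: str
    id2: str
    tm_max: float

    def __post_init__(self):
        if self.id1 == self.id2:
            raise ValueError("self-pairs are not training samples")

    @property
    def bin(self) -> float:
        return bin_tm(self.tm_max)


@dataclass
class TrainingConfig:
    """Hyperparameters of a training run.

    The reference run uses 320 000 pairs per epoch, a two-epoch warmup
    and a 2% validation split; the mini defaults here train the mini
    aggregator preset on one CPU in a few minutes.
    """

    batch_size: int = 48
    pairs_per_epoch: int = 1536
    epochs: int = 15
    peak_lr: float = 3e-4
    min_lr: float | None = None        # defaults to peak_lr / 100
    warmup_epochs: int = 2
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    validation_fraction: float = 0.02
    regress_binned: bool = True        # False regresses raw tm_max (ablation)
    master_seed: int = 0

    def __post_init__(self):
        if not self.warmup_epochs < self.epochs:
            raise ValueError("warmup_epochs must be < epochs")
        if not 0.0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must be in (0, 0.5)")
        if self.min_lr is None:
            self.min_lr = self.peak_lr / 100.0


@dataclass
class TrainingHistory:
    """Per-epoch record of loss, validation AUPRC and learning rate."""

    train_loss: list = field(default_factory=list)
    val_auprc: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    checkpoint_paths: list = field(default_factory=list)
    val_pairs: list = field(default_factory=list)   # the held-out PairSamples

    @property
    def best_epoch(self) -> int:
        """argmax of validation AUPRC; earliest epoch on ties."""
        best = max(self.val_auprc)
        return self.val_auprc.index(best)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "epoch": range(len(self.train_loss)),
            "loss": self.train_loss,
            "val_auprc": self.val_auprc,
            "lr": self.lr,
        })


def sample_uniform_batch(pool, batch_size: int, rng,
                         mode: str = "quota") -> list:
    """Draw a batch with equal representation of non-empty TM-score bins.

    ``quota`` mode assigns each non-empty bin an exact equal quota (any
    remainder spread over rng-chosen bins); ``expected`` mode draws each
    sample by first picking a bin uniformly.  Both draw pairs within a
    bin uniformly with replacement.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    pool = list(pool)
    if not pool:
        raise ValueError("empty pair pool")
    by_bin: dict = {}
    for p in pool:
        by_bin.setdefault(p.bin, []).append(p)
    bins = sorted(by_bin)
    batch = []
    if mode == "quota":
        base, rem = divmod(batch_size, len(bins))
        extra = set(rng.choice(len(bins), size=rem, replace=False)) if rem else set()
        for bi, b in enumerate(bins):
            take = base + (1 if bi in extra else 0)
            members = by_bin[b]
            idx = rng.integers(0, len(members), size=take)
            batch.extend(members[i] for i in idx)
    elif mode == "expected":
        for _ in range(batch_size):
            b = bins[rng.integers(0, len(bins))]
            members = by_bin[b]
            batch.append(members[rng.integers(0, len(members))])
    else:
        raise ValueError("mode must be 'quota' or 'expected'")
    return batch


def pair_loss(cosine: float, tm_target: float) -> float:
    """Squared error between a cosine similarity and a TM target."""
    if not -1.0 <= cosine <= 1.0:
        raise ValueError("cosine outside [-1, 1]")
    return (cosine - tm_target) ** 2


def lr_at(step: int, total_steps: int, cfg: TrainingConfig) -> float:
    """Learning rate: linear ramp 0 -> peak, then cosine decay to the floor."""
    if not 0 <= step <= total_steps:
        raise ValueError("step outside [0, total_steps]")
    warmup = int(round(total_steps * cfg.warmup_epochs / cfg.epochs))
    if warmup > 0 and step < warmup:
        return cfg.peak_lr * step / warmup
    if total_steps == warmup:
        return cfg.peak_lr
    frac = (step - warmup) / (total_steps - warmup)
    return cfg.min_lr + 0.5 * (cfg.peak_lr - cfg.min_lr) * (1 + math.cos(math.pi * frac))


def split_validation(pairs, fraction: float, rng):
    """Bin-stratified pair holdout: >= 1 pair per non-empty bin."""
    by_bin: dict = {}
    for p in pairs:
        by_bin.setdefault(p.bin, []).append(p)
    train, val = [], []
    for b in sorted(by_bin):
        members = list(by_bin[b])
        perm = rng.permutation(len(members))
        n_val = max(1, int(round(fraction * len(members))))
        if n_val >= len(members):  # never empty a bin's training side entirely
            n_val = max(0, len(members) - 1)
        val.extend(members[i] for i in perm[:n_val])
        train.extend(members[i] for i in perm[n_val:])
    return train, val


def _cosine_tensor(e1: Tensor, e2: Tensor) -> Tensor:
    dot = (e1 * e2).sum()
    return dot * ((e1 * e1).sum() ** -0.5) * ((e2 * e2).sum() ** -0.5)


def pairs_from_table(table) -> list:
    """PairSamples from a ``id1, id2, tm_max`` DataFrame."""
    return [PairSample(r.id1, r.id2, float(r.tm_max))
            for r in table.itertuples(index=False)]


def train(data, encoder_cfg: EncoderConfig, aggregator_cfg: AggregatorConfig,
          cfg: TrainingConfig, pairs=None, checkpoint_dir: str | None = None):
    """Train the aggregator as a twin network.

    Parameters
    ----------
    data : BenchmarkSet or iterable of ChainStructure
        The structures; ids are their ``source`` fields.
    encoder_cfg, aggregator_cfg : configs of the two model stages.
    cfg : TrainingConfig
    pairs : DataFrame or list of PairSample, optional
        ``id1, id2, tm_max`` labels.  If omitted, they are computed with
        the in-repo TM-score oracle over all structure pairs.
    checkpoint_dir : str, optional
        Directory for per-epoch checkpoints and ``history.tsv``.

    Returns
    -------
    (weights, TrainingHistory)
        The weights of the epoch with the best validation AUPRC.
    """
    structures = list(getattr(data, "structures", data))
    by_id = {s.source or s.chain_id: s for s in structures}
    if pairs is None:
        from .tmscore import pairwise_tm_table

        pairs = pairwise_tm_table(structures)
    if not isinstance(pairs, list):
        pairs = pairs_from_table(pairs)

    rng = np.random.default_rng(abs(int(cfg.master_seed)))
    train_pool, val_pool = split_validation(pairs, cfg.validation_fraction, rng)
    val_pos = [p.tm_max >= 0.5 for p in val_pool]
    if not any(val_pos) or all(val_pos):
        raise ValueError(
            "validation split lacks positives or negatives; AUPRC undefined"
        )

    # frozen residue encodings, computed once
    encoded = {sid: encode_residues(s, encoder_cfg).embeddings
               for sid, s in by_id.items()}

    weights = init_aggregator_weights(
        aggregator_cfg, seed=int(rng.integers(2**31 - 1)))
    opt = Adam(weights, lr=0.0, beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.eps)

    steps_per_epoch = max(1, int(np.ceil(cfg.pairs_per_epoch / cfg.batch_size)))
    total_steps = cfg.epochs * steps_per_epoch

    def embed_all(ids):
        out = {}
        for sid in ids:
            out[sid] = aggregate_tensor(Tensor(encoded[sid]),
                                        aggregator_cfg, weights)
        return out

    history = TrainingHistory(val_pairs=list(val_pool))
    best_weights = None
    best_auprc = -1.0
    step = 0
    for epoch in range(cfg.epochs):
        losses = []
        for _ in range(steps_per_epoch):
            batch = sample_uniform_batch(train_pool, cfg.batch_size, rng)
            opt.lr = lr_at(step, total_steps, cfg)
            ids = {p.id1 for p in batch} | {p.id2 for p in batch}
            emb = embed_all(ids)
            loss = None
            for p in batch:
                target = p.bin if cfg.regress_binned else p.tm_max
                term = (_cosine_tensor(emb[p.id1], emb[p.id2]) - target) ** 2.0
                loss = term if loss is None else loss + term
            loss = loss * (1.0 / len(batch))
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1

        # validation AUPRC on held-out pairs, gradients off
        val_ids = {p.id1 for p in val_pool} | {p.id2 for p in val_pool}
        vemb = {sid: aggregate_tensor(Tensor(encoded[sid]), aggregator_cfg,
                                      {k: Tensor(w.data) for k, w in weights.items()})
                for sid in val_ids}
        scores = [float(_cosine_tensor(vemb[p.id1], vemb[p.id2]).data)
                  for p in val_pool]
        auprc = auprc_score(scores, val_pos)

        history.train_loss.append(float(np.mean(losses)))
        history.val_auprc.append(float(auprc))
        history.lr.append(opt.lr)
        if checkpoint_dir is not None:
            os.makedirs(checkpoint_dir, exist_ok=True)
            path = os.path.join(checkpoint_dir, f"epoch{epoch:03d}.npz")
            save_checkpoint(path, weights, aggregator_cfg, encoder_cfg,
                            extra={"epoch": epoch, "val_auprc": float(auprc)})
            history.checkpoint_paths.append(path)
        if auprc > best_auprc:
            best_auprc = auprc
            best_weights = {k: Tensor(w.data.copy(), requires_grad=True)
                            for k, w in weights.items()}

    if checkpoint_dir is not None:
        history.to_frame().to_csv(os.path.join(checkpoint_dir, "history.tsv"),
                                  sep="\t", index=False)
    return best_weights, history
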