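"""Transformer set-aggregation of key patches into a 4-level Sydney grade.

The top-ranked patch embeddings of a slide are projected into the model
width, a learned class token is prepended, and the set is passed through
pre-norm self-attention layers with no positional encoding (patches are an
unordered set). The class token is read out through a linear head and a
4-way softmax over grades 0-3. Slides with fewer selected patches than
`k_select` are padded with a masked pad token that attention ignores.

The binary slide score used for ROC analysis is P(grade 2) + P(grade 3),
i.e. the predicted probability of moderate-or-marked disease.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import Tensor
from .metrics import weighted_kappa


class AggregatorError(ValueError):
    pass


@dataclass
class AggregatorConfig:
    n_layers: int = 2
    n_heads: int = 4
    model_dim: int = 256
    ff_dim: int | None = None  # defaults to 4 * model_dim
    dropout: float = 0.1
    n_classes: int = 4
    head: str = "softmax"  # or "ordinal": expected-grade regression loss
    k_select: int = 20
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.model_dim % self.n_heads:
            raise AggregatorError("model_dim must be divisible by n_heads")
        if self.ff_dim is None:
            self.ff_dim = 4 * self.model_dim


@dataclass
class SlideGradePrediction:
    slide_id: str
    feature: str
    probs: np.ndarray  # (4,) summing to 1
    grade: int  # argmax
    binary_score: float  # P(grade 2) + P(grade 3)


class _Attention(_nn.Module):
    def __init__(self, cfg: AggregatorConfig, rng):
        super().__init__()
        d, h = cfg.model_dim, cfg.n_heads
        self.h, self.dh = h, d // h
        self.wq = _nn.Linear(d, d, rng)
        self.wk = _nn.Linear(d, d, rng)
        self.wv = _nn.Linear(d, d, rng)
        self.wo = _nn.Linear(d, d, rng)

    def __call__(self, x: Tensor, neg_mask: np.ndarray) -> Tensor:
        b, t, d = x.shape
        def split(z):  # (B,T,D) -> (B,H,T,dh)
            return z.reshape(b, t, self.h, self.dh).transpose((0, 2, 1, 3))
        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = q @ k.transpose((0, 1, 3, 2)) * (1.0 / np.sqrt(self.dh))
        scores = scores + Tensor(neg_mask[:, None, None, :])  # -inf on pad keys
        att = _nn.softmax(scores, axis=-1)
        out = (att @ v).transpose((0, 2, 1, 3)).reshape(b, t, d)
        return self.wo(out)


class _Block(_nn.Module):
    def __init__(self, cfg: AggregatorConfig, rng):
        super().__init__()
        self.ln1 = _nn.LayerNorm(cfg.model_dim)
        self.att = _Attention(cfg, rng)
        self.ln2 = _nn.LayerNorm(cfg.model_dim)
        self.ff1 = _nn.Linear(cfg.model_dim, cfg.ff_dim, rng)
        self.ff2 = _nn.Linear(cfg.ff_dim, cfg.model_dim, rng)
        self.drop = _nn.Dropout(cfg.dropout, rng)

    def __call__(self, x: Tensor, neg_mask: np.ndarray) -> Tensor:
        x = x + self.drop(self.att(self.ln1(x), neg_mask))
        return x + self.drop(self.ff2(self.drop(self.ff1(self.ln2(x)).relu())))


class TransformerAggregator(_nn.Module):
    def __init__(self, d_in: int, config: AggregatorConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.d_in = d_in
        self.proj = _nn.Linear(d_in, config.model_dim, rng)
        self.cls = Tensor(rng.normal(0, 0.02, size=(1, 1, config.model_dim)),
                          requires_grad=True)
        self.blocks = [_Block(config, rng) for _ in range(config.n_layers)]
        self.ln_out = _nn.LayerNorm(config.model_dim)
        self.head = _nn.Linear(config.model_dim, config.n_classes, rng)

    def logits(self, batch: np.ndarray, lengths: np.ndarray) -> Tensor:
        """`batch` is (B, k, d_in) zero-padded; `lengths` gives real counts."""
        if batch.shape[2] != self.d_in:
            raise AggregatorError(f"input dim {batch.shape[2]} != expected {self.d_in}")
        b, k, _ = batch.shape
        x = self.proj(Tensor(batch))
        cls = self.cls * Tensor(np.ones((b, 1, 1)))
        x = _nn.concat([cls, x], axis=1)  # (B, 1+k, D)
        pad = np.where(np.arange(k)[None, :] >= lengths[:, None], -1e9, 0.0)
        neg_mask = np.concatenate([np.zeros((b, 1)), pad], axis=1)
        for blk in self.blocks:
            x = blk(x, neg_mask)
        cls_out = self.ln_out(x)[:, 0, :]
        return self.head(cls_out)


def _pad_batch(sets: list[np.ndarray], k: int) -> tuple[np.ndarray, np.ndarray]:
    d = sets[0].shape[1]
    batch = np.zeros((len(sets), k, d))
    lengths = np.zeros(len(sets), dtype=int)
    for i, s in enumerate(sets):
        m = min(len(s), k)
        batch[i, :m] = s[:m]
        lengths[i] = m
    return batch, lengths


def aggregate(selected: np.ndarray, model: TransformerAggregator,
              slide_id: str = "slide", feature: str = "atrophy") -> SlideGradePrediction:
    """Grade one slide from its selected key-patch embeddings."""
    selected = np.asarray(selected, dtype=float)
    if selected.ndim != 2 or len(selected) == 0:
        raise AggregatorError("need a non-empty (n, d) embedding array")
    model.eval()
    k = max(model.config.k_select, len(selected))
    batch, lengths = _pad_batch([selected], k)
    logits = model.logits(batch, lengths).data[0]
    z = np.exp(logits - logits.max())
    probs = z / z.sum()
    return SlideGradePrediction(
        slide_id=slide_id,
        feature=feature,
        probs=probs,
        grade=int(np.argmax(probs)),
        binary_score=float(probs[2] + probs[3]),
    )


def train_aggregator(
    selected_sets: list[np.ndarray],
    grades: list[int],
    config: AggregatorConfig,
    splits: list[str] | None = None,
) -> tuple[TransformerAggregator, list[dict]]:
    """Train the 4-class aggregator; model selection on validation QWK.

    `selected_sets[i]` is the (<= k_select, d) key-patch matrix of slide i
    with 4-level grade `grades[i]`; `splits` marks train/val membership.
    """
    grades = [int(g) for g in grades]
    if splits is None:
        splits = ["train"] * len(grades)
    tr = [i for i, s in enumerate(splits) if s == "train"]
    va = [i for i, s in enumerate(splits) if s == "val"]
    if not tr:
        raise AggregatorError("no training slides")
    if len({grades[i] for i in tr}) < 2:
        raise AggregatorError("training set must contain >= 2 distinct grades")
    d = selected_sets[0].shape[1]
    model = TransformerAggregator(d, config)
    log: list[dict] = []
    if config.epochs == 0:
        return model, log
    opt = _nn.Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 3)
    best_state, best_kappa = None, -np.inf
    kcap = config.k_select
    for epoch in range(config.epochs):
        order = rng.permutation(len(tr))
        model.train()
        losses = []
        for start in range(0, len(tr), config.batch_size):
            idx = [tr[j] for j in order[start : start + config.batch_size]]
            batch, lengths = _pad_batch([selected_sets[i] for i in idx], kcap)
            y = np.array([grades[i] for i in idx])
            logits = model.logits(batch, lengths)
            if config.head == "ordinal":
                p = _nn.softmax(logits, axis=-1)
                expected = (p * Tensor(np.arange(config.n_classes)[None, :])).sum(axis=1)
                loss = ((expected - Tensor(y.astype(float))) ** 2.0).mean()
            else:
                loss = _nn.cross_entropy(logits, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if va:
            model.eval()
            batch, lengths = _pad_batch([selected_sets[i] for i in va], kcap)
            pred = model.logits(batch, lengths).data.argmax(axis=1)
            truth = [grades[i] for i in va]
            if len(set(truth)) > 1 or len(set(pred)) > 1:
                kap = weighted_kappa(truth, pred, k=config.n_classes, n_boot=0).point
            else:
                kap = 1.0 if list(pred) == truth else 0.0
            entry["val_kappa"] = kap
            if kap > best_kappa:
                best_kappa, best_state = kap, model.state_dict()
        log.append(entry)
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, log


def save_aggregator(path: Path, model: TransformerAggregator) -> None:
    path = Path(path)
    np.savez(Path(str(path) + ".npz"), **model.state_dict())
    cfg = asdict(model.config)
    cfg["d_in"] = model.d_in
    Path(str(path) + ".json").write_text(json.dumps(cfg, sort_keys=True))


def load_aggregator(path: Path) -> TransformerAggregator:
    path = Path(path)
    cfg = json.loads(Path(str(path) + ".json").read_text())
    d_in = cfg.pop("d_in")
    model = TransformerAggregator(d_in, AggregatorConfig(**cfg))
    model.load_state_dict(dict(np.load(Path(str(path) + ".npz"))))
    model.eval()
    return model
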