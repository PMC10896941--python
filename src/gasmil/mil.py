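"""Weakly-supervised patch classification and key-patch selection.

Under the MIL hypothesis a slide labelled positive (Sydney grade > 0) must
contain at least one lesion patch, while a negative slide contains none.
An MLP scores every multi-scale patch embedding; training is iterative
max-instance MIL: each epoch the current model scores all instances of a
bag, the top `s_train` instances inherit the bag's binary label, and only
those are trained on. Model selection uses slide-level validation error
where a slide's score is its maximum instance probability. After training,
the `k_select` highest-scoring patches of each slide (default 20) are
forwarded to the transformer aggregator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import Tensor
from .staging import SlideGrades
from .tiling import TileRef


class MILError(ValueError):
    pass


@dataclass
class Bag:
    """One slide's instances plus its weak slide-level labels."""

    slide_id: str
    instances: np.ndarray  # (n, d) multi-scale embeddings
    refs: list[TileRef]
    labels: SlideGrades
    split: str = "train"  # train/val/test

    def __post_init__(self):
        if len(self.instances) < 1:
            raise MILError(f"bag {self.slide_id} has no instances")
        if len(self.refs) != len(self.instances):
            raise MILError("refs and instances length mismatch")


@dataclass
class MILConfig:
    feature: str = "atrophy"  # one of inflammation/activity/atrophy/IM
    hidden_dims: tuple[int, ...] = (512, 128)
    dropout: float = 0.25
    k_select: int = 20
    s_train: int = 1
    lr: float = 1e-3
    epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.k_select < 1:
            raise MILError("k_select must be >= 1")
        if self.s_train < 1:
            raise MILError("s_train must be >= 1")


@dataclass
class PatchScore:
    ref: TileRef
    p_lesion: float


def binarize_bag_label(grade: int) -> int:
    """Slide is a positive bag iff its grade exceeds 0."""
    if grade not in (0, 1, 2, 3):
        raise MILError(f"grade {grade} outside 0-3")
    return int(grade > 0)


class PatchClassifier(_nn.Module):
    """Binary lesion-vs-background MLP over multi-scale embeddings."""

    def __init__(self, d_in: int, config: MILConfig):
        super().__init__()
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.d_in = d_in
        dims = [d_in, *config.hidden_dims]
        self.layers = [_nn.Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.head = _nn.Linear(dims[-1], 1, rng)
        self.drop = _nn.Dropout(config.dropout, np.random.default_rng(config.seed + 1))

    def logits(self, x: Tensor) -> Tensor:
        h = x
        for lin in self.layers:
            h = self.drop(lin(h).relu())
        return self.head(h)

    def probs(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.d_in:
            raise MILError(f"instance dim {x.shape[1]} != trained dim {self.d_in}")
        was_training = self.training
        self.eval()
        z = self.logits(Tensor(x)).data[:, 0]
        if was_training:
            self.train()
        return 1.0 / (1.0 + np.exp(-z))


def _bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    # softplus(-t*z) with t in {-1,+1}: relu(m) + log(1 + exp(-|m|)), stable
    t = 2.0 * np.asarray(y, dtype=np.float64) - 1.0
    m = logits.reshape(logits.shape[0]) * Tensor(-t)
    absm = m.relu() + (-m).relu()
    return (m.relu() + ((absm * -1.0).exp() + 1.0).log()).mean()


def train_patch_classifier(bags: list[Bag], config: MILConfig,
                           ) -> tuple[PatchClassifier, list[dict]]:
    """Iterative max-instance MIL training; returns classifier and epoch log.

    Requires both positive and negative bags in the train split; validation
    bags (if any) drive best-weight selection by slide-level error.
    """
    train = [b for b in bags if b.split == "train"]
    val = [b for b in bags if b.split == "val"]
    if not train:
        raise MILError("no training bags")
    ylab = [binarize_bag_label(getattr(b.labels, config.feature)) for b in train]
    if len(set(ylab)) < 2:
        raise MILError("training set must contain both positive and negative bags")
    d = train[0].instances.shape[1]
    clf = PatchClassifier(d, config)
    log: list[dict] = []
    if config.epochs == 0:
        return clf, log
    opt = _nn.Adam(clf.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 2)
    best_state, best_err = None, np.inf
    for epoch in range(config.epochs):
        xs, ys = [], []
        for bag, y in zip(train, ylab):
            p = clf.probs(bag.instances)
            top = np.argsort(-p, kind="stable")[: config.s_train]
            xs.append(bag.instances[top])
            ys.extend([y] * len(top))
        x = np.concatenate(xs)
        y = np.asarray(ys, dtype=float)
        order = rng.permutation(len(y))
        clf.train()
        losses = []
        for start in range(0, len(y), 64):
            sel = order[start : start + 64]
            logit = clf.logits(Tensor(x[sel]))
            loss = _bce_with_logits(logit, y[sel])
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        entry = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val:
            yv = [binarize_bag_label(getattr(b.labels, config.feature)) for b in val]
            sv = [float(clf.probs(b.instances).max()) for b in val]
            err = float(np.mean((np.asarray(sv) >= 0.5).astype(int) != np.asarray(yv)))
            entry["val_slide_error"] = err
            if err < best_err:
                best_err, best_state = err, clf.state_dict()
        log.append(entry)
    if best_state is not None:
        clf.load_state_dict(best_state)
    clf.eval()
    return clf, log


def score_patches(clf: PatchClassifier, bag: Bag) -> list[PatchScore]:
    """Lesion probability for every instance of one bag."""
    p = clf.probs(bag.instances)
    return [PatchScore(r, float(pi)) for r, pi in zip(bag.refs, p)]


def slide_score(clf: PatchClassifier, bag: Bag) -> float:
    """Slide-level lesion score = maximum instance probability."""
    return float(clf.probs(bag.instances).max())


def select_top_k(scores: list[PatchScore], k: int) -> list[TileRef]:
    """Top-k refs by descending probability; ties break by (row, col) ascending."""
    if k < 1:
        raise MILError("k must be >= 1")
    if not scores:
        raise MILError("empty score list")
    ranked = sorted(scores, key=lambda s: (-s.p_lesion, s.ref.row, s.ref.col))
    return [s.ref for s in ranked[:k]]


def select_top_k_embeddings(bag: Bag, clf: PatchClassifier, k: int) -> np.ndarray:
    """Embeddings of the top-k patches, in rank order (<=k rows if bag is small)."""
    scores = score_patches(clf, bag)
    refs = select_top_k(scores, k)
    index = {(r.row, r.col): i for i, r in enumerate(bag.refs)}
    return bag.instances[[index[(r.row, r.col)] for r in refs]]


def save_classifier(path: Path, clf: PatchClassifier) -> None:
    path = Path(path)
    np.savez(Path(str(path) + ".npz"), **clf.state_dict())
    cfg = asdict(clf.config)
    cfg["d_in"] = clf.d_in
    Path(str(path) + ".json").write_text(json.dumps(cfg, sort_keys=True))


def load_classifier(path: Path) -> PatchClassifier:
    path = Path(path)
    cfg = json.loads(Path(str(path) + ".json").read_text())
    d_in = cfg.pop("d_in")
    cfg["hidden_dims"] = tuple(cfg["hidden_dims"])
    clf = PatchClassifier(d_in, MILConfig(**cfg))
    clf.load_state_dict(dict(np.load(Path(str(path) + ".npz"))))
    clf.eval()
    return clf
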