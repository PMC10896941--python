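"""SimCLR-style contrastive pretraining of per-resolution patch encoders.

Each 224x224 tile is augmented twice (rotation, flips, crop-resize, colour
distortion); the encoder plus a 2-layer projection head maps the two views
into a space where the NT-Xent loss pulls views of the same tile together
and pushes apart views of different tiles within the batch. The backbone
output (before the projection head) is exported as the patch embedding for
downstream multiple-instance learning, following standard SimCLR practice.

One encoder is trained per resolution (0.5 MPP and 2.0 MPP), since texture
statistics differ across magnifications.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv, hsv2rgb
from skimage.measure import block_reduce
from skimage.transform import resize

from . import _nn
from ._nn import Tensor
from .tiling import Patch, TileRef, TILE_SIZE


class ContrastiveError(ValueError):
    pass


# -- augmentation --------------------------------------------------------


@dataclass
class AugmentationPolicy:
    """Random view-generation policy applied twice per patch.

    Rotation draws one of {0, 90, 180, 270} degrees plus continuous jitter of
    up to `rotation_jitter_deg`; colour distortion perturbs brightness,
    contrast, saturation and hue by the given relative strengths; crop_scale
    is the area fraction range for random crop-and-resize.
    """

    rotation_choices: tuple[int, ...] = (0, 90, 180, 270)
    rotation_jitter_deg: float = 10.0
    brightness: float = 0.2
    contrast: float = 0.2
    saturation: float = 0.2
    hue: float = 0.05
    crop_scale: tuple[float, float] = (0.6, 1.0)
    flip_prob: float = 0.5

    def is_identity(self) -> bool:
        return (
            tuple(self.rotation_choices) == (0,)
            and self.rotation_jitter_deg == 0
            and self.brightness == self.contrast == self.saturation == self.hue == 0
            and tuple(self.crop_scale) == (1.0, 1.0)
            and self.flip_prob == 0
        )


def _augment_once(pixels: np.ndarray, policy: AugmentationPolicy,
                  rng: np.random.Generator) -> np.ndarray:
    img = pixels.astype(np.float64) / 255.0
    # crop and resize back
    lo, hi = policy.crop_scale
    if (lo, hi) != (1.0, 1.0):
        scale = np.sqrt(rng.uniform(lo, hi))
        side = max(8, int(round(TILE_SIZE * scale)))
        r0 = rng.integers(0, TILE_SIZE - side + 1)
        c0 = rng.integers(0, TILE_SIZE - side + 1)
        img = resize(img[r0 : r0 + side, c0 : c0 + side], (TILE_SIZE, TILE_SIZE, 3),
                     anti_aliasing=side > TILE_SIZE, preserve_range=True)
    # flips
    if policy.flip_prob > 0:
        if rng.random() < policy.flip_prob:
            img = img[:, ::-1]
        if rng.random() < policy.flip_prob:
            img = img[::-1, :]
    # rotation: right angle (exact via rot90) plus optional continuous jitter
    choices = tuple(policy.rotation_choices)
    deg = choices[int(rng.integers(0, len(choices)))]
    if deg % 360:
        img = np.rot90(img, k=(deg // 90) % 4)
    if policy.rotation_jitter_deg > 0:
        ang = rng.uniform(-policy.rotation_jitter_deg, policy.rotation_jitter_deg)
        img = ndimage.rotate(img, ang, axes=(0, 1), reshape=False, mode="reflect", order=1)
    # colour distortion in HSV
    if policy.brightness or policy.contrast or policy.saturation or policy.hue:
        if policy.brightness:
            img = img * (1.0 + rng.uniform(-policy.brightness, policy.brightness))
        if policy.contrast:
            m = img.mean()
            img = m + (img - m) * (1.0 + rng.uniform(-policy.contrast, policy.contrast))
        img = np.clip(img, 0, 1)
        if policy.saturation or policy.hue:
            hsv = rgb2hsv(img)
            if policy.saturation:
                hsv[..., 1] = np.clip(
                    hsv[..., 1] * (1.0 + rng.uniform(-policy.saturation, policy.saturation)), 0, 1)
            if policy.hue:
                hsv[..., 0] = (hsv[..., 0] + rng.uniform(-policy.hue, policy.hue)) % 1.0
            img = hsv2rgb(hsv)
    img = np.clip(img, 0, 1)
    return np.ascontiguousarray(np.rint(img * 255.0)).astype(np.uint8)


def make_views(patch: Patch, policy: AugmentationPolicy,
               seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Two independently augmented views of one patch; same seed, same pair."""
    if policy.is_identity():
        return patch.pixels.copy(), patch.pixels.copy()
    rng = np.random.default_rng(seed)
    return _augment_once(patch.pixels, policy, rng), _augment_once(patch.pixels, policy, rng)


# -- NT-Xent loss --------------------------------------------------------


def nt_xent_loss(projections: np.ndarray, temperature: float = 0.5) -> float:
    """Normalized-temperature cross-entropy over a batch of 2N paired views.

    Row i of `projections` is paired with row i+N. For each anchor the loss
    is the cross-entropy of picking its positive among the other 2N-1 rows
    under cosine similarity scaled by 1/temperature; the mean over all 2N
    anchors is returned.
    """
    z = np.asarray(projections, dtype=np.float64)
    two_n = z.shape[0]
    if two_n < 4 or two_n % 2:
        raise ContrastiveError("need 2N projections with N >= 2")
    if temperature <= 0:
        raise ContrastiveError("temperature must be positive")
    norms = np.linalg.norm(z, axis=1)
    if np.any(norms == 0):
        raise ContrastiveError("zero-norm projection vector")
    zn = z / norms[:, None]
    sim = zn @ zn.T / temperature
    np.fill_diagonal(sim, -np.inf)
    n = two_n // 2
    pos = np.concatenate([np.arange(n) + n, np.arange(n)])
    logZ = np.logaddexp.reduce(sim, axis=1)
    return float(np.mean(logZ - sim[np.arange(two_n), pos]))


def _nt_xent_tensor(z: Tensor, temperature: float) -> Tensor:
    """Differentiable NT-Xent used inside training (same maths as above)."""
    two_n = z.shape[0]
    n = two_n // 2
    norm = ((z**2.0).sum(axis=1, keepdims=True)) ** 0.5
    zn = z / norm
    sim = zn @ zn.transpose((1, 0)) * (1.0 / temperature)
    sim = sim + Tensor(np.diag(np.full(two_n, -1e9)))  # exclude self-pairs
    pos = np.concatenate([np.arange(n) + n, np.arange(n)])
    return _nn.cross_entropy(sim, pos)


# -- encoders ------------------------------------------------------------


@dataclass
class EncoderConfig:
    backbone: str = "resnet18-style"  # or "small-cnn" for CPU-scale runs
    embed_dim: int = 512
    projection_dim: int = 128
    temperature: float = 0.5
    mpp: float = 0.5

    def __post_init__(self):
        if self.embed_dim <= 0 or self.projection_dim <= 0:
            raise ContrastiveError("embed_dim and projection_dim must be positive")
        if self.temperature <= 0:
            raise ContrastiveError("temperature must be positive")


@dataclass
class EmbeddingRecord:
    ref: TileRef
    vector: np.ndarray
    encoder_id: str


class SmallCNN(_nn.Module):
    """3 conv blocks on an 8x-pooled input; embed_dim defaults to 64.

    The cheap test-scale backbone: average-pool 224 -> 28, then
    conv3x3/relu/maxpool x3 and a linear head.
    """

    POOL = 8

    def __init__(self, embed_dim: int, rng: np.random.Generator):
        super().__init__()
        self.c1 = _nn.Conv2d(3, 16, 3, rng, pad=1)
        self.c2 = _nn.Conv2d(16, 32, 3, rng, pad=1)
        self.c3 = _nn.Conv2d(32, 64, 3, rng, pad=1)
        self.fc = _nn.Linear(64, embed_dim, rng)

    def preprocess(self, batch_uint8: np.ndarray) -> np.ndarray:
        x = batch_uint8.astype(np.float64) / 255.0 - 0.5
        x = block_reduce(x, (1, self.POOL, self.POOL, 1), np.mean)  # 224 -> 28
        return x.transpose(0, 3, 1, 2)

    def __call__(self, x: Tensor) -> Tensor:
        h = _nn.max_pool2d(self.c1(x).relu())          # 28 -> 14
        h = _nn.max_pool2d(self.c2(h).relu())          # 14 -> 7
        h = _nn.max_pool2d(self.c3(h).relu(), 2)       # 7 -> 3
        h = h.mean(axis=(2, 3))
        return self.fc(h)


class _BasicBlock(_nn.Module):
    def __init__(self, c_in: int, c_out: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = _nn.Conv2d(c_in, c_out, 3, rng, stride=stride, pad=1)
        self.bn1 = _nn.BatchNorm2d(c_out)
        self.conv2 = _nn.Conv2d(c_out, c_out, 3, rng, pad=1)
        self.bn2 = _nn.BatchNorm2d(c_out)
        self.down = None
        if stride != 1 or c_in != c_out:
            self.down = _nn.Conv2d(c_in, c_out, 1, rng, stride=stride)
            self.down_bn = _nn.BatchNorm2d(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu()))
        sc = x if self.down is None else self.down_bn(self.down(x))
        return (h + sc).relu()


class ResNet18Style(_nn.Module):
    """Residual backbone mirroring the resnet18 layout (4 stages x 2 blocks)."""

    POOL = 1

    def __init__(self, embed_dim: int, rng: np.random.Generator):
        super().__init__()
        self.stem = _nn.Conv2d(3, 64, 7, rng, stride=2, pad=3)
        self.stem_bn = _nn.BatchNorm2d(64)
        widths = [64, 128, 256, 512]
        blocks = []
        c_in = 64
        for i, w in enumerate(widths):
            blocks.append(_BasicBlock(c_in, w, 1 if i == 0 else 2, rng))
            blocks.append(_BasicBlock(w, w, 1, rng))
            c_in = w
        self.blocks = blocks
        self.fc = _nn.Linear(512, embed_dim, rng)

    def preprocess(self, batch_uint8: np.ndarray) -> np.ndarray:
        x = batch_uint8.astype(np.float64) / 255.0 - 0.5
        return x.transpose(0, 3, 1, 2)

    def __call__(self, x: Tensor) -> Tensor:
        h = _nn.max_pool2d(self.stem_bn(self.stem(x)).relu(), 3, 2)
        for b in self.blocks:
            h = b(h)
        h = h.mean(axis=(2, 3))
        return self.fc(h)


class Encoder(_nn.Module):
    """Backbone + SimCLR projection head, tagged with its resolution."""

    def __init__(self, config: EncoderConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        if config.backbone == "small-cnn":
            self.backbone = SmallCNN(config.embed_dim, rng)
        elif config.backbone == "resnet18-style":
            self.backbone = ResNet18Style(config.embed_dim, rng)
        else:
            raise ContrastiveError(f"unknown backbone {config.backbone!r}")
        self.proj1 = _nn.Linear(config.embed_dim, config.embed_dim, rng)
        self.proj2 = _nn.Linear(config.embed_dim, config.projection_dim, rng)

    def features(self, x: Tensor) -> Tensor:
        return self.backbone(x)

    def project(self, feats: Tensor) -> Tensor:
        return self.proj2(self.proj1(feats).relu())

    @property
    def encoder_id(self) -> str:
        h = hashlib.sha256()
        h.update(json.dumps(asdict(self.config), sort_keys=True).encode())
        for k in sorted(self.state_dict()):
            h.update(self.state_dict()[k].tobytes())
        return h.hexdigest()[:16]


def train_encoder(
    patches: list[Patch],
    config: EncoderConfig,
    policy: AugmentationPolicy,
    epochs: int = 5,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 0,
) -> tuple[Encoder, list[float]]:
    """Contrastive pretraining; returns the encoder and per-epoch mean loss."""
    if batch_size < 4:
        raise ContrastiveError("batch_size must be >= 4 (NT-Xent needs N >= 2)")
    if len(patches) < batch_size:
        raise ContrastiveError("need at least batch_size patches")
    for p in patches:
        if p.ref.mpp != config.mpp:
            raise ContrastiveError(f"patch at {p.ref.mpp} MPP fed to {config.mpp} MPP encoder")
    enc = Encoder(config, seed=seed)
    log: list[float] = []
    if epochs == 0:
        return enc, log
    rng = np.random.default_rng(seed + 1)
    opt = _nn.Adam(enc.parameters(), lr=lr)
    n = len(patches)
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n - batch_size + 1, batch_size):
            idx = order[start : start + batch_size]
            views = []
            for i in idx:
                a, b = make_views(patches[i], policy, seed=int(rng.integers(2**31)))
                views.append(a)
                views.append(b)
            # order [a0,b0,a1,b1,...] -> [a0..aN-1, b0..bN-1]
            batch = np.stack(views)[np.r_[0 : 2 * batch_size : 2, 1 : 2 * batch_size : 2]]
            x = Tensor(enc.backbone.preprocess(batch))
            z = enc.project(enc.features(x))
            loss = _nt_xent_tensor(z, config.temperature)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        log.append(float(np.mean(losses)))
    enc.eval()
    return enc, log


def embed(patches: list[Patch], encoder: Encoder,
          batch_size: int = 128) -> list[EmbeddingRecord]:
    """Run tiles through the (frozen) backbone; one record per tile."""
    for p in patches:
        if p.ref.mpp != encoder.config.mpp:
            raise ContrastiveError(
                f"patch at {p.ref.mpp} MPP fed to {encoder.config.mpp} MPP encoder")
    encoder.eval()
    eid = encoder.encoder_id
    out: list[EmbeddingRecord] = []
    for start in range(0, len(patches), batch_size):
        chunk = patches[start : start + batch_size]
        batch = np.stack([p.pixels for p in chunk])
        feats = encoder.features(Tensor(encoder.backbone.preprocess(batch))).data
        for p, v in zip(chunk, feats):
            out.append(EmbeddingRecord(p.ref, v.copy(), eid))
    return out


# -- persistence ---------------------------------------------------------


def save_embeddings(path: Path, records: list[EmbeddingRecord],
                    multiscale: bool = False) -> None:
    path = Path(path)
    np.savez(Path(str(path) + ".npz"), vectors=np.stack([r.vector for r in records]))
    sidecar = {
        "multiscale": multiscale,
        "encoder_id": records[0].encoder_id if records else "",
        "refs": [[r.ref.slide_id, r.ref.mpp, r.ref.row, r.ref.col] for r in records],
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, sort_keys=True))


def load_embeddings(path: Path) -> list[EmbeddingRecord]:
    path = Path(path)
    vectors = np.load(Path(str(path) + ".npz"))["vectors"]
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    return [
        EmbeddingRecord(TileRef(s, m, r, c), v, sidecar["encoder_id"])
        for (s, m, r, c), v in zip(sidecar["refs"], vectors)
    ]


def save_encoder(path: Path, encoder: Encoder) -> None:
    path = Path(path)
    np.savez(Path(str(path) + ".npz"), **encoder.state_dict())
    Path(str(path) + ".json").write_text(json.dumps(asdict(encoder.config), sort_keys=True))


def load_encoder(path: Path) -> Encoder:
    path = Path(path)
    cfg = EncoderConfig(**json.loads(Path(str(path) + ".json").read_text()))
    enc = Encoder(cfg, seed=0)
    state = dict(np.load(Path(str(path) + ".npz")))
    enc.load_state_dict(state)
    enc.eval()
    return enc
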