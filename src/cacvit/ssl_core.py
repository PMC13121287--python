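"""Vision-transformer backbone and label-guided self-distillation training.

The trainer implements the self-distillation scheme in which a student
network matches a momentum (EMA) teacher's sharpened, centered output
distributions across augmented views: the teacher sees only the 2 global
views, the student sees every view, and the loss is the cross-entropy
between teacher and student output distributions averaged over view pairs
(a global view is never matched against itself).  The label-guided variant
adds guided local crops — anchored inside the annotation mask — for labeled
slices, steering the learned features toward small calcified regions while
unlabeled slices follow the standard recipe.

Collapse is avoided the usual way: teacher output centering (running mean
with momentum 0.9) plus temperature sharpening (student 0.1, teacher warmed
from 0.04 to 0.07).  The teacher is an exponential moving average of the
student with momentum on a cosine schedule from 0.996 to 1.0.

Everything runs on the package's NumPy autodiff core, so training is
CPU-bound; the shipped default configuration is a desk-scale profile
(32x32 global views, embed dim 64, depth 3) — the full-scale profile
(ViT-Base/8, 768-dim embeddings, 150 epochs) uses the same code path.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .augment import AugmentParams, multi_crop
from .nn import Tensor

__all__ = [
    "ViTConfig",
    "DinoConfig",
    "VisionTransformer",
    "DinoHead",
    "FeatureMatrix",
    "dino_loss",
    "train_dino",
    "extract_features",
    "pca_feature_map",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class ViTConfig:
    """Backbone geometry.  ViT-Base/8 is (768, 12, 12, 224); the defaults
    here are the desk-scale profile."""

    image_size: int = 32
    patch_size: int = 8
    embed_dim: int = 64
    depth: int = 3
    heads: int = 4
    in_channels: int = 1
    mlp_ratio: float = 2.0

    def __post_init__(self):
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.embed_dim % self.heads:
            raise ValueError("embed_dim must be divisible by heads")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size


@dataclass
class DinoConfig:
    """Training conditions for (label-guided) self-distillation."""

    vit: ViTConfig = field(default_factory=ViTConfig)
    proj_hidden: int = 128
    bottleneck: int = 32
    n_prototypes: int = 64
    epochs: int = 15
    batch_size: int = 16
    lr: float = 5e-3
    weight_decay: float = 0.04
    warmup_epochs: int = 2
    student_temp: float = 0.1
    teacher_temp_start: float = 0.04
    teacher_temp_end: float = 0.07
    teacher_temp_warmup_epochs: int = 10
    center_momentum: float = 0.9
    # EMA momentum schedule: the classic 0.996 -> 1.0 assumes ~1e5 steps; the
    # desk-scale default is faster so the teacher converges within ~1e2 steps
    # while staying slow enough to keep the student/teacher asymmetry.
    ema_start: float = 0.98
    ema_end: float = 0.9995
    clip_grad: float = 3.0
    rlc: int = 8
    glc: int = 4
    augment: AugmentParams = field(default_factory=AugmentParams)

    def __post_init__(self):
        self.augment.global_size = self.vit.image_size
        if self.augment.local_size % self.vit.patch_size:
            raise ValueError("local view size must be divisible by patch_size")


# ---------------------------------------------------------------------------
# Backbone
# ---------------------------------------------------------------------------


def _bilinear_grid_matrix(base_g: int, new_g: int) -> np.ndarray:
    """(new_g^2, base_g^2) bilinear interpolation matrix between patch grids."""
    if new_g == base_g:
        return np.eye(base_g * base_g, dtype=np.float32)
    M = np.zeros((new_g * new_g, base_g * base_g), dtype=np.float32)
    # align-corners mapping of grid centers
    for i in range(new_g):
        for j in range(new_g):
            y = i * (base_g - 1) / max(new_g - 1, 1)
            x = j * (base_g - 1) / max(new_g - 1, 1)
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, base_g - 1), min(x0 + 1, base_g - 1)
            dy, dx = y - y0, x - x0
            row = i * new_g + j
            M[row, y0 * base_g + x0] += (1 - dy) * (1 - dx)
            M[row, y0 * base_g + x1] += (1 - dy) * dx
            M[row, y1 * base_g + x0] += dy * (1 - dx)
            M[row, y1 * base_g + x1] += dy * dx
    return M


class _Attention(nn.Module):
    def __init__(self, dim: int, heads: int, rng):
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.heads = heads
        self.dim = dim

    def forward(self, x: Tensor) -> Tensor:
        B, T, E = x.shape
        h = self.heads
        d = E // h
        qkv = self.qkv(x).reshape(B, T, 3, h, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B, h, T, d)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (d ** -0.5)
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, E)
        return self.proj(out)


class _Mlp(nn.Module):
    def __init__(self, dim: int, hidden: int, rng):
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class _Block(nn.Module):
    def __init__(self, dim: int, heads: int, mlp_ratio: float, rng):
        self.norm1 = nn.LayerNorm(dim)
        self.attn = _Attention(dim, heads, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.mlp = _Mlp(dim, int(dim * mlp_ratio), rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.mlp(self.norm2(x))


class VisionTransformer(nn.Module):
    """Single-channel ViT; positional embeddings are stored on the base
    patch grid and bilinearly interpolated for other input resolutions
    (local crops)."""

    def __init__(self, config: ViTConfig, rng: np.random.Generator):
        self.config = config
        c = config
        pdim = c.patch_size * c.patch_size * c.in_channels
        self.patch_embed = nn.Linear(pdim, c.embed_dim, rng)
        self.cls_token = Tensor(
            (rng.normal(0, 0.02, size=(1, 1, c.embed_dim))).astype(np.float32),
            requires_grad=True)
        self.pos_cls = Tensor(
            (rng.normal(0, 0.02, size=(1, 1, c.embed_dim))).astype(np.float32),
            requires_grad=True)
        self.pos_patch = Tensor(
            (rng.normal(0, 0.02, size=(c.grid * c.grid, c.embed_dim))).astype(np.float32),
            requires_grad=True)
        self.blocks = [_Block(c.embed_dim, c.heads, c.mlp_ratio, rng)
                       for _ in range(c.depth)]
        self.norm = nn.LayerNorm(c.embed_dim)
        self._interp_cache: dict[int, np.ndarray] = {}

    def _pos_for_grid(self, g: int) -> Tensor:
        if g not in self._interp_cache:
            self._interp_cache[g] = _bilinear_grid_matrix(self.config.grid, g)
        M = Tensor(self._interp_cache[g])
        return (M @ self.pos_patch).reshape(1, g * g, self.config.embed_dim)

    def forward(self, x) -> Tensor:
        """x: (B, 1, H, W) array or Tensor -> token embeddings (B, T+1, E)."""
        x = nn.as_tensor(x)
        B, C, H, W = x.shape
        p = self.config.patch_size
        if H % p or W % p:
            raise ValueError(f"input size {(H, W)} incompatible with patch size {p}")
        gh, gw = H // p, W // p
        if gh != gw:
            raise ValueError("square inputs only")
        patches = (x.reshape(B, C, gh, p, gw, p)
                    .transpose(0, 2, 4, 1, 3, 5)
                    .reshape(B, gh * gw, C * p * p))
        tok = self.patch_embed(patches)
        ones = Tensor(np.ones((B, 1, 1), dtype=np.float32))
        cls = ones * self.cls_token
        z = nn.concat([cls + self.pos_cls, tok + self._pos_for_grid(gh)], axis=1)
        for blk in self.blocks:
            z = blk(z)
        return self.norm(z)

    def cls_embedding(self, x) -> Tensor:
        return self.forward(x)[:, 0]

    def patch_embeddings(self, x) -> Tensor:
        return self.forward(x)[:, 1:]


class DinoHead(nn.Module):
    """Projection head: 3-layer MLP to a bottleneck, L2-normalization, then
    a weight-normalized, bias-free map onto the prototype logits.

    Both the bottleneck embedding and the prototype vectors are unit-norm,
    so logits are cosine similarities in [-1, 1] — the scale the 0.04-0.07
    teacher temperature is designed for."""

    def __init__(self, in_dim: int, hidden: int, bottleneck: int, n_prototypes: int,
                 rng: np.random.Generator):
        self.fc1 = nn.Linear(in_dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, hidden, rng)
        self.fc3 = nn.Linear(hidden, bottleneck, rng)
        self.prototypes_v = Tensor(
            rng.normal(0.0, 1.0, size=(bottleneck, n_prototypes)).astype(np.float32),
            requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        z = self.fc3(self.fc2(self.fc1(x).gelu()).gelu())
        norm = ((z * z).sum(axis=-1, keepdims=True) + 1e-8) ** -0.5
        w = self.prototypes_v
        wnorm = ((w * w).sum(axis=0, keepdims=True) + 1e-8) ** -0.5
        return (z * norm) @ (w * wnorm)


class _DinoNet(nn.Module):
    def __init__(self, config: DinoConfig, rng: np.random.Generator):
        self.backbone = VisionTransformer(config.vit, rng)
        self.head = DinoHead(config.vit.embed_dim, config.proj_hidden,
                             config.bottleneck, config.n_prototypes, rng)

    def forward(self, x) -> Tensor:
        return self.head(self.backbone.cls_embedding(x))


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def dino_loss(student_logits, teacher_logits, center, student_temp: float = 0.1,
              teacher_temp: float = 0.04):
    """Self-distillation loss for one image.

    Parameters
    ----------
    student_logits : (V, K) for all V views, the first 2 being the global views
    teacher_logits : (2, K) for the 2 global views (treated as constants)
    center : (K,) running center subtracted from teacher logits

    Returns the mean over (teacher view t, student view s) pairs with s != t
    of the cross-entropy between the sharpened, centered teacher distribution
    and the student's log-softmax.
    """
    s = nn.as_tensor(student_logits)
    t = (teacher_logits.data if isinstance(teacher_logits, Tensor)
         else np.asarray(teacher_logits, dtype=np.float64))
    if not (np.all(np.isfinite(s.data)) and np.all(np.isfinite(t))):
        raise ValueError("non-finite logits")
    V = s.shape[0]
    if t.shape[0] != 2:
        raise ValueError("teacher logits must cover exactly the 2 global views")
    centered = (t - np.asarray(center)) / teacher_temp
    centered = centered - centered.max(axis=-1, keepdims=True)
    e = np.exp(centered)
    probs = e / e.sum(axis=-1, keepdims=True)  # (2, K), no gradient
    log_s = (s * (1.0 / student_temp)).log_softmax(axis=-1)  # (V, K)
    total = None
    n_terms = 0
    for tv in range(2):
        p = Tensor(probs[tv])
        for sv in range(V):
            if sv == tv:
                continue
            ce = -(p * log_s[sv]).sum()
            total = ce if total is None else total + ce
            n_terms += 1
    return total * (1.0 / n_terms)


def _batched_dino_loss(student_global: Tensor, student_local: Tensor | None,
                       local_img_idx: np.ndarray, teacher_probs: np.ndarray,
                       student_temp: float):
    """Vectorized loss over a batch.

    student_global: (2B, K) ordered [view0 of all imgs, view1 of all imgs];
    student_local: (L, K) with ``local_img_idx`` mapping rows to images;
    teacher_probs: (2, B, K) sharpened centered teacher distributions.
    Equals the average of per-image :func:`dino_loss` terms (global
    normalization over all pairs).
    """
    B = teacher_probs.shape[1]
    K = teacher_probs.shape[2]
    logs_g = (student_global * (1.0 / student_temp)).log_softmax(axis=-1)
    terms = None
    n_terms = 0
    # teacher view tv vs the *other* global view
    for tv in (0, 1):
        sv = 1 - tv
        p = Tensor(teacher_probs[tv])  # (B, K)
        sl = logs_g[sv * B:(sv + 1) * B]
        ce = -(p * sl).sum()
        terms = ce if terms is None else terms + ce
        n_terms += B
    if student_local is not None and student_local.shape[0] > 0:
        logs_l = (student_local * (1.0 / student_temp)).log_softmax(axis=-1)
        L = logs_l.shape[0]
        for tv in (0, 1):
            p = Tensor(teacher_probs[tv][local_img_idx])  # (L, K)
            ce = -(p * logs_l).sum()
            terms = terms + ce
            n_terms += L
    return terms * (1.0 / n_terms)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _ema_update(teacher: nn.Module, student: nn.Module, momentum: float) -> None:
    tp = teacher.named_parameters()
    sp = student.named_parameters()
    for k in tp:
        tp[k].data = momentum * tp[k].data + (1.0 - momentum) * sp[k].data


def _stack_views(views, size: int) -> np.ndarray:
    return np.stack([v.image for v in views]).astype(np.float32)[:, None, :, :]


def train_dino(dataset, config: DinoConfig | None = None, label_guided: bool = True,
               seed: int = 0, out_dir: str | Path | None = None):
    """Train a backbone by (label-guided) self-distillation.

    Parameters
    ----------
    dataset : sequence of (slice, mask-or-None) pairs; slices are 2-D arrays
        normalized to [-1, 1], masks are binary/integer annotation grids of
        the same shape.
    label_guided : when False, no guided crops are ever built regardless of
        masks (the standard recipe).

    Returns ``(backbone, log)`` where ``log`` is a dict with per-step loss,
    learning rate, EMA momentum and a counter of guided crops built.
    Deterministic under (dataset, config, seed).
    """
    cfg = config or DinoConfig()
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    student = _DinoNet(cfg, rng)
    teacher = _DinoNet(cfg, np.random.default_rng(seed))  # same init as student
    teacher.load_state_dict(student.state_dict())
    # the teacher is only ever run under no_grad and updated via EMA

    n = len(dataset)
    steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    total_steps = steps_per_epoch * cfg.epochs
    lr_sched = nn.cosine_schedule(cfg.lr, cfg.lr * 1e-2, total_steps,
                                  warmup_steps=cfg.warmup_epochs * steps_per_epoch)
    ema_sched = cfg.ema_end - 0.5 * (cfg.ema_end - cfg.ema_start) * (
        1 + np.cos(np.pi * np.arange(total_steps) / max(total_steps - 1, 1)))

    opt = nn.AdamW(student.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    center = np.zeros(cfg.n_prototypes, dtype=np.float64)
    log = {"step": [], "epoch": [], "loss": [], "lr": [], "ema_momentum": []}
    guided_crop_count = 0
    step = 0

    for epoch in range(cfg.epochs):
        t_frac = min(epoch / max(cfg.teacher_temp_warmup_epochs, 1), 1.0)
        teacher_temp = (cfg.teacher_temp_start
                        + t_frac * (cfg.teacher_temp_end - cfg.teacher_temp_start))
        order = rng.permutation(n)
        for b0 in range(0, n, cfg.batch_size):
            idx = order[b0:b0 + cfg.batch_size]
            B = len(idx)
            globals_, locals_, local_img = [], [], []
            for pos, i in enumerate(idx):
                img, mask = dataset[i]
                glc = cfg.glc if (label_guided and mask is not None
                                  and np.asarray(mask).any()) else 0
                mcs = multi_crop(img, mask if glc else None, rlc=cfg.rlc, glc=glc,
                                 rng=rng, params=cfg.augment)
                guided_crop_count += sum(v.kind == "guided_local" for v in mcs.views)
                globals_.append((mcs.views[0], mcs.views[1]))
                for v in mcs.views[2:]:
                    locals_.append(v)
                    local_img.append(pos)
            g_batch = np.concatenate([
                _stack_views([g[0] for g in globals_], cfg.augment.global_size),
                _stack_views([g[1] for g in globals_], cfg.augment.global_size)])
            l_batch = (_stack_views(locals_, cfg.augment.local_size)
                       if locals_ else None)
            local_idx = np.asarray(local_img, dtype=int)

            with nn.no_grad():
                t_logits = teacher(g_batch).data  # (2B, K)
            t_stack = t_logits.reshape(2, B, -1)
            centered = (t_stack - center) / teacher_temp
            centered = centered - centered.max(axis=-1, keepdims=True)
            e = np.exp(centered)
            t_probs = e / e.sum(axis=-1, keepdims=True)

            s_global = student(g_batch)
            s_local = student(l_batch) if l_batch is not None else None
            loss = _batched_dino_loss(s_global, s_local, local_idx, t_probs,
                                      cfg.student_temp)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at step {step}")
            student.zero_grad()
            loss.backward()
            if cfg.clip_grad:
                total = np.sqrt(sum(float((p.grad ** 2).sum())
                                    for p in student.parameters() if p.grad is not None))
                if total > cfg.clip_grad:
                    scale = cfg.clip_grad / (total + 1e-12)
                    for p in student.parameters():
                        if p.grad is not None:
                            p.grad = p.grad * scale
            opt.lr = float(lr_sched[step])
            opt.step()
            _ema_update(teacher, student, float(ema_sched[step]))
            center = (cfg.center_momentum * center
                      + (1 - cfg.center_momentum) * t_logits.mean(axis=0))

            log["step"].append(step)
            log["epoch"].append(epoch)
            log["loss"].append(float(loss.data))
            log["lr"].append(float(lr_sched[step]))
            log["ema_momentum"].append(float(ema_sched[step]))
            step += 1
        if out_dir is not None:
            save_checkpoint(teacher.backbone, cfg, epoch,
                            Path(out_dir) / f"dino_epoch{epoch:03d}.npz")
    log["guided_crop_count"] = guided_crop_count
    # two bookkeeping definitions of the effective guided-crop ratio: the
    # realized fraction of all local crops, and the nominal labeled-fraction
    # x glc/(rlc+glc) accounting
    n_labeled = sum(1 for _, m in dataset
                    if m is not None and np.asarray(m).any())
    total_locals = (len(dataset) * cfg.rlc + n_labeled * cfg.glc) * cfg.epochs
    log["guided_ratio_realized"] = (guided_crop_count / total_locals
                                    if total_locals else 0.0)
    log["guided_ratio_nominal"] = (n_labeled / len(dataset)) * cfg.glc / (cfg.rlc + cfg.glc)
    if out_dir is not None:
        with open(Path(out_dir) / "dino_log.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["step", "epoch", "loss", "lr", "ema_momentum"])
            w.writerows(zip(log["step"], log["epoch"], log["loss"], log["lr"],
                            log["ema_momentum"]))
    # the teacher backbone is the final feature extractor
    return teacher.backbone, log


# ---------------------------------------------------------------------------
# Feature extraction and visualization
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Per-slice embedding vectors (rows) with a (patient, slice) index."""

    values: np.ndarray
    row_index: list[tuple[str, int]]
    source: str = "cls_token"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if len(self.row_index) != self.values.shape[0]:
            raise ValueError("row_index length must match the number of rows")

    def save(self, path: str | Path) -> None:
        """Dense matrix (.npy) plus a sidecar CSV row index (.index.csv)."""
        path = Path(path)
        np.save(path, self.values)
        import csv as _csv

        with open(path.with_suffix(".index.csv"), "w", newline="") as fh:
            w = _csv.writer(fh)
            w.writerow(["patient_id", "slice_index", "source"])
            for pid, idx in self.row_index:
                w.writerow([pid, idx, self.source])

    @staticmethod
    def load(path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        values = np.load(path.with_suffix(".npy") if path.suffix != ".npy" else path)
        import csv as _csv

        with open(path.with_suffix(".index.csv")) as fh:
            rows = list(_csv.DictReader(fh))
        return FeatureMatrix(values=values,
                             row_index=[(r["patient_id"], int(r["slice_index"]))
                                        for r in rows],
                             source=rows[0]["source"] if rows else "cls_token")


def _prepare_batch(slices, size: int) -> np.ndarray:
    from skimage.transform import resize

    arr = []
    for s in slices:
        img = np.asarray(s, dtype=np.float64)
        if img.shape != (size, size):
            img = resize(img, (size, size), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
        arr.append(img)
    return np.stack(arr).astype(np.float32)[:, None, :, :]


def extract_features(backbone: VisionTransformer, slices,
                     row_index: list[tuple[str, int]] | None = None,
                     batch_size: int = 64, size: int | None = None) -> FeatureMatrix:
    """Final-layer class-token embeddings, one row per slice.

    Slices are fed at their native resolution when it is square and
    divisible by the patch size (positional embeddings are interpolated);
    otherwise they are resized to the backbone's training resolution.
    ``size`` overrides this choice.
    """
    if size is None:
        shape = np.asarray(slices[0]).shape if len(slices) else (0, 0)
        if (shape[0] == shape[1] and shape[0] > 0
                and shape[0] % backbone.config.patch_size == 0):
            size = int(shape[0])
        else:
            size = backbone.config.image_size
    if row_index is None:
        row_index = [("", i) for i in range(len(slices))]
    rows = []
    for b0 in range(0, len(slices), batch_size):
        batch = _prepare_batch(slices[b0:b0 + batch_size], size)
        with nn.no_grad():
            rows.append(backbone.cls_embedding(batch).data.astype(np.float64))
    values = np.concatenate(rows, axis=0) if rows else np.empty((0, backbone.config.embed_dim))
    return FeatureMatrix(values=values, row_index=list(row_index))


def pca_feature_map(backbone: VisionTransformer, slice_img: np.ndarray,
                    n_components: int = 3) -> np.ndarray:
    """Project patch-token embeddings onto principal components.

    Returns an (H, W, n_components) map scaled to [0, 1], upsampled from the
    patch grid to the slice size.  Zero-variance token sets (e.g. a constant
    input) yield an all-zero map.
    """
    from skimage.transform import resize

    cfg = backbone.config
    if n_components > cfg.embed_dim:
        raise ValueError("n_components cannot exceed the embedding dimension")
    arr = np.asarray(slice_img)
    H, W = arr.shape
    if np.all(arr == arr.flat[0]):
        # a constant image carries no spatial information; tokens differ only
        # through positional embeddings, so the map is defined as all-zero
        return np.zeros((H, W, n_components))
    batch = _prepare_batch([slice_img], cfg.image_size)
    with nn.no_grad():
        tokens = backbone.patch_embeddings(batch).data[0]  # (g*g, E)
    g = cfg.grid
    centered = tokens - tokens.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0.0):
        return np.zeros((H, W, n_components))
    # PCA via SVD on the centered token matrix
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    comps = centered @ vt[:n_components].T  # (g*g, n_components)
    grid_map = comps.reshape(g, g, n_components)
    up = resize(grid_map, (H, W, n_components), order=1, mode="edge",
                anti_aliasing=False, preserve_range=True)
    lo = up.min(axis=(0, 1), keepdims=True)
    hi = up.max(axis=(0, 1), keepdims=True)
    rng_ = np.where(hi - lo > 0, hi - lo, 1.0)
    return (up - lo) / rng_


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(backbone: VisionTransformer, config: DinoConfig, epoch: int,
                    path: str | Path) -> None:
    """Self-describing checkpoint: backbone parameters + geometry + epoch."""
    meta = dict(asdict(config.vit), epoch=epoch)
    state = {f"param/{k}": v for k, v in backbone.state_dict().items()}
    np.savez(path, __meta__=np.array([repr(meta)]), **state)


def load_checkpoint(path: str | Path) -> tuple[VisionTransformer, int]:
    import ast

    data = np.load(path, allow_pickle=False)
    meta = ast.literal_eval(str(data["__meta__"][0]))
    epoch = int(meta.pop("epoch"))
    vit_cfg = ViTConfig(**meta)
    backbone = VisionTransformer(vit_cfg, np.random.default_rng(0))
    backbone.load_state_dict({k[len("param/"):]: data[k] for k in data.files
                              if k.startswith("param/")})
    return backbone, epoch
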