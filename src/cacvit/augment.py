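"""Medical multi-crop augmentation, including guided local crops.

The multi-crop scheme produces 2 global views plus a set of small local
views per slice.  For annotated slices, a number of the local views are
*guided*: their anchor pixel is drawn uniformly from the annotated lesion
mask so the crop is guaranteed to contain calcification.  Defaults follow
the label-guided recipe: 8 random local crops for every image plus 4 guided
local crops for labeled images (12 local views total), local crop areas
between 5% and 40% of the image.

Photometric transforms are the medical variant of the standard
self-distillation recipe: horizontal/vertical flips, 3x3 Gaussian blur,
brightness/contrast jitter within +/-40%, sharpness factor 1.5 with p=0.8,
and additive Gaussian noise.  Solarization and hue/saturation jitter are
RGB-specific and never applied.  Views are single-channel arrays in [-1, 1];
brightness/contrast/sharpness operate in a [0, 1] working range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = [
    "AugmentParams",
    "CropView",
    "MultiCropSet",
    "sample_guided_crop",
    "sample_random_crop",
    "multi_crop",
    "medical_transforms",
]


@dataclass
class AugmentParams:
    """Probabilities and magnitudes of the photometric transforms.

    Setting every probability and the jitter magnitude to 0 makes
    :func:`medical_transforms` the identity.
    """

    hflip_p: float = 0.5
    vflip_p: float = 0.5
    blur_p: float = 0.5
    jitter: float = 0.4          # brightness/contrast factor in [1-j, 1+j]
    sharpness_factor: float = 1.5
    sharpness_p: float = 0.8
    noise_sigma: float = 0.01    # fraction of the [0, 1] dynamic range
    noise_p: float = 0.5
    global_size: int = 32
    local_size: int = 16
    global_scale: tuple[float, float] = (0.4, 1.0)
    local_scale: tuple[float, float] = (0.05, 0.4)

    @staticmethod
    def identity() -> "AugmentParams":
        return AugmentParams(hflip_p=0.0, vflip_p=0.0, blur_p=0.0, jitter=0.0,
                             sharpness_p=0.0, noise_p=0.0)


@dataclass
class CropView:
    image: np.ndarray
    kind: str  # global | random_local | guided_local
    source_box: tuple[int, int, int, int]  # (row0, col0, height, width)
    anchor: tuple[int, int] | None = None

    def __post_init__(self):
        if self.kind not in ("global", "random_local", "guided_local"):
            raise ValueError(f"unknown view kind {self.kind!r}")
        if self.anchor is not None:
            r0, c0, h, w = self.source_box
            ar, ac = self.anchor
            if not (r0 <= ar < r0 + h and c0 <= ac < c0 + w):
                raise ValueError("anchor must lie inside the source box")


@dataclass
class MultiCropSet:
    views: list[CropView]
    rlc: int
    glc: int

    def __post_init__(self):
        kinds = [v.kind for v in self.views]
        n_global = kinds.count("global")
        if n_global != 2 or kinds[:2] != ["global", "global"]:
            raise ValueError("a multi-crop set starts with exactly 2 global views")
        if kinds.count("random_local") != self.rlc:
            raise ValueError("random-local view count does not match rlc")
        if kinds.count("guided_local") not in (0, self.glc):
            raise ValueError("guided-local view count must be 0 or glc")

    @property
    def n_local(self) -> int:
        return len(self.views) - 2


def _resize(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape == (size, size):
        return img.astype(np.float64, copy=True)
    return _sk_resize(img, (size, size), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def _crop_side(shape: tuple[int, int], scale_range: tuple[float, float],
               rng: np.random.Generator) -> int:
    h, w = shape
    s = rng.uniform(*scale_range)
    side = int(np.round(np.sqrt(s * h * w)))
    return int(np.clip(side, 1, min(h, w)))


def sample_random_crop(slice_img: np.ndarray, scale_range: tuple[float, float],
                       rng: np.random.Generator, out_size: int,
                       kind: str = "random_local") -> CropView:
    h, w = slice_img.shape
    side = _crop_side((h, w), scale_range, rng)
    r0 = int(rng.integers(0, h - side + 1))
    c0 = int(rng.integers(0, w - side + 1))
    patch = slice_img[r0:r0 + side, c0:c0 + side]
    return CropView(image=_resize(patch, out_size), kind=kind,
                    source_box=(r0, c0, side, side))


def sample_guided_crop(slice_img: np.ndarray, mask: np.ndarray,
                       scale_range: tuple[float, float],
                       rng: np.random.Generator, out_size: int = 16) -> CropView:
    """A local crop anchored on a pixel drawn from the annotation mask.

    The crop is a square of area uniform in ``scale_range`` (as a fraction
    of the image), centered on the anchor and shifted as needed to stay in
    bounds — the anchor always remains inside the crop.
    """
    mask = np.asarray(mask)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("guided crop requires a non-empty annotation mask")
    h, w = slice_img.shape
    j = int(rng.integers(rows.size))
    ar, ac = int(rows[j]), int(cols[j])
    side = _crop_side((h, w), scale_range, rng)
    r0 = int(np.clip(ar - side // 2, 0, h - side))
    c0 = int(np.clip(ac - side // 2, 0, w - side))
    patch = slice_img[r0:r0 + side, c0:c0 + side]
    return CropView(image=_resize(patch, out_size), kind="guided_local",
                    source_box=(r0, c0, side, side), anchor=(ar, ac))


def medical_transforms(view: CropView, rng: np.random.Generator,
                       params: AugmentParams | None = None) -> CropView:
    """Apply the medical photometric transform stack to one view in place.

    Order: horizontal flip, vertical flip, Gaussian blur (3x3), brightness
    then contrast jitter, sharpness, additive noise; output clipped to
    [-1, 1].
    """
    p = params or AugmentParams()
    img = view.image.astype(np.float64, copy=True)
    if rng.random() < p.hflip_p:
        img = img[:, ::-1].copy()
    if rng.random() < p.vflip_p:
        img = img[::-1, :].copy()
    if rng.random() < p.blur_p:
        img = _gaussian_blur3(img)
    work = (img + 1.0) / 2.0  # [0, 1] working range
    if p.jitter > 0:
        work = work * rng.uniform(1 - p.jitter, 1 + p.jitter)  # brightness
        m = work.mean()
        work = (work - m) * rng.uniform(1 - p.jitter, 1 + p.jitter) + m  # contrast
    if rng.random() < p.sharpness_p:
        blurred = _gaussian_blur3(work)
        work = blurred + p.sharpness_factor * (work - blurred)
    if rng.random() < p.noise_p:
        work = work + rng.normal(0.0, p.noise_sigma, size=work.shape)
    img = np.clip(2.0 * work - 1.0, -1.0, 1.0)
    view.image = img
    return view


_BLUR3 = None


def _gaussian_blur3(img: np.ndarray) -> np.ndarray:
    """3x3 Gaussian kernel (sigma 0.8), edge-replicated borders."""
    global _BLUR3
    if _BLUR3 is None:
        ax = np.array([-1.0, 0.0, 1.0])
        k1 = np.exp(-(ax ** 2) / (2 * 0.8 ** 2))
        k1 /= k1.sum()
        _BLUR3 = np.outer(k1, k1)
    return ndimage.convolve(img, _BLUR3, mode="nearest")


def multi_crop(slice_img: np.ndarray, mask: np.ndarray | None = None,
               rlc: int = 8, glc: int = 4,
               rng: np.random.Generator | None = None,
               params: AugmentParams | None = None) -> MultiCropSet:
    """Build a multi-crop view set for one normalized slice.

    Labeled slices (non-empty ``mask``) receive 2 global + ``rlc`` random
    local + ``glc`` guided local views; unlabeled slices receive 2 global +
    ``rlc`` random local views.  With ``glc=0`` the output is structurally
    the standard (unguided) multi-crop.  Every view passes through
    :func:`medical_transforms`.
    """
    rng = rng if rng is not None else np.random.default_rng()
    p = params or AugmentParams()
    views: list[CropView] = []
    for _ in range(2):
        v = sample_random_crop(slice_img, p.global_scale, rng, p.global_size, kind="global")
        views.append(medical_transforms(v, rng, p))
    for _ in range(rlc):
        v = sample_random_crop(slice_img, p.local_scale, rng, p.local_size)
        views.append(medical_transforms(v, rng, p))
    has_mask = mask is not None and np.asarray(mask).any()
    if has_mask:
        for _ in range(glc):
            v = sample_guided_crop(slice_img, mask, p.local_scale, rng, p.local_size)
            views.append(medical_transforms(v, rng, p))
    return MultiCropSet(views=views, rlc=rlc, glc=glc)
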