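"""Raw z-stacks to classifier-ready tensors.

The fixed pipeline is: maximum-intensity projection over z, 16->8-bit
conversion, composition of the stained channels into an RGB image
(BIII-tubulin -> red, RBP -> green, DAPI -> blue, pitch-black placeholders
for unused slots), per-channel autocontrast, tiling into non-overlapping
crops, bilinear resize, and mean/std normalization with the ImageNet
constants.  ``preprocess_field`` chains all steps; the single-step
functions are exposed for testing and reuse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

#: Marker names with a fixed RGB slot.  Any other marker name is treated as
#: an RNA-binding-protein stain and lands in the green slot.
DAPI = "DAPI"
BIII = "BIII"

#: Sentinel marker for an unused (pitch-black) color slot.
PLACEHOLDER = "PLACEHOLDER"

#: RGB slot order used throughout: index 0 = red, 1 = green, 2 = blue.
SLOT_NAMES = ("red", "green", "blue")


@dataclass(frozen=True)
class NormalizationConstants:
    """Per-slot mean and std applied after scaling intensities to [0, 1]."""

    mean: tuple[float, float, float] = (0.485, 0.456, 0.406)
    std: tuple[float, float, float] = (0.229, 0.224, 0.225)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.std):
            raise ValueError("normalization std must be positive")


IMAGENET = NormalizationConstants()


@dataclass(frozen=True)
class ChannelCombination:
    """A subset of markers with their derived RGB slot assignment.

    ``members`` is the marker subset; ``slot_map`` maps red/green/blue to a
    marker name or PLACEHOLDER.  BIII occupies red, the RBP green and DAPI
    blue whenever present.
    """

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate markers in combination: {self.members}")
        n_rbp = sum(1 for m in self.members if m not in (DAPI, BIII))
        if n_rbp > 1:
            raise ValueError("at most one RBP marker per combination")

    @property
    def slot_map(self) -> tuple[str, str, str]:
        red = BIII if BIII in self.members else PLACEHOLDER
        blue = DAPI if DAPI in self.members else PLACEHOLDER
        green = PLACEHOLDER
        for m in self.members:
            if m not in (DAPI, BIII):
                green = m
        return (red, green, blue)

    @property
    def name(self) -> str:
        order = [m for m in (DAPI, BIII) if m in self.members]
        order += [m for m in self.members if m not in (DAPI, BIII)]
        return ":".join(order)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


@dataclass
class RGBImage8:
    """8-bit H x W x 3 image plus the marker occupying each slot."""

    pixels: np.ndarray
    slot_map: tuple[str, str, str] = (PLACEHOLDER, PLACEHOLDER, PLACEHOLDER)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected HxWx3 pixels, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {self.pixels.dtype}")


def max_intensity_projection(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum across the z-planes of a (n_z, H, W) stack."""
    zstack = np.asarray(zstack)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError(f"expected non-empty (n_z, H, W) stack, got shape {zstack.shape}")
    return zstack.max(axis=0)


def to_8bit(img16: np.ndarray) -> np.ndarray:
    """16->8-bit by floor(x / 256); content-independent fixed scaling."""
    img16 = np.asarray(img16)
    return (img16 // 256).astype(np.uint8)


def compose_rgb(channels: Mapping[str, np.ndarray], combo: ChannelCombination) -> RGBImage8:
    """Fill RGB slots from 16-bit channels; pitch-black placeholders elsewhere."""
    missing = [m for m in combo.members if m not in channels]
    if missing:
        raise KeyError(f"marker(s) {missing} required by combination {combo.name!r} "
                       f"not present in channels {sorted(channels)}")
    slot_map = combo.slot_map
    ref = next(iter(channels.values()))
    h, w = np.asarray(ref).shape[-2:]
    out = np.zeros((h, w, 3), dtype=np.uint8)
    for i, marker in enumerate(slot_map):
        if marker != PLACEHOLDER:
            out[:, :, i] = to_8bit(channels[marker])
    return RGBImage8(out, slot_map)


def autocontrast(img: RGBImage8, cutoff_percent: float = 0.1) -> RGBImage8:
    """Per-channel histogram stretch after trimming ``cutoff_percent`` of
    pixels from each tail; constant (and placeholder) channels pass through.

    Matches Pillow's ``ImageOps.autocontrast`` semantics: the cumulative
    histogram locates the lowest and highest surviving intensities, which
    are remapped linearly to 0 and 255 with clipping.
    """
    out = img.pixels.copy()
    n = out.shape[0] * out.shape[1]
    cut = int(n * cutoff_percent / 100.0)
    for i, marker in enumerate(img.slot_map):
        if marker == PLACEHOLDER:
            continue
        ch = out[:, :, i]
        hist = np.bincount(ch.ravel(), minlength=256)
        cum = np.cumsum(hist)
        lo_idx = int(np.searchsorted(cum, cut + 1))
        hi_idx = 255 - int(np.searchsorted(np.cumsum(hist[::-1]), cut + 1))
        if hi_idx <= lo_idx:
            continue  # constant or near-constant channel: unchanged
        # LUT built exactly as Pillow's ImageOps.autocontrast (truncation)
        scale = 255.0 / (hi_idx - lo_idx)
        offset = -lo_idx * scale
        lut = np.clip(np.floor(np.arange(256) * scale + offset), 0, 255).astype(np.uint8)
        out[:, :, i] = lut[ch]
    return RGBImage8(out, img.slot_map)


def tile(img: RGBImage8, tile_size: int = 270) -> list[RGBImage8]:
    """Split into a row-major grid of non-overlapping ``tile_size`` crops.

    A 1080 x 1080 field yields the canonical 16 crops of 270 x 270.
    """
    h, w = img.pixels.shape[:2]
    if h % tile_size or w % tile_size:
        raise ValueError(f"image of {h}x{w} not divisible by tile size {tile_size}")
    tiles = []
    for r in range(h // tile_size):
        for c in range(w // tile_size):
            block = img.pixels[r * tile_size:(r + 1) * tile_size,
                               c * tile_size:(c + 1) * tile_size]
            tiles.append(RGBImage8(block.copy(), img.slot_map))
    return tiles


def resize_and_normalize(img: RGBImage8, constants: NormalizationConstants = IMAGENET,
                         size: int = 224) -> np.ndarray:
    """Bilinear resize to ``size`` x ``size``, scale to [0, 1], then
    (x - mean) / std per slot.  Returns float64 (size, size, 3)."""
    scaled = img.pixels.astype(np.float64) / 255.0
    resized = _sk_resize(scaled, (size, size), order=1, anti_aliasing=False,
                         preserve_range=True)
    mean = np.asarray(constants.mean)
    std = np.asarray(constants.std)
    return (resized - mean) / std


def augment(img: np.ndarray) -> list[np.ndarray]:
    """Sixfold dihedral augmentation of a square image.

    Returns ``[original, rot90, hmirror, vmirror, rot90(hmirror),
    rot90(vmirror)]`` in that fixed order.  Works on H x W or H x W x C.
    """
    img = np.asarray(img)
    if img.shape[0] != img.shape[1]:
        raise ValueError(f"augmentation requires a square image, got {img.shape[:2]}")
    rot = lambda a: np.rot90(a, axes=(0, 1))
    hmirror = img[:, ::-1]
    vmirror = img[::-1, :]
    return [img, rot(img), hmirror, vmirror, rot(hmirror), rot(vmirror)]


def preprocess_field(channels: Mapping[str, np.ndarray], combo: ChannelCombination,
                     constants: NormalizationConstants = IMAGENET,
                     cutoff_percent: float = 0.1, tile_size: int = 270,
                     size: int = 224) -> list[np.ndarray]:
    """Full chain MIP -> 8-bit -> compose -> autocontrast -> tile -> resize
    -> normalize for one field of view.

    ``channels`` maps marker name to a (n_z, H, W) 16-bit stack (a single
    H x W plane is accepted as a 1-plane stack).  Returns one normalized
    array per crop, in row-major tile order.
    """
    mips = {}
    for marker, stack in channels.items():
        stack = np.asarray(stack)
        if stack.ndim == 2:
            stack = stack[None]
        mips[marker] = max_intensity_projection(stack)
    rgb = compose_rgb(mips, combo)
    rgb = autocontrast(rgb, cutoff_percent)
    return [resize_and_normalize(t, constants, size) for t in tile(rgb, tile_size)]
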