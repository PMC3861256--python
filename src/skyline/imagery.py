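"""Image I/O, L*a*b* decomposition, condition transforms, coordinate algebra.

Horizon positions are always expressed as normalized vertical coordinates of
the *full upright* image: 0 at the top edge, 1 at the bottom, with pixel row
``r`` of an ``H``-row image centered at ``(r + 0.5) / H``. Six stimulus
conditions manipulate the image — norm (identity), inverted (vertical
mirror), blurred (Gaussian low-pass), and the lower/middle/upper subwindows
that crop to two thirds of the rows and then trim columns until the original
aspect ratio is restored. Every transform carries a :class:`CoordinateMap`
so estimates made in the conditioned image can be mapped back to full-image
coordinates, which is what makes estimates comparable across conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image as _PILImage
from scipy.ndimage import gaussian_filter
from skimage.color import rgb2lab

from ._records import ImageRecord

__all__ = [
    "CONDITIONS",
    "LabImage",
    "ConditionSpec",
    "ConditionedImage",
    "CoordinateMap",
    "read_image",
    "write_image",
    "to_lab",
    "apply_condition",
    "to_full_coords",
]

CONDITIONS = ("norm", "inverted", "blurred", "lower", "middle", "upper")


@dataclass
class LabImage:
    """CIE 1976 L*a*b* channels of one image (D65 white point).

    L* lies in [0, 100]; a* and b* are signed chromatic axes. All three
    channels share identical dimensions.
    """

    L_channel: np.ndarray
    a_channel: np.ndarray
    b_channel: np.ndarray

    def __post_init__(self) -> None:
        if not (
            self.L_channel.shape == self.a_channel.shape == self.b_channel.shape
        ):
            raise ValueError("L*, a*, b* channels must share dimensions")

    def channel(self, tag: str) -> np.ndarray:
        try:
            return {"L": self.L_channel, "a": self.a_channel,
                    "b": self.b_channel}[tag]
        except KeyError:
            raise ValueError(f"unknown channel tag {tag!r}; use 'L', 'a', 'b'")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L_channel.shape


@dataclass
class ConditionSpec:
    """One of the six stimulus manipulations.

    ``blur_sigma_fraction`` (blurred only) is the Gaussian sigma as a
    fraction of image height, so the filter scales with resolution; ``seed``
    drives the random left/right order of column removal for the subwindow
    conditions.
    """

    name: str
    blur_sigma_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in CONDITIONS:
            raise ValueError(
                f"unknown condition {self.name!r}; expected one of {CONDITIONS}"
            )


@dataclass
class ConditionedImage:
    pixels: np.ndarray  # H' x W' x 3 uint8
    condition: str
    source_id: str = ""
    scene_class: str = ""

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class CoordinateMap:
    """Affine map from window-normalized to full-image-normalized positions.

    ``to_full(y) = offset + scale * y`` for un-flipped windows; a flipped
    window (the inverted condition) mirrors the result through the image
    center: ``to_full(y) = 1 - (offset + scale * y)``.
    """

    scale: float = 1.0
    offset: float = 0.0
    flip: bool = False

    def to_full(self, y: float) -> float:
        v = self.offset + self.scale * float(y)
        if self.flip:
            v = 1.0 - v
        return v

    def to_window(self, y_full: float) -> float:
        v = 1.0 - float(y_full) if self.flip else float(y_full)
        return (v - self.offset) / self.scale

    def to_json(self) -> str:
        return json.dumps(
            {"scale": self.scale, "offset": self.offset, "flip": self.flip}
        )

    @classmethod
    def from_json(cls, s: str) -> "CoordinateMap":
        d = json.loads(s)
        return cls(scale=d["scale"], offset=d["offset"], flip=d["flip"])


def read_image(path, id: str | None = None) -> ImageRecord:
    """Read a PNG/JPEG file into an :class:`ImageRecord`.

    Grayscale files are promoted to three identical channels. The record's
    scene class and true horizon are unknown for files read from disk and
    are filled with neutral placeholders ('other', 0.5).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file does not exist: {path}")
    try:
        with _PILImage.open(path) as im:
            if im.mode in ("L", "I", "I;16", "F"):
                im = im.convert("L").convert("RGB")
            elif im.mode != "RGB":
                im = im.convert("RGB")
            pixels = np.asarray(im, dtype=np.uint8)
    except Exception as exc:
        raise ValueError(f"cannot read image file {path}: {exc}") from exc
    return ImageRecord(
        id=id if id is not None else path.stem,
        pixels=pixels,
        scene_class="other",
        true_horizon=0.5,
    )


def write_image(image: ImageRecord | ConditionedImage, path) -> None:
    """Write an image to disk as PNG (lossless) or JPEG by extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _PILImage.fromarray(image.pixels, mode="RGB").save(path)


def _pixels_of(image) -> np.ndarray:
    if isinstance(image, np.ndarray):
        return image
    return image.pixels


def to_lab(image) -> LabImage:
    """sRGB -> XYZ (D65) -> CIE L*a*b* decomposition of an 8-bit image."""
    pixels = _pixels_of(image)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 sRGB pixels, got {pixels.shape}")
    lab = rgb2lab(pixels)
    return LabImage(
        L_channel=lab[..., 0], a_channel=lab[..., 1], b_channel=lab[..., 2]
    )


def _trim_columns(
    pixels: np.ndarray, orig_ratio: float, rng: np.random.Generator
) -> np.ndarray:
    """Remove columns alternately from right/left (seeded starting side)
    until the width:height ratio is as close to the original as one column
    allows."""
    h = pixels.shape[0]
    target_w = int(round(orig_ratio * h))
    n_remove = max(pixels.shape[1] - target_w, 0)
    left = 0
    right = pixels.shape[1]
    from_right = bool(rng.integers(0, 2))
    for _ in range(n_remove):
        if from_right:
            right -= 1
        else:
            left += 1
        from_right = not from_right
    return pixels[:, left:right]


def apply_condition(
    image: ImageRecord, spec: ConditionSpec
) -> tuple[ConditionedImage, CoordinateMap]:
    """Apply one of the six stimulus conditions.

    Returns the transformed image together with the coordinate map that
    takes window-normalized estimates back to full-image coordinates.

    Row-crop rounding: the subwindow conditions remove ``floor(H/6)`` rows
    from top and bottom (middle) or ``floor(H/3)`` rows from top (lower) or
    bottom (upper); any remainder rows stay with the kept block.
    """
    pixels = image.pixels
    H, W = pixels.shape[:2]
    rng = np.random.default_rng(spec.seed)
    name = spec.name

    if name == "norm":
        return (
            ConditionedImage(pixels.copy(), name, image.id, image.scene_class),
            CoordinateMap(),
        )
    if name == "inverted":
        return (
            ConditionedImage(
                pixels[::-1].copy(), name, image.id, image.scene_class
            ),
            CoordinateMap(flip=True),
        )
    if name == "blurred":
        sigma = spec.blur_sigma_fraction * H
        blurred = np.empty_like(pixels)
        for c in range(3):
            blurred[..., c] = np.clip(
                np.round(
                    gaussian_filter(
                        pixels[..., c].astype(float), sigma, mode="reflect"
                    )
                ),
                0,
                255,
            ).astype(np.uint8)
        return (
            ConditionedImage(blurred, name, image.id, image.scene_class),
            CoordinateMap(),
        )

    orig_ratio = W / H
    if name == "lower":
        r0 = H // 3
        rows = pixels[r0:]
    elif name == "middle":
        d = H // 6
        rows = pixels[d : H - d]
        r0 = d
    elif name == "upper":
        rows = pixels[: H - H // 3]
        r0 = 0
    else:  # pragma: no cover - ConditionSpec already validates
        raise ValueError(f"unknown condition {name!r}")
    trimmed = _trim_columns(rows, orig_ratio, rng)
    h = rows.shape[0]
    cmap = CoordinateMap(scale=h / H, offset=r0 / H)
    return (
        ConditionedImage(trimmed.copy(), name, image.id, image.scene_class),
        cmap,
    )


def to_full_coords(
    window_position: float, cmap: CoordinateMap
) -> tuple[float, bool]:
    """Map a window-normalized estimate to full-image coordinates.

    Returns ``(position, clamped)``; positions that land outside [0, 1]
    (possible only for inputs outside the window span) are clamped to the
    boundary and flagged.
    """
    v = cmap.to_full(window_position)
    clamped = not 0.0 <= v <= 1.0
    return (float(np.clip(v, 0.0, 1.0)), clamped)
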