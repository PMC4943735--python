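"""Photograph loading, white-standard calibration, cropping and luminance.

Field photographs of animal bodies are taken under uncontrolled natural
light. To make colors comparable across photos, each frame includes an
in-frame white reference (a white ruler); channels are rescaled by a
per-channel linear gain so that the mean color over the reference region
equals a target white. Downstream feature extraction consumes the
calibrated, body-cropped image and (for the pattern-only pathway) its
luminance.

All pixel data are gamma-encoded sRGB reals in [0, 1], row-major, with
0-based half-open rectangle coordinates throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

#: ITU-R BT.601 luma weights.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

MIN_IMAGE_SIDE = 32


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class ReferenceRegion:
    """0-based half-open rectangle marking the in-frame white standard."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValidationError(f"empty reference region {self}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValidationError(f"negative reference coordinates {self}")
        if (self.row1 - self.row0) * (self.col1 - self.col0) < 16:
            raise ValidationError("reference region must cover >= 16 pixels")

    def check_inside(self, height: int, width: int) -> None:
        if self.row1 > height or self.col1 > width:
            raise ValidationError(
                f"reference region {self} exceeds image bounds {height}x{width}"
            )


@dataclass(frozen=True)
class CropBox:
    """0-based half-open rectangle delimiting the body extent."""

    row0: int
    col0: int
    row1: int
    col1: int

    def __post_init__(self) -> None:
        if not (self.row0 < self.row1 and self.col0 < self.col1):
            raise ValidationError(f"empty crop box {self}")
        if self.row0 < 0 or self.col0 < 0:
            raise ValidationError(f"negative crop coordinates {self}")

    def check_inside(self, height: int, width: int) -> None:
        if self.row1 > height or self.col1 > width:
            raise ValidationError(
                f"crop box {self} exceeds image bounds {height}x{width}"
            )

    def compose(self, inner: "CropBox") -> "CropBox":
        """Box selecting, in the original frame, what ``inner`` selects in the crop."""
        return CropBox(
            self.row0 + inner.row0,
            self.col0 + inner.col0,
            self.row0 + inner.row1,
            self.col0 + inner.col1,
        )


def _check_pixels(pixels: np.ndarray, min_side: int = 1) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValidationError(f"expected HxWx3 pixel array, got shape {pixels.shape}")
    if pixels.shape[0] < min_side or pixels.shape[1] < min_side:
        raise ValidationError(
            f"image {pixels.shape[0]}x{pixels.shape[1]} smaller than "
            f"{min_side}x{min_side}"
        )
    if not np.isfinite(pixels).all():
        raise ValidationError("non-finite pixel values")
    if pixels.min() < 0 or pixels.max() > 1:
        raise ValidationError("pixel values outside [0, 1]")
    return pixels


@dataclass
class RawImage:
    """A decoded photograph: H×W×3 sRGB reals in [0, 1]."""

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = _check_pixels(self.pixels, min_side=MIN_IMAGE_SIDE)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class CalibratedImage:
    """A white-standardized image plus the gains that produced it."""

    pixels: np.ndarray
    gains: np.ndarray = field(default_factory=lambda: np.ones(3))
    reference_white: np.ndarray = field(default_factory=lambda: np.ones(3))
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = _check_pixels(self.pixels)
        self.gains = np.asarray(self.gains, dtype=float)
        self.reference_white = np.asarray(self.reference_white, dtype=float)
        if self.gains.shape != (3,) or (self.gains <= 0).any():
            raise ValidationError("gains must be 3 positive reals")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def load_image(path: str) -> RawImage:
    """Load a PNG/TIFF/JPEG photo, normalizing bit depth to [0, 1] floats.

    Grayscale sources are replicated to 3 channels; an alpha channel, if
    present, is dropped.
    """
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by plugin
        raise IOError(f"cannot decode image file {path!r}: {exc}") from exc
    arr = np.asarray(arr)
    if np.issubdtype(arr.dtype, np.integer):
        scale = float(np.iinfo(arr.dtype).max)
        pixels = arr.astype(float) / scale
    else:
        pixels = arr.astype(float)
    if pixels.ndim == 2:
        pixels = np.stack([pixels] * 3, axis=-1)
    elif pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    elif pixels.ndim != 3 or pixels.shape[2] != 3:
        raise IOError(f"unsupported channel layout {arr.shape} in {path!r}")
    pixels = np.clip(pixels, 0.0, 1.0)
    return RawImage(pixels=pixels, source_path=str(path))


def save_png(path: str, pixels: np.ndarray) -> None:
    """Write an [0,1] float RGB array as 8-bit PNG."""
    arr = np.clip(np.asarray(pixels, dtype=float), 0.0, 1.0)
    iio.imwrite(path, np.round(arr * 255).astype(np.uint8))


def calibrate_white(
    img: RawImage | CalibratedImage,
    ref: ReferenceRegion,
    reference_white: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> CalibratedImage:
    """White-standardize: per-channel gain so the reference region means
    equal ``reference_white``, then clip to [0, 1].

    The gain model is the white-patch model: ``g_c = white_c / mean_c(ref)``,
    with no offset term. Applying the operation twice with the same region
    is idempotent (up to clipping).
    """
    ref.check_inside(img.pixels.shape[0], img.pixels.shape[1])
    white = np.asarray(reference_white, dtype=float)
    patch = img.pixels[ref.row0 : ref.row1, ref.col0 : ref.col1, :]
    means = patch.reshape(-1, 3).mean(axis=0)
    if (means <= 0).any():
        raise ValidationError(
            "degenerate white reference: a channel mean over the region is 0"
        )
    gains = white / means
    pixels = np.clip(img.pixels * gains, 0.0, 1.0)
    image_id = getattr(img, "image_id", "") or getattr(img, "source_path", "")
    return CalibratedImage(
        pixels=pixels, gains=gains, reference_white=white, image_id=image_id
    )


def crop_body(img: CalibratedImage, box: CropBox) -> CalibratedImage:
    """Crop to the body extent, preserving calibration metadata."""
    box.check_inside(img.height, img.width)
    return replace(img, pixels=img.pixels[box.row0 : box.row1, box.col0 : box.col1, :])


def to_luminance(img: CalibratedImage | np.ndarray) -> np.ndarray:
    """BT.601 luma: L = 0.299 R + 0.587 G + 0.114 B, pixelwise."""
    pixels = img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)
    return pixels @ LUMA_WEIGHTS


def pixels_to_length(pixel_span: float, scale_pixels_per_unit: float) -> float:
    """Convert a measured pixel span to physical length given the image scale.

    Landmark placement (e.g. snout and vent for SVL) is manual; only the
    unit conversion is provided.
    """
    if pixel_span <= 0 or scale_pixels_per_unit <= 0:
        raise ValidationError("pixel span and scale must be positive")
    return pixel_span / scale_pixels_per_unit


def resize_max_side(pixels: np.ndarray, max_side: int = 256) -> np.ndarray:
    """Downsample so the longer side is at most ``max_side`` (no upscaling).

    Full-resolution field photos (thousands of pixels per side) are far
    larger than feature extraction needs; anti-aliased resampling keeps
    pattern structure while bounding cost.
    """
    pixels = np.asarray(pixels, dtype=float)
    h, w = pixels.shape[:2]
    longer = max(h, w)
    if longer <= max_side:
        return pixels
    factor = max_side / longer
    out_shape = (max(1, round(h * factor)), max(1, round(w * factor)))
    out = _sk_resize(pixels, out_shape, anti_aliasing=True, preserve_range=True)
    return np.clip(out, 0.0, 1.0)
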