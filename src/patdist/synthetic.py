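"""Synthetic pattern-class images and capture metadata.

The generators stand in for field photographs and capture records so the
whole pipeline is testable end to end. Pattern classes vary along the
three axes that define real body-pattern categories — base color,
stripes, and blotches — plus overall brightness; images carry a rendered
white reference strip so white-standard calibration is exercised, and a
``separation`` dial scales all between-class spec differences (0
collapses every class onto the mean spec, a null fixture in which labels
carry no visual information). Capture metadata follows a logistic model:
the probability that an individual is brown rather than green increases
with month (toward the breeding season) and decreases with snout-vent
length.

All randomness flows from one top-level seed through spawned substreams,
so every stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .imaging import (
    CalibratedImage,
    CropBox,
    RawImage,
    ReferenceRegion,
    ValidationError,
    calibrate_white,
    crop_body,
    to_luminance,
    LUMA_WEIGHTS,
)


@dataclass(frozen=True)
class PatternSpec:
    """Generative description of one pattern class.

    Colors are sRGB triples in [0, 1]; stripe width and blotch radii are
    fractions of the body's minor semi-axis; ``stripe_contrast`` blends
    the stripe color over the base (0 = invisible). Noise terms: hue
    jitter (per-image base-color sd), placement jitter (stripe/blotch
    position sd, body-fraction units) and pixel noise (per-pixel sd).
    """

    name: str
    base_color: tuple[float, float, float]
    n_stripes: int = 0
    stripe_orientation: float = 90.0  # degrees; 90 = vertical bars
    stripe_width: float = 0.10
    stripe_color: tuple[float, float, float] = (0.9, 0.85, 0.6)
    stripe_contrast: float = 0.0
    n_blotches: int = 0
    blotch_radius: tuple[float, float] = (0.12, 0.25)
    blotch_color: tuple[float, float, float] = (0.2, 0.15, 0.1)
    body_aspect: float = 1.7
    brightness: float = 1.0
    hue_jitter: float = 0.02
    placement_jitter: float = 0.03
    pixel_noise: float = 0.02

    def __post_init__(self) -> None:
        for c in (self.base_color, self.stripe_color, self.blotch_color):
            arr = np.asarray(c, dtype=float)
            if arr.shape != (3,) or arr.min() < 0 or arr.max() > 1:
                raise ValidationError(f"colors must be RGB triples in [0,1], got {c}")
        if min(self.hue_jitter, self.placement_jitter, self.pixel_noise) < 0:
            raise ValidationError("noise sds must be >= 0")
        if not 0 < self.stripe_width < 1:
            raise ValidationError("stripe width must be in (0, 1)")
        if not 0 < self.blotch_radius[0] <= self.blotch_radius[1]:
            raise ValidationError("blotch radius range must be positive and ordered")
        if self.blotch_radius[1] > 1:
            raise ValidationError(
                "blotch radius exceeds the body (fractions of the minor semi-axis)"
            )


def default_pattern_specs() -> dict[str, PatternSpec]:
    """A palette of six classes loosely spanning the study's taxonomy:
    plain brown (A), laterally striped brown (B), blotched brown (C),
    bright-striped brown (E), bright high-contrast green (F) and plain
    green (L). Names are labels, not claims about the real patterns."""
    return {
        "A": PatternSpec("A", base_color=(0.45, 0.32, 0.18)),
        "B": PatternSpec(
            "B", base_color=(0.42, 0.30, 0.18), n_stripes=1,
            stripe_orientation=0.0, stripe_width=0.22,
            stripe_color=(0.8, 0.75, 0.62), stripe_contrast=0.9,
        ),
        "C": PatternSpec(
            "C", base_color=(0.5, 0.36, 0.2), n_blotches=4,
            blotch_color=(0.26, 0.18, 0.1),
        ),
        "E": PatternSpec(
            "E", base_color=(0.5, 0.38, 0.2), n_stripes=3,
            stripe_width=0.12, stripe_color=(0.85, 0.72, 0.25),
            stripe_contrast=0.9, brightness=1.1,
        ),
        "F": PatternSpec(
            "F", base_color=(0.24, 0.55, 0.2), n_stripes=3,
            stripe_width=0.14, stripe_color=(0.88, 0.88, 0.45),
            stripe_contrast=1.0, brightness=1.15,
        ),
        "L": PatternSpec("L", base_color=(0.3, 0.55, 0.25)),
    }


_BLEND_SCALARS = (
    "n_stripes", "stripe_orientation", "stripe_width", "stripe_contrast",
    "n_blotches", "body_aspect", "brightness",
)
_BLEND_COLORS = ("base_color", "stripe_color", "blotch_color")


def blend_specs(specs: list[PatternSpec], separation: float) -> list[PatternSpec]:
    """Scale between-class differences: each numeric field becomes
    ``mean + separation * (value - mean)``.

    separation 0 collapses all classes onto the mean spec; 1 returns the
    specs unchanged; > 1 exaggerates the differences (clipped to valid
    ranges). Counts are rounded; noise terms are left untouched.
    """
    if separation < 0:
        raise ValidationError("separation must be >= 0")
    out = []
    means: dict[str, np.ndarray | float] = {}
    for name in _BLEND_COLORS:
        means[name] = np.mean([np.asarray(getattr(s, name)) for s in specs], axis=0)
    for name in _BLEND_SCALARS:
        means[name] = float(np.mean([getattr(s, name) for s in specs]))
    for s in specs:
        kw: dict = {}
        for name in _BLEND_COLORS:
            v = means[name] + separation * (np.asarray(getattr(s, name)) - means[name])
            kw[name] = tuple(np.clip(v, 0.0, 1.0))
        for name in _BLEND_SCALARS:
            v = means[name] + separation * (getattr(s, name) - means[name])
            kw[name] = v
        kw["n_stripes"] = max(0, round(kw["n_stripes"]))
        kw["n_blotches"] = max(0, round(kw["n_blotches"]))
        kw["stripe_width"] = float(np.clip(kw["stripe_width"], 0.02, 0.9))
        kw["stripe_contrast"] = float(np.clip(kw["stripe_contrast"], 0.0, 1.0))
        kw["body_aspect"] = float(np.clip(kw["body_aspect"], 1.0, 6.0))
        kw["brightness"] = float(max(0.1, kw["brightness"]))
        out.append(replace(s, **kw))
    return out


@dataclass
class RenderedImage:
    """A rendered frame plus the regions downstream stages need."""

    raw: RawImage
    reference: ReferenceRegion
    body_box: CropBox
    body_mask: np.ndarray


def generate_pattern_image(
    spec: PatternSpec,
    size: tuple[int, int] = (128, 128),
    seed: int | np.random.Generator = 0,
    illumination: float = 1.0,
    strip_fraction: float = 0.10,
    background: float = 0.55,
) -> RenderedImage:
    """Render one body image: an elongated elliptical body on a neutral
    ground with stripes/blotches, a white reference strip along the top
    edge, and a global illumination gain that white calibration undoes.
    Deterministic given the seed."""
    if not 0 < illumination <= 1:
        raise ValidationError("illumination gain must be in (0, 1]")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    h, w = size
    if h < 48 or w < 48:
        raise ValidationError("synthetic frames need at least 48x48 pixels")
    strip_h = max(4, int(round(strip_fraction * h)))
    frame = np.full((h, w, 3), float(background))
    frame[:strip_h] = 1.0

    base = np.clip(
        np.asarray(spec.base_color) + rng.normal(0.0, spec.hue_jitter, 3), 0.0, 1.0
    )
    body_h = h - strip_h
    cy, cx = strip_h + body_h / 2.0, w / 2.0
    semi_x = 0.46 * w
    semi_y = min(semi_x / spec.body_aspect, 0.45 * body_h)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    dx, dy = xx - cx, yy - cy
    mask = (dx / semi_x) ** 2 + (dy / semi_y) ** 2 <= 1.0
    frame[mask] = base

    if spec.n_stripes > 0 and spec.stripe_contrast > 0:
        theta = np.deg2rad(spec.stripe_orientation)
        # coordinate across the stripes, normalized by the body extent
        u = dx * np.cos(theta) + dy * np.sin(theta)
        extent = np.sqrt((semi_x * np.cos(theta)) ** 2 + (semi_y * np.sin(theta)) ** 2)
        u = u / extent
        centers = np.linspace(-0.7, 0.7, spec.n_stripes)
        centers = centers + rng.normal(0.0, spec.placement_jitter, spec.n_stripes)
        for c in centers:
            smask = mask & (np.abs(u - c) < spec.stripe_width / 2.0)
            frame[smask] = (1 - spec.stripe_contrast) * frame[smask] + (
                spec.stripe_contrast * np.asarray(spec.stripe_color)
            )

    for _ in range(spec.n_blotches):
        # uniform position inside the central part of the ellipse
        while True:
            p, q = rng.uniform(-0.8, 0.8, 2)
            if p * p + q * q <= 0.64:
                break
        bx, by = cx + p * semi_x, cy + q * semi_y
        radius = rng.uniform(*spec.blotch_radius) * semi_y
        bmask = mask & ((xx - bx) ** 2 + (yy - by) ** 2 <= radius**2)
        frame[bmask] = np.asarray(spec.blotch_color)

    frame[mask] = np.clip(frame[mask] * spec.brightness, 0.0, 1.0)
    if spec.pixel_noise > 0:
        frame = frame + rng.normal(0.0, spec.pixel_noise, frame.shape)
    frame = np.clip(frame * illumination, 0.0, 1.0)

    rows = np.where(mask.any(axis=1))[0]
    cols = np.where(mask.any(axis=0))[0]
    body_box = CropBox(int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
    reference = ReferenceRegion(0, 0, strip_h, w)
    return RenderedImage(
        raw=RawImage(pixels=frame, source_path=f"synthetic:{spec.name}"),
        reference=reference,
        body_box=body_box,
        body_mask=mask,
    )


@dataclass
class SyntheticDataset:
    images: list[CalibratedImage]
    labels: list[str]
    manifest: pd.DataFrame


def generate_class_dataset(
    specs: list[PatternSpec] | None = None,
    n_per_class: int = 10,
    size: tuple[int, int] = (128, 128),
    separation: float = 1.0,
    seed: int = 0,
    illumination_range: tuple[float, float] = (0.85, 1.0),
    calibrate: bool = True,
) -> SyntheticDataset:
    """Render ``n_per_class`` images per class at the requested class
    separation, calibrate each against its white strip and crop to the
    body box. Images are ordered class-by-class; the manifest records
    per-image seeds, gains and illumination."""
    if specs is None:
        specs = list(default_pattern_specs().values())
    if n_per_class < 2:
        raise ValidationError("n_per_class must be >= 2")
    specs = blend_specs(specs, separation)
    top = np.random.SeedSequence(seed)
    illum_rng = np.random.default_rng(top.spawn(1)[0])
    images: list[CalibratedImage] = []
    labels: list[str] = []
    rows = []
    for spec in specs:
        for child in top.spawn(n_per_class):
            rng = np.random.default_rng(child)
            lo, hi = illumination_range
            illum = float(illum_rng.uniform(lo, hi))
            rendered = generate_pattern_image(spec, size=size, seed=rng,
                                              illumination=illum)
            if calibrate:
                cal = calibrate_white(rendered.raw, rendered.reference)
                img = crop_body(cal, rendered.body_box)
            else:
                img = CalibratedImage(
                    pixels=rendered.raw.pixels[
                        rendered.body_box.row0 : rendered.body_box.row1,
                        rendered.body_box.col0 : rendered.body_box.col1,
                    ]
                )
            img.image_id = f"{spec.name}_{len(images)}"
            images.append(img)
            labels.append(spec.name)
            rows.append(
                {
                    "image_id": img.image_id,
                    "label": spec.name,
                    "illumination": illum,
                    "gain_r": img.gains[0],
                    "gain_g": img.gains[1],
                    "gain_b": img.gains[2],
                }
            )
    return SyntheticDataset(images=images, labels=labels,
                            manifest=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Constant-luminance hue rotation (pattern-vs-color fixture)
# ---------------------------------------------------------------------------


def hue_rotate_constant_luminance(pixels: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate every RGB vector about the gray axis, then restore the
    original BT.601 luminance by shifting along (1,1,1).

    The result has pixel-identical luminance but different chromaticity —
    the fixture that separates the pattern-only (grayscale) pathway from
    the color pathway. Raises if the rotated colors leave the RGB gamut
    (choose moderate input colors)."""
    pixels = np.asarray(pixels, dtype=float)
    axis = np.ones(3) / np.sqrt(3.0)
    a = np.deg2rad(degrees)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)
    rotated = pixels @ R.T
    lum = to_luminance(pixels)
    shift = lum - rotated @ LUMA_WEIGHTS
    out = rotated + shift[..., None]
    if out.min() < -1e-9 or out.max() > 1 + 1e-9:
        raise ValidationError(
            "hue rotation left the RGB gamut; use smaller angles or "
            "less saturated colors"
        )
    return np.clip(out, 0.0, 1.0)


def hue_rotated_pair_dataset(
    spec: PatternSpec | None = None,
    n_per_class: int = 10,
    size: tuple[int, int] = (128, 128),
    degrees: float = 55.0,
    seed: int = 0,
) -> tuple[SyntheticDataset, list[CalibratedImage]]:
    """Two classes that differ only in hue at matched luminance.

    2n independent renders of one spec are drawn; the first n keep their
    colors ('orig'), the last n are hue-rotated at constant luminance
    ('rotated'). Using disjoint renders for the two classes avoids the
    degenerate leave-one-out geometry of exact twins. Returns the
    dataset plus the *unrotated* copies of the rotated half (same
    order), whose luminance — hence grayscale signature — is pixel-
    identical to their rotated versions.
    """
    if spec is None:
        spec = PatternSpec(
            "hue", base_color=(0.5, 0.42, 0.28), n_stripes=2,
            stripe_width=0.14, stripe_color=(0.6, 0.52, 0.34),
            stripe_contrast=1.0, pixel_noise=0.01,
        )
    base = generate_class_dataset(
        [spec], n_per_class=2 * n_per_class, size=size, separation=1.0, seed=seed
    )
    images: list[CalibratedImage] = []
    labels: list[str] = []
    twins: list[CalibratedImage] = []
    for i, img in enumerate(base.images):
        if i < n_per_class:
            img.image_id = f"orig_{i}"
            images.append(img)
            labels.append("orig")
        else:
            rot = CalibratedImage(
                pixels=hue_rotate_constant_luminance(img.pixels, degrees),
                gains=img.gains,
                reference_white=img.reference_white,
                image_id=f"rotated_{i}",
            )
            images.append(rot)
            labels.append("rotated")
            twins.append(img)
    manifest = pd.DataFrame({"image_id": [i.image_id for i in images],
                             "label": labels})
    return SyntheticDataset(images=images, labels=labels, manifest=manifest), twins


# ---------------------------------------------------------------------------
# Capture metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticMetadataSpec:
    """Generating model of a capture table: months uniform over a range,
    SVL truncated-normal (cm), and P(brown) logistic in month and SVL.

    Defaults are the study conditions of the recovery simulations: n=148
    males, months 5-10, SVL ~ TN(10, 2; 5, 16) cm, month coefficient
    0.416 and SVL coefficient -0.289 on the logit scale, intercept -0.23
    (approximately half brown overall)."""

    n: int = 148
    month_range: tuple[int, int] = (5, 10)
    svl_mean: float = 10.0
    svl_sd: float = 2.0
    svl_min: float = 5.0
    svl_max: float = 16.0
    intercept: float = -0.23
    beta_month: float = 0.416
    beta_svl: float = -0.289
    sex: str = "male"

    def __post_init__(self) -> None:
        if self.n < 10:
            raise ValidationError("n must be >= 10")
        if self.svl_sd <= 0:
            raise ValidationError("SVL sd must be positive")
        if not self.svl_min < self.svl_max:
            raise ValidationError("degenerate SVL interval")
        if self.month_range[0] > self.month_range[1]:
            raise ValidationError("empty month range")


def generate_metadata(
    spec: SyntheticMetadataSpec | None = None, seed: int = 0, **overrides
) -> pd.DataFrame:
    """Simulate a capture table (id, sex, month, svl, color).

    color is 'brown' with probability
    ``logistic(intercept + beta_month * month + beta_svl * svl)`` and
    'green' otherwise; deterministic given the seed."""
    if spec is None:
        spec = SyntheticMetadataSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    months = rng.integers(spec.month_range[0], spec.month_range[1] + 1, size=spec.n)
    a = (spec.svl_min - spec.svl_mean) / spec.svl_sd
    b = (spec.svl_max - spec.svl_mean) / spec.svl_sd
    svl = stats.truncnorm.rvs(
        a, b, loc=spec.svl_mean, scale=spec.svl_sd, size=spec.n, random_state=rng
    )
    logit = spec.intercept + spec.beta_month * months + spec.beta_svl * svl
    p_brown = 1.0 / (1.0 + np.exp(-logit))
    brown = rng.random(spec.n) < p_brown
    return pd.DataFrame(
        {
            "id": [f"{spec.sex[0]}{i:04d}" for i in range(spec.n)],
            "sex": spec.sex,
            "month": months.astype(int),
            "svl": svl,
            "color": np.where(brown, "brown", "green"),
        }
    )
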