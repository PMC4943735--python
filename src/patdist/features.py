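"""Bio-inspired visual signatures: Gabor C1 maps, single-opponent color
channels, and template-based C2 max-similarity pooling.

The descriptor follows the HMAX family of hierarchical visual models. An
image is first expanded into channel maps — the luminance alone for the
grayscale (pattern-only) pathway, or eight half-wave-rectified
single-opponent center–surround channels for the color pathway. Each map
is filtered with a bank of Gabor "bar detectors" at many scales and four
orientations; responses are max-pooled over adjacent scale pairs and
local spatial neighborhoods (C1, a complex-cell-like shift-tolerant edge
representation). An image's signature is then a fixed-length vector: per
stored template (a C1-space patch sampled from a corpus), the maximal
Gaussian similarity between the template and any location/band of the
image (C2). Signatures are the unit of all downstream classification.

The grayscale pathway is a pure pattern channel — invariant to chroma
changes at constant luminance — while the color pathway is not; comparing
the two isolates what color itself contributes to distinguishability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .imaging import CalibratedImage, ValidationError, resize_max_side, to_luminance

# ---------------------------------------------------------------------------
# Gabor bank configuration (HMAX defaults)
# ---------------------------------------------------------------------------

_HMAX_FILTER_SIZES = tuple(range(7, 39, 2))  # 7..37, 16 scales
_HMAX_SIGMAS = (2.8, 3.6, 4.5, 5.4, 6.3, 7.3, 8.2, 9.2,
                10.2, 11.3, 12.3, 13.4, 14.6, 15.8, 17.0, 18.2)
_HMAX_LAMBDAS = (3.5, 4.6, 5.6, 6.8, 7.9, 9.1, 10.3, 11.5,
                 12.7, 14.1, 15.4, 16.8, 18.2, 19.7, 21.2, 22.8)
_HMAX_POOL_SIZES = (8, 10, 12, 14, 16, 18, 20, 22)  # C1 spatial pool per band


@dataclass(frozen=True)
class GaborBankConfig:
    """Gabor filter bank plus C1 pooling geometry.

    Defaults are the published HMAX parameters: 16 scales with odd filter
    sizes 7..37, four orientations (0/45/90/135 deg), aspect ratio 0.3,
    and per-band spatial pooling neighborhoods of 8..22 C1 cells with
    half-overlap subsampling. Scales are pooled in adjacent pairs, so the
    number of bands is ``n_scales // 2``.
    """

    n_scales: int = 16
    n_orientations: int = 4
    filter_sizes: tuple[int, ...] = _HMAX_FILTER_SIZES
    sigmas: tuple[float, ...] = _HMAX_SIGMAS
    wavelengths: tuple[float, ...] = _HMAX_LAMBDAS
    pool_sizes: tuple[int, ...] = _HMAX_POOL_SIZES
    aspect_ratio: float = 0.3

    def __post_init__(self) -> None:
        if self.n_scales < 2 or self.n_scales % 2:
            raise ValidationError("n_scales must be even and >= 2")
        for name in ("filter_sizes", "sigmas", "wavelengths"):
            if len(getattr(self, name)) < self.n_scales:
                raise ValidationError(f"{name} must list >= n_scales entries")
        sizes = self.filter_sizes[: self.n_scales]
        if any(s % 2 == 0 for s in sizes):
            raise ValidationError("filter sizes must be odd")
        if any(b >= a for b, a in zip(sizes, sizes[1:])):
            raise ValidationError("filter sizes must be strictly increasing")
        if len(self.pool_sizes) < self.n_scales // 2:
            raise ValidationError("pool_sizes must list >= n_scales/2 entries")

    @property
    def n_bands(self) -> int:
        return self.n_scales // 2

    @property
    def orientations(self) -> np.ndarray:
        """Orientations in radians, evenly spaced over [0, pi)."""
        return np.arange(self.n_orientations) * np.pi / self.n_orientations

    def truncated(self, n_scales: int) -> "GaborBankConfig":
        """A bank restricted to the first ``n_scales`` scales (smaller filters)."""
        return GaborBankConfig(
            n_scales=n_scales,
            n_orientations=self.n_orientations,
            filter_sizes=self.filter_sizes[:n_scales],
            sigmas=self.sigmas[:n_scales],
            wavelengths=self.wavelengths[:n_scales],
            pool_sizes=self.pool_sizes[: n_scales // 2],
            aspect_ratio=self.aspect_ratio,
        )


def gabor_filter(size: int, sigma: float, wavelength: float, theta: float,
                 aspect_ratio: float = 0.3) -> np.ndarray:
    """A single zero-mean, unit-norm Gabor patch on circular support.

    ``theta`` is the orientation of the *bar* the filter detects
    (0 = horizontal): the sinusoidal carrier runs perpendicular to the
    bar and the envelope is elongated along it.
    """
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    u = -x * np.sin(theta) + y * np.cos(theta)  # across the bar (carrier)
    v = x * np.cos(theta) + y * np.sin(theta)  # along the bar
    g = np.exp(-(u**2 + (aspect_ratio * v) ** 2) / (2 * sigma**2)) * np.cos(
        2 * np.pi * u / wavelength
    )
    g[x**2 + y**2 > half**2] = 0.0
    g -= g.mean()
    norm = np.sqrt((g**2).sum())
    if norm > 0:
        g /= norm
    return g


def gabor_bank(config: GaborBankConfig) -> list[list[np.ndarray]]:
    """All filters, indexed [scale][orientation]."""
    return [
        [
            gabor_filter(
                config.filter_sizes[s],
                config.sigmas[s],
                config.wavelengths[s],
                theta,
                config.aspect_ratio,
            )
            for theta in config.orientations
        ]
        for s in range(config.n_scales)
    ]


@lru_cache(maxsize=8)
def _bank_ffts(config: GaborBankConfig, ph: int, pw: int):
    """Per-scale stacked rFFTs of the (flipped) bank filters at padded size.

    Correlation is implemented as convolution with the flipped kernel;
    caching amortizes the kernel transforms over a whole image corpus.
    """
    bank = gabor_bank(config)
    return [
        np.stack([np.fft.rfft2(f[::-1, ::-1], s=(ph, pw)) for f in row])
        for row in bank
    ]


def _fft_correlate_scale(img_fft: np.ndarray, scale_fft: np.ndarray,
                         k: int, h: int, w: int, ph: int, pw: int) -> np.ndarray:
    """'same'-mode zero-padded correlation responses for all orientations
    of one scale. Returns (n_orientations, h, w)."""
    full = np.fft.irfft2(img_fft[None] * scale_fft, s=(ph, pw))
    r0 = (k - 1) // 2
    return full[:, r0 : r0 + h, r0 : r0 + w]


# ---------------------------------------------------------------------------
# Single-opponent channels
# ---------------------------------------------------------------------------

OPPONENT_PAIR_NAMES = (
    ("red_green", "green_red"),
    ("yellow_blue", "blue_yellow"),
    ("red_cyan", "cyan_red"),
    ("white_black", "black_white"),
)

#: Channel order of the color pathway.
OPPONENT_CHANNEL_NAMES = tuple(n for pair in OPPONENT_PAIR_NAMES for n in pair)


@dataclass
class OpponentChannels:
    """Eight rectified single-opponent center–surround maps.

    Each opponent pair (e.g. red-center/green-surround and its reverse) is
    the positive and negative half of one signed difference-of-Gaussians
    response, so the two maps of a pair are complementary: their pixelwise
    product is zero. Rectification keeps "firing rates" non-negative.
    """

    maps: dict[str, np.ndarray]
    center_sigma: float
    surround_sigma: float

    def stacked(self) -> np.ndarray:
        """(8, H, W) array in canonical channel order."""
        return np.stack([self.maps[name] for name in OPPONENT_CHANNEL_NAMES])


def compute_opponent_channels(
    img: CalibratedImage | np.ndarray,
    center_sigma: float = 1.0,
    surround_sigma: float = 3.0,
) -> OpponentChannels:
    """Compute the 8 rectified single-opponent channels of an RGB image.

    Pairs: red/green, yellow/blue (yellow = (R+G)/2), red/cyan
    (cyan = (G+B)/2) and white/black (both sides the luminance). The
    signed response is center-Gaussian of the first color minus
    surround-Gaussian of the second; the two channels of a pair are its
    positive and negative parts.
    """
    if not surround_sigma > center_sigma > 0:
        raise ValidationError("need surround_sigma > center_sigma > 0")
    pixels = img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)
    r, g, b = pixels[..., 0], pixels[..., 1], pixels[..., 2]
    lum = to_luminance(pixels)
    pairs = {
        ("red_green", "green_red"): (r, g),
        ("yellow_blue", "blue_yellow"): ((r + g) / 2, b),
        ("red_cyan", "cyan_red"): (r, (g + b) / 2),
        ("white_black", "black_white"): (lum, lum),
    }
    maps: dict[str, np.ndarray] = {}
    for (pos_name, neg_name), (center, surround) in pairs.items():
        signed = ndimage.gaussian_filter(center, center_sigma) - ndimage.gaussian_filter(
            surround, surround_sigma
        )
        maps[pos_name] = np.maximum(signed, 0.0)
        maps[neg_name] = np.maximum(-signed, 0.0)
    return OpponentChannels(maps=maps, center_sigma=center_sigma,
                            surround_sigma=surround_sigma)


# ---------------------------------------------------------------------------
# C1
# ---------------------------------------------------------------------------


@dataclass
class C1Stack:
    """Scale-band/orientation grid of pooled Gabor responses.

    ``bands[b]`` has shape (n_channels, n_orientations, h_b, w_b); grids
    shrink with band because the pooling neighborhood and subsampling step
    grow with scale.
    """

    bands: list[np.ndarray]
    channel_names: tuple[str, ...]
    config: GaborBankConfig
    image_id: str = ""

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)


def compute_c1(
    channel_maps: list[np.ndarray] | np.ndarray,
    config: GaborBankConfig | None = None,
    channel_names: tuple[str, ...] | None = None,
    image_id: str = "",
) -> C1Stack:
    """Gabor-filter every channel map and apply HMAX C1 pooling.

    Each map is correlated with every filter of the bank; the absolute
    response is taken (a bar detector fires on both contrast polarities).
    Adjacent scale pairs are max-pooled together, then max-pooled over
    local spatial neighborhoods on a grid subsampled at half the
    neighborhood size.
    """
    if config is None:
        config = GaborBankConfig()
    maps = [np.asarray(m, dtype=float) for m in channel_maps]
    if not maps:
        raise ValidationError("channel_maps is empty")
    h, w = maps[0].shape
    largest = config.filter_sizes[config.n_scales - 1]
    if min(h, w) < largest:
        raise ValidationError(
            f"image {h}x{w} smaller than the largest Gabor filter ({largest}); "
            "resize the image up or truncate the filter bank"
        )
    for m in maps:
        if m.shape != (h, w) or not np.isfinite(m).all():
            raise ValidationError("channel maps must share a shape and be finite")
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(len(maps)))

    ph, pw = h + largest - 1, w + largest - 1
    ffts = _bank_ffts(config, ph, pw)
    img_ffts = [np.fft.rfft2(m, s=(ph, pw)) for m in maps]

    bands: list[np.ndarray] = [None] * config.n_bands
    for b in range(config.n_bands):
        pool = config.pool_sizes[b]
        step = max(1, pool // 2)
        band_maps = None
        for m_idx, img_fft in enumerate(img_ffts):
            s_lo, s_hi = 2 * b, 2 * b + 1
            scale_max = np.maximum(
                np.abs(_fft_correlate_scale(img_fft, ffts[s_lo],
                                            config.filter_sizes[s_lo], h, w, ph, pw)),
                np.abs(_fft_correlate_scale(img_fft, ffts[s_hi],
                                            config.filter_sizes[s_hi], h, w, ph, pw)),
            )  # (O, H, W)
            pooled = ndimage.maximum_filter(
                scale_max, size=(1, pool, pool), mode="constant", cval=0.0
            )[:, step // 2 :: step, step // 2 :: step]
            if band_maps is None:
                band_maps = np.empty((len(maps),) + pooled.shape)
            band_maps[m_idx] = pooled
        bands[b] = band_maps
    return C1Stack(bands=bands, channel_names=tuple(channel_names),
                   config=config, image_id=image_id)


# ---------------------------------------------------------------------------
# Templates and signatures
# ---------------------------------------------------------------------------


@dataclass
class Template:
    size_class: int
    patch: np.ndarray  # (n_channels, n_orientations, s, s)
    source: tuple[int, int, int, int]  # image index, band, row, col

    def __post_init__(self) -> None:
        if not np.isfinite(self.patch).all():
            raise ValidationError("template patch has non-finite values")
        if self.patch.shape[-1] != self.size_class or self.patch.shape[-2] != self.size_class:
            raise ValidationError("patch extent does not match size class")


@dataclass
class TemplateSet:
    """Ordered dictionary of C1-space patches; coordinate i of every
    signature refers to template i."""

    templates: list[Template]
    mode: str  # "color" | "grayscale"
    seed: int
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.templates)


DEFAULT_SIZE_CLASSES = (4, 8, 12, 16)


def sample_templates(
    corpus: list[C1Stack],
    n_templates: int = 1000,
    size_classes: tuple[int, ...] = DEFAULT_SIZE_CLASSES,
    seed: int = 0,
    mode: str = "color",
) -> TemplateSet:
    """Sample template patches uniformly over (image, band, location).

    The template count is split equally among the size classes (the
    default 1000 templates over 4 sizes gives 250 each); sampling is
    uniform over all C1 locations at which a patch of that size fits, and
    deterministic given seed and corpus order.
    """
    if not corpus:
        raise ValidationError("empty corpus")
    if n_templates % len(size_classes):
        raise ValidationError(
            f"n_templates={n_templates} not divisible by {len(size_classes)} size classes"
        )
    rng = np.random.default_rng(seed)
    per_class = n_templates // len(size_classes)
    templates: list[Template] = []
    for s in size_classes:
        # every (image, band) slot where an s x s patch fits, with its location count
        slots: list[tuple[int, int, int, int]] = []
        for i, stack in enumerate(corpus):
            for b, band in enumerate(stack.bands):
                nr, nc = band.shape[-2] - s + 1, band.shape[-1] - s + 1
                if nr > 0 and nc > 0:
                    slots.append((i, b, nr, nc))
        if not slots:
            raise ValidationError(
                f"size class {s} exceeds every available C1 map in the corpus"
            )
        counts = np.array([nr * nc for _, _, nr, nc in slots])
        cum = np.cumsum(counts)
        draws = rng.integers(0, cum[-1], size=per_class)
        for d in draws:
            k = int(np.searchsorted(cum, d, side="right"))
            i, b, nr, nc = slots[k]
            local = int(d - (cum[k] - counts[k]))
            r, c = divmod(local, nc)
            patch = corpus[i].bands[b][:, :, r : r + s, c : c + s].copy()
            templates.append(Template(size_class=s, patch=patch, source=(i, b, r, c)))
    channel_names = corpus[0].channel_names
    return TemplateSet(templates=templates, mode=mode, seed=seed,
                       channel_names=channel_names)


@dataclass
class VisualSignature:
    values: np.ndarray
    mode: str
    image_id: str = ""


def _template_matrix(templates: list[Template]) -> np.ndarray:
    return np.stack([t.patch.ravel() for t in templates])


def compute_signature(
    stack: C1Stack,
    templates: TemplateSet,
    sigma_sq: float | None = None,
) -> VisualSignature:
    """Max-similarity (C2) pooling of one C1 stack against a template set.

    For template t, the signature coordinate is
    ``max over bands and locations of exp(-||patch - t||^2 / (2 sigma^2))``
    with ``sigma^2`` equal to the patch dimensionality unless overridden.
    The distance search uses the inner-product expansion for speed, then
    re-evaluates the winning location by direct subtraction, so the
    returned value equals an exhaustive direct scan.
    """
    if stack.channel_names != templates.channel_names:
        raise ValidationError(
            f"channel mode mismatch: stack has {stack.channel_names}, "
            f"templates were sampled from {templates.channel_names}"
        )
    n_t = len(templates)
    values = np.zeros(n_t)
    best = [None] * n_t  # (band, row, col) of current best per template
    by_size: dict[int, list[int]] = {}
    for idx, t in enumerate(templates.templates):
        by_size.setdefault(t.size_class, []).append(idx)

    best_d2 = np.full(n_t, np.inf)
    for s, idxs in sorted(by_size.items()):
        t_mat = _template_matrix([templates.templates[i] for i in idxs])  # (K, D)
        t_norms = (t_mat**2).sum(axis=1)
        for b, band in enumerate(stack.bands):
            nr, nc = band.shape[-2] - s + 1, band.shape[-1] - s + 1
            if nr <= 0 or nc <= 0:
                continue
            win = sliding_window_view(band, (s, s), axis=(-2, -1))
            # (C, O, nr, nc, s, s) -> (nr*nc, C*O*s*s) matching patch.ravel order
            win = win.transpose(2, 3, 0, 1, 4, 5).reshape(nr * nc, -1)
            w_norms = (win**2).sum(axis=1)
            d2 = w_norms[:, None] - 2.0 * (win @ t_mat.T) + t_norms[None, :]
            loc = np.argmin(d2, axis=0)
            d2_min = d2[loc, np.arange(len(idxs))]
            for k, t_idx in enumerate(idxs):
                if d2_min[k] < best_d2[t_idx]:
                    best_d2[t_idx] = d2_min[k]
                    r, c = divmod(int(loc[k]), nc)
                    best[t_idx] = (b, r, c)
        # exact re-evaluation at the winning location, direct subtraction
        for k, t_idx in enumerate(idxs):
            if best[t_idx] is None:
                raise ValidationError(
                    f"template of size {s} fits no band of the image's C1 stack"
                )
            b, r, c = best[t_idx]
            w = stack.bands[b][:, :, r : r + s, c : c + s].ravel()
            d2_exact = ((w - t_mat[k]) ** 2).sum()
            ssq = sigma_sq if sigma_sq is not None else float(t_mat.shape[1])
            values[t_idx] = np.exp(-d2_exact / (2.0 * ssq))
    return VisualSignature(values=values, mode=templates.mode,
                           image_id=stack.image_id)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class SignatureExtractor(TransformerMixin, BaseEstimator):
    """Transform calibrated images into visual-signature vectors.

    ``fit`` builds the template dictionary by sampling random C1-space
    locations from the corpus (the study's procedure: templates are a
    preliminary step drawn from all images, which mildly couples train
    and test; pass the training images only to ``fit`` for a strict
    leakage-free protocol). ``transform`` computes one signature row per
    image.

    Parameters
    ----------
    mode : "color" | "grayscale"
        Color pathway (8 single-opponent channels) or pattern-only
        pathway (luminance).
    n_templates : int
        Dictionary size, split equally over ``size_classes``.
    size_classes : tuple of int
        Spatial extents of templates, in C1 cells.
    n_scales : int
        Gabor scales (even); pooled into ``n_scales/2`` bands.
    center_sigma, surround_sigma : float
        Center/surround Gaussian widths of the opponent channels, in
        pixels of the (resized) image.
    sigma_sq : float or None
        Similarity width; None means the patch dimensionality.
    max_side : int
        Images are downsampled so their longer side is at most this.
    random_state : int
        Seed of template sampling.
    """

    def __init__(
        self,
        mode: str = "color",
        n_templates: int = 200,
        size_classes: tuple[int, ...] = DEFAULT_SIZE_CLASSES,
        n_scales: int = 16,
        n_orientations: int = 4,
        center_sigma: float = 1.0,
        surround_sigma: float = 3.0,
        sigma_sq: float | None = None,
        max_side: int = 256,
        random_state: int = 0,
    ):
        self.mode = mode
        self.n_templates = n_templates
        self.size_classes = size_classes
        self.n_scales = n_scales
        self.n_orientations = n_orientations
        self.center_sigma = center_sigma
        self.surround_sigma = surround_sigma
        self.sigma_sq = sigma_sq
        self.max_side = max_side
        self.random_state = random_state

    def _bank(self) -> GaborBankConfig:
        base = GaborBankConfig()
        cfg = base.truncated(self.n_scales) if self.n_scales < 16 else base
        if self.n_orientations != cfg.n_orientations:
            cfg = GaborBankConfig(
                n_scales=cfg.n_scales,
                n_orientations=self.n_orientations,
                filter_sizes=cfg.filter_sizes,
                sigmas=cfg.sigmas,
                wavelengths=cfg.wavelengths,
                pool_sizes=cfg.pool_sizes,
                aspect_ratio=cfg.aspect_ratio,
            )
        return cfg

    def _channel_maps(self, img) -> tuple[list[np.ndarray], tuple[str, ...]]:
        pixels = img.pixels if hasattr(img, "pixels") else np.asarray(img, dtype=float)
        pixels = resize_max_side(pixels, self.max_side)
        if self.mode == "grayscale":
            return [to_luminance(pixels)], ("luminance",)
        if self.mode == "color":
            opp = compute_opponent_channels(pixels, self.center_sigma,
                                            self.surround_sigma)
            return list(opp.stacked()), OPPONENT_CHANNEL_NAMES
        raise ValidationError(f"unknown mode {self.mode!r} (use 'color' or 'grayscale')")

    def _stack(self, img, image_id: str = "") -> C1Stack:
        maps, names = self._channel_maps(img)
        if not image_id:
            image_id = getattr(img, "image_id", "") or ""
        return compute_c1(maps, self._bank(), channel_names=names, image_id=image_id)

    def fit(self, X, y=None):
        if len(X) < 1:
            raise ValidationError("need at least one image to sample templates")
        stacks = [self._stack(img, image_id=str(i)) for i, img in enumerate(X)]
        self.templates_ = sample_templates(
            stacks,
            n_templates=self.n_templates,
            size_classes=self.size_classes,
            seed=self.random_state,
            mode=self.mode,
        )
        self.n_features_ = self.n_templates
        self._fit_stacks = stacks
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "templates_")
        return np.stack(
            [
                compute_signature(self._stack(img), self.templates_,
                                  sigma_sq=self.sigma_sq).values
                for img in X
            ]
        )

    def fit_transform(self, X, y=None) -> np.ndarray:
        # reuse the C1 stacks computed during fit
        self.fit(X)
        out = np.stack(
            [
                compute_signature(stack, self.templates_, sigma_sq=self.sigma_sq).values
                for stack in self._fit_stacks
            ]
        )
        return out


def build_signature_matrix(
    images: list[CalibratedImage],
    mode: str = "color",
    n_templates: int = 200,
    seed: int = 0,
    **extractor_kwargs,
) -> tuple[np.ndarray, TemplateSet]:
    """One-call driver: sample templates from all images and return the
    n x T signature matrix (rows in input order) plus the template set."""
    if len(images) < 2:
        raise ValidationError("need at least 2 images")
    ex = SignatureExtractor(mode=mode, n_templates=n_templates,
                            random_state=seed, **extractor_kwargs)
    matrix = ex.fit_transform(images)
    return matrix, ex.templates_
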