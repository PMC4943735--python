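"""Gabor C1, opponent channels, template sampling and C2 signatures."""

import numpy as np
import pytest

from patdist.features import (
    GaborBankConfig,
    SignatureExtractor,
    compute_c1,
    compute_opponent_channels,
    compute_signature,
    gabor_filter,
    sample_templates,
)
from patdist.imaging import CalibratedImage, ValidationError

from conftest import SMALL_EXTRACTOR, random_c1_stack

BANK8 = GaborBankConfig().truncated(8)


def c2_exhaustive_scan(stack, template, sigma_sq=None):
    """Independent oracle: direct distance at every band and location."""
    s = template.size_class
    d2_best = np.inf
    for band in stack.bands:
        nr, nc = band.shape[-2] - s + 1, band.shape[-1] - s + 1
        for r in range(max(nr, 0)):
            for c in range(max(nc, 0)):
                w = band[:, :, r : r + s, c : c + s].ravel()
                d2 = ((w - template.patch.ravel()) ** 2).sum()
                d2_best = min(d2_best, d2)
    ssq = sigma_sq if sigma_sq is not None else template.patch.size
    return np.exp(-d2_best / (2.0 * ssq))


class TestOpponentChannels:
    def test_uniform_image_gives_flat_tonic_response(self):
        # on a uniform field both Gaussians pass their input unchanged,
        # so each signed response is the constant P - Q: spatially flat,
        # with only one channel of each pair active (white/black: zero)
        img = np.full((48, 48, 3), [0.3, 0.6, 0.2])
        opp = compute_opponent_channels(img)
        for name, m in opp.maps.items():
            assert np.ptp(m) < 1e-10, name
        assert opp.maps["green_red"][24, 24] == pytest.approx(0.3, abs=1e-10)
        assert opp.maps["red_green"].max() < 1e-10
        assert opp.maps["white_black"].max() < 1e-10
        assert opp.maps["black_white"].max() < 1e-10

    def test_red_disk_on_green_ground(self):
        yy, xx = np.mgrid[0:48, 0:48]
        disk = (yy - 24) ** 2 + (xx - 24) ** 2 <= 100
        img = np.zeros((48, 48, 3))
        img[..., 1] = 0.6
        img[disk] = [0.8, 0.0, 0.0]
        opp = compute_opponent_channels(img)
        assert opp.maps["red_green"][24, 24] > 0
        # green-red fires on the green side of the rim
        rim = opp.maps["green_red"][24, 24 + 13]
        assert rim > 0

    def test_pair_channels_are_complementary(self, rng):
        img = rng.random((48, 48, 3))
        opp = compute_opponent_channels(img)
        for pos, neg in [("red_green", "green_red"), ("yellow_blue", "blue_yellow"),
                         ("red_cyan", "cyan_red"), ("white_black", "black_white")]:
            assert np.abs(opp.maps[pos] * opp.maps[neg]).max() < 1e-12
            assert opp.maps[pos].min() >= 0 and opp.maps[neg].min() >= 0

    def test_sigma_ordering_enforced(self, rng):
        with pytest.raises(ValidationError):
            compute_opponent_channels(rng.random((48, 48, 3)),
                                      center_sigma=3.0, surround_sigma=1.0)


class TestC1:
    def test_zero_input_zero_output(self):
        stack = compute_c1([np.zeros((48, 48))], BANK8)
        for band in stack.bands:
            assert np.abs(band).max() == 0.0

    def test_bar_orientation_selectivity(self):
        img = np.zeros((64, 64))
        img[30:33, 8:56] = 1.0  # horizontal bar
        stack = compute_c1([img], BANK8)
        band = stack.bands[0][0]  # (orientations, h, w)
        r, c = band.shape[1] // 2, band.shape[2] // 2
        assert band[0, r, c] > band[2, r, c]  # 0 deg beats 90 deg

    def test_linearity_under_contrast_scaling(self, rng):
        img = 0.4 * rng.random((48, 48))
        s1 = compute_c1([img], BANK8)
        s2 = compute_c1([2 * img], BANK8)
        for b1, b2 in zip(s1.bands, s2.bands):
            assert np.allclose(b2, 2 * b1, atol=1e-12)

    def test_geometry_and_rectification(self, rng):
        maps = [rng.random((48, 48)) for _ in range(2)]
        stack = compute_c1(maps, BANK8)
        assert stack.n_bands == BANK8.n_scales // 2
        for band in stack.bands:
            assert band.min() >= 0
            assert band.shape[0] == 2 and band.shape[1] == BANK8.n_orientations
            assert band.shape[-2] < 48 and band.shape[-1] < 48

    def test_image_smaller_than_largest_filter_rejected(self):
        with pytest.raises(ValidationError, match="resize"):
            compute_c1([np.zeros((16, 16))], BANK8)

    def test_gabor_filters_zero_mean_unit_norm(self):
        for s in (7, 21, 37):
            g = gabor_filter(s, 2.8, 3.5, np.pi / 4)
            assert abs(g.mean()) < 1e-12
            assert np.sqrt((g**2).sum()) == pytest.approx(1.0)


class TestTemplates:
    def test_equal_split_across_size_classes(self, rng):
        corpus = [random_c1_stack(rng, shapes=((10, 10), (8, 8))) for _ in range(3)]
        ts = sample_templates(corpus, n_templates=20, size_classes=(2, 3, 4, 5), seed=1)
        sizes = [t.size_class for t in ts.templates]
        assert all(sizes.count(s) == 5 for s in (2, 3, 4, 5))

    def test_deterministic_given_seed_and_corpus(self, rng):
        corpus = [random_c1_stack(rng) for _ in range(2)]
        t1 = sample_templates(corpus, 8, (2, 3), seed=7)
        t2 = sample_templates(corpus, 8, (2, 3), seed=7)
        for a, b in zip(t1.templates, t2.templates):
            assert a.source == b.source
            assert np.array_equal(a.patch, b.patch)

    def test_one_template_per_size_class(self, rng):
        corpus = [random_c1_stack(rng)]
        ts = sample_templates(corpus, 4, (2, 3, 4, 5), seed=0)
        assert sorted(t.size_class for t in ts.templates) == [2, 3, 4, 5]

    def test_oversized_class_rejected(self, rng):
        corpus = [random_c1_stack(rng, shapes=((6, 6), (4, 4)))]
        with pytest.raises(ValidationError):
            sample_templates(corpus, 2, (7, 9), seed=0)


class TestSignature:
    def test_self_match_is_one(self, rng):
        corpus = [random_c1_stack(rng), random_c1_stack(rng)]
        ts = sample_templates(corpus, 8, (2, 3), seed=3)
        for i, stack in enumerate(corpus):
            sig = compute_signature(stack, ts)
            own = [j for j, t in enumerate(ts.templates) if t.source[0] == i]
            assert own, "each stack should contribute templates at this seed"
            assert np.allclose(sig.values[own], 1.0)
            assert sig.values.min() > 0 and sig.values.max() <= 1.0

    def test_zero_stack_closed_form(self, rng):
        corpus = [random_c1_stack(rng)]
        ts = sample_templates(corpus, 4, (2, 3), seed=5)
        zero = random_c1_stack(np.random.default_rng(0))
        for band in zero.bands:
            band[:] = 0.0
        sig = compute_signature(zero, ts)
        for v, t in zip(sig.values, ts.templates):
            expected = np.exp(-(t.patch**2).sum() / (2.0 * t.patch.size))
            assert v == pytest.approx(expected, rel=1e-12)

    def test_matches_exhaustive_scan_exactly(self, rng):
        corpus = [random_c1_stack(rng, shapes=((8, 8), (6, 6))) for _ in range(2)]
        ts = sample_templates(corpus, 8, (2, 4), seed=9)
        probe = random_c1_stack(np.random.default_rng(77), shapes=((8, 8), (6, 6)))
        sig = compute_signature(probe, ts)
        for v, t in zip(sig.values, ts.templates):
            assert v == c2_exhaustive_scan(probe, t)

    def test_mode_mismatch_rejected(self, rng):
        corpus = [random_c1_stack(rng, n_channels=2)]
        ts = sample_templates(corpus, 4, (2, 3), seed=0)
        other = random_c1_stack(rng, n_channels=3)
        with pytest.raises(ValidationError, match="mismatch"):
            compute_signature(other, ts)


class TestExtractor:
    def _images(self, rng, n=3, size=56):
        return [CalibratedImage(pixels=rng.random((size, size, 3))) for _ in range(n)]

    def test_matrix_shape_and_determinism(self, rng):
        images = self._images(rng)
        ex = SignatureExtractor(mode="color", n_templates=16, random_state=4,
                                **SMALL_EXTRACTOR)
        m1 = ex.fit_transform(images)
        assert m1.shape == (3, 16)
        m2 = SignatureExtractor(mode="color", n_templates=16, random_state=4,
                                **SMALL_EXTRACTOR).fit(images).transform(images)
        assert np.array_equal(m1, m2)

    def test_grayscale_uses_single_luminance_channel(self, rng):
        images = self._images(rng)
        ex = SignatureExtractor(mode="grayscale", n_templates=8, random_state=1,
                                **SMALL_EXTRACTOR)
        ex.fit(images)
        assert ex.templates_.channel_names == ("luminance",)

    def test_sklearn_param_interface(self):
        from sklearn.base import clone

        ex = SignatureExtractor(mode="grayscale", n_templates=12)
        assert clone(ex).get_params()["n_templates"] == 12
        ex.set_params(n_templates=8)
        assert ex.n_templates == 8
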