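"""Per-row confidence algorithms against brute-force oracles and their
symmetry/readout contracts."""

import numpy as np
import pytest
from scipy import stats
from scipy.ndimage import convolve, gaussian_filter

from skyline.estimators import (
    ConfidenceProfile,
    DivParams,
    DummyParams,
    GaborParams,
    VanParams,
    dummy_estimate,
    gabor_kernel_zero_mean,
    profile_div,
    profile_gab,
    profile_lin,
    profile_van,
    rasterize_lines,
    van_lines,
    winner_takes_all,
)


def two_tone(H=100, W=60, boundary=50, top=200.0, bottom=20.0):
    img = np.full((H, W), bottom)
    img[:boundary] = top
    return img


# ---------------------------------------------------------------------------
# Brute-force oracles (independent double-loop implementations)


def oracle_div(channel, params, polarity):
    H, W = channel.shape
    g = np.zeros(H)
    for r in range(1, H):
        above = np.mean([channel[i, j] for i in range(r) for j in range(W)])
        below = np.mean([channel[i, j] for i in range(r, H) for j in range(W)])
        g[r] = above - below
    if polarity == "dark_above":
        g = -g
    sm = (
        gaussian_filter(channel, params.smoothing_sigma, mode="reflect")
        if params.smoothing_sigma > 0
        else channel
    )
    local = np.zeros(H)
    for r in range(1, H):
        local[r] = np.mean([abs(sm[r, c] - sm[r - 1, c]) for c in range(W)])

    def norm(v):
        lo, hi = v[1:].min(), v[1:].max()
        out = np.zeros_like(v)
        if hi > lo:
            out[1:] = (v[1:] - lo) / (hi - lo)
        return out

    w = params.local_weight
    score = (1 - w) * norm(g) + w * norm(local)
    score[0] = 0.0
    return score


def oracle_lin(channel, sigma):
    sm = gaussian_filter(channel, sigma, mode="reflect") if sigma > 0 else channel
    H, W = sm.shape
    out = np.zeros(H)
    for r in range(H - 1):
        out[r] = sum(abs(sm[r + 1, c] - sm[r, c]) for c in range(W))
    return out


def oracle_gab(channel, params):
    kernel = gabor_kernel_zero_mean(
        params.wavelength, params.bandwidth, params.selectivity
    )
    re = convolve(channel, kernel.real, mode="reflect")
    im = convolve(channel, kernel.imag, mode="reflect")
    return np.hypot(re, im).sum(axis=1)


def oracle_rasterize(lines, shape):
    H, W = shape
    votes = np.zeros((H, W))
    if not lines:
        return votes
    smax = max(s for s, _, _ in lines)
    for strength, rho, theta in lines:
        if abs(np.sin(theta)) < 1e-12:
            continue
        for x in range(W):
            y = int(round((rho - x * np.cos(theta)) / np.sin(theta)))
            if 0 <= y < H:
                votes[y, x] += strength / smax
    return votes


# ---------------------------------------------------------------------------


class TestDiv:
    def test_two_tone_global_peak_at_boundary(self):
        p = profile_div(two_tone(), DivParams(local_weight=0.0))
        assert np.argmax(p.values) == 50

    def test_dark_above_inverts_preference(self):
        img = two_tone()
        light = profile_div(img, DivParams(local_weight=0.0), "light_above")
        dark = profile_div(img, DivParams(local_weight=0.0), "dark_above")
        assert dark.values[50] <= light.values.min() + 1e-12
        assert np.argmax(dark.values) != 50

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            img = rng.uniform(0, 255, (40, 30))
            params = DivParams(smoothing_sigma=1.2, local_weight=0.7)
            got = profile_div(img, params).values
            want = oracle_div(img, params, "light_above")
            np.testing.assert_allclose(got, want, atol=1e-9)

    def test_constant_image_gives_zero_profile(self):
        p = profile_div(np.full((20, 20), 9.0), DivParams())
        assert np.all(p.values == 0)

    def test_polarity_duality_of_global_term(self, rng):
        img = rng.uniform(0, 200, (30, 20))
        neg = 200.0 - img  # value-inverted image shifted into a valid range
        a = profile_div(img, DivParams(local_weight=0.0), "dark_above")
        b = profile_div(neg, DivParams(local_weight=0.0), "light_above")
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_rejects_color_array(self, rng):
        with pytest.raises(ValueError, match="one channel"):
            profile_div(rng.uniform(0, 1, (10, 10, 3)), DivParams())


class TestLin:
    def test_two_tone_unsmoothed_single_peak(self):
        p = profile_lin(two_tone(), 0.0)
        assert np.count_nonzero(p.values) == 1
        assert np.argmax(p.values) == 49  # forward difference at the boundary

    def test_constant_image_zero(self):
        assert np.all(profile_lin(np.full((15, 9), 3.0), 1.0).values == 0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            img = rng.uniform(0, 255, (25, 25))
            np.testing.assert_allclose(
                profile_lin(img, 1.5).values, oracle_lin(img, 1.5), atol=1e-9
            )


class TestGab:
    def test_constant_image_near_zero(self):
        p = profile_gab(np.full((40, 40), 7.0), GaborParams(wavelength=8))
        assert np.all(np.abs(p.values) < 1e-9)

    def test_step_edge_peak_near_boundary(self):
        params = GaborParams(wavelength=8)
        p = profile_gab(two_tone(), params)
        assert abs(np.argmax(p.values) - 50) <= int(np.ceil(8 / 2))

    def test_matches_dense_convolution_oracle(self, rng):
        params = GaborParams(wavelength=6, bandwidth=1.2, selectivity=0.6)
        for _ in range(5):
            img = rng.uniform(0, 255, (48, 32))
            np.testing.assert_allclose(
                profile_gab(img, params).values,
                oracle_gab(img, params),
                atol=1e-9,
            )

    def test_grating_translation_invariance(self):
        wavelength = 8
        H, W = 80, 40
        img = 100 + 50 * np.sin(2 * np.pi * np.arange(H) / wavelength)
        img = np.tile(img[:, None], (1, W))
        p = profile_gab(img, GaborParams(wavelength=wavelength)).values
        interior = p[20:-20]
        assert interior.max() <= interior.min() * 1.05

    def test_wavelength_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="wavelength"):
            profile_gab(np.zeros((16, 16)), GaborParams(wavelength=40))


def bundle_image(seed, n=6, H=96, W=128, row_frac=None, min_sep_deg=12.0):
    """Synthetic line-bundle image: n dark segments with well-separated
    directions converging at a vanishing point on a known row."""
    from skimage.draw import line

    rng = np.random.default_rng(seed)
    frac = row_frac if row_frac is not None else rng.uniform(0.35, 0.65)
    img = np.full((H, W), 200.0)
    vy, vx = int(frac * H), int(rng.integers(W // 3, 2 * W // 3))
    angles: list[float] = []
    while len(angles) < n:
        a = rng.uniform(np.pi * 0.2, np.pi * 0.8)
        if all(abs(np.degrees(a - b)) >= min_sep_deg for b in angles):
            angles.append(a)
    for ang in angles:
        t = min(
            (H - 1 - vy) / max(np.sin(ang), 1e-9),
            abs((W - 1 - vx) / np.cos(ang)) if np.cos(ang) > 0
            else abs(vx / np.cos(ang)) if np.cos(ang) < 0 else 1e9,
        )
        y1 = int(min(vy + t * np.sin(ang), H - 1))
        x1 = int(min(max(vx + t * np.cos(ang), 0), W - 1))
        rr, cc = line(vy, vx, y1, x1)
        img[rr, cc] = 20.0
    return img, vy


class TestVan:
    def test_bundle_recovered(self):
        img, vy = bundle_image(seed=2, n=3, row_frac=0.4)
        p = profile_van(img, VanParams())
        assert abs(np.argmax(p.values) - vy) <= 1

    def test_blank_image_zero_profile(self):
        p = profile_van(np.full((64, 64), 128.0), VanParams())
        assert np.all(p.values == 0)

    def test_voting_stage_matches_brute_force(self, rng):
        from scipy.ndimage import gaussian_filter as gf

        img, _ = bundle_image(seed=5, n=4)
        params = VanParams(exponent_rho=2.0)
        lines = van_lines(img, params)
        assert lines  # the bundle must produce Hough peaks
        votes = gf(
            oracle_rasterize(lines, img.shape), params.vote_smoothing,
            mode="constant",
        )
        want = (votes**2.0).sum(axis=1)
        np.testing.assert_allclose(
            profile_van(img, params).values, want, atol=1e-9
        )

    def test_strong_bundle_beats_faint_bundle(self):
        from skimage.draw import line

        H, W = 96, 128
        img = np.full((H, W), 200.0)
        strong_row, faint_row = int(0.3 * H), int(0.7 * H)
        for row, angles_deg, shade in [
            (strong_row, (55.0, 75.0, 105.0, 125.0), 20.0),
            (faint_row, (65.0, 115.0), 160.0),
        ]:
            vx = W // 2
            for deg in angles_deg:
                ang = np.radians(deg)
                y1 = H - 1
                x1 = int(np.clip(vx + (y1 - row) / np.tan(ang), 0, W - 1))
                rr, cc = line(row, vx, y1, x1)
                img[rr, cc] = shade
        p = profile_van(img, VanParams())
        assert abs(np.argmax(p.values) - strong_row) <= 2

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            profile_van(np.zeros((8, 8)), VanParams())

    def test_invalid_params(self):
        with pytest.raises(ValueError, match="canny_low"):
            VanParams(canny_low=5.0, canny_high=2.0)
        with pytest.raises(ValueError, match="exponent_rho"):
            VanParams(exponent_rho=0.5)


class TestWinnerTakesAll:
    def test_simple_argmax(self):
        assert winner_takes_all(ConfidenceProfile([0, 0, 5, 0])) == 0.625

    def test_all_equal_prefers_center(self):
        assert winner_takes_all(ConfidenceProfile([1, 1, 1, 1, 1])) == 0.5

    def test_tie_broken_toward_center(self):
        assert winner_takes_all(ConfidenceProfile([0, 3, 3, 0, 0])) == 0.5

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            winner_takes_all(ConfidenceProfile([0.0, np.nan, 1.0]))


class TestFlipEquivariance:
    @pytest.mark.parametrize("algorithm", ["lin", "gab"])
    def test_estimate_mirrors_under_vertical_flip(self, algorithm, rng):
        for _ in range(10):
            img = rng.uniform(0, 255, (60, 40))
            img[: rng.integers(20, 40)] += 80  # give the profile a clear peak
            if algorithm == "lin":
                y = winner_takes_all(profile_lin(img, 1.0))
                y_flip = winner_takes_all(profile_lin(img[::-1], 1.0))
            else:
                params = GaborParams(wavelength=8)
                y = winner_takes_all(profile_gab(img, params))
                y_flip = winner_takes_all(profile_gab(img[::-1], params))
            assert abs(y_flip - (1 - y)) <= 1 / 60 + 1e-12


class TestDummies:
    def test_degenerate_draws(self):
        assert dummy_estimate(DummyParams("uniform", 0.4, 0.0), 0) == 0.4
        assert dummy_estimate(DummyParams("normal", 0.6, 0.0), 1) == 0.6

    def test_uniform_distribution(self):
        params = DummyParams("uniform", 0.5, 0.2)
        draws = np.array([dummy_estimate(params, s) for s in range(20_000)])
        assert (
            stats.kstest(draws, stats.uniform(0.3, 0.4).cdf).pvalue > 0.01
        )

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError):
            dummy_estimate(DummyParams("uniform", 2.0, 0.1), 0)


def test_profile_csv_round_trip(tmp_path):
    import csv

    profile = ConfidenceProfile([0.0, 2.5, 1.25])
    path = tmp_path / "profile.csv"
    profile.to_csv(path)
    with path.open() as fh:
        rows = list(csv.DictReader(fh))
    assert [float(r["value"]) for r in rows] == [0.0, 2.5, 1.25]
    assert [int(r["row_index"]) for r in rows] == [0, 1, 2]
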