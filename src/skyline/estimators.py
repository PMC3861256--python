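"""Single-cue per-row horizon-confidence algorithms and their readout.

Each algorithm consumes exactly one L*a*b* channel and returns one
non-negative confidence per image row; a winner-takes-all readout converts
the profile into a point estimate at the center of the winning row,
``(argmax + 0.5) / H``. The cues:

* ``div`` — how well a row splits the image into a light region above and a
  dark region below (sky brighter than ground), as a linear mix of a global
  mean-difference term and a local smoothed vertical-gradient term.
* ``-div`` — the same with light and dark exchanged (``polarity``).
* ``lin`` — summed absolute vertical gradient per row: the horizon tends to
  be the strongest horizontal luminance discontinuity.
* ``gab`` — row-summed magnitude of the response to a horizontally oriented
  Gabor filter, a biologically motivated detector of horizontal structure.
* ``van`` — a vanishing-point cue: Canny edges feed a Hough transform, the
  strongest non-vertical lines are redrawn full-width into a voting image,
  voting maxima are emphasized by exponentiation and summed per row.

Two image-blind dummy baselines draw estimates from a uniform interval or a
clamped normal, providing the chance floor for comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d as _conv1d_raw
from scipy.ndimage import gaussian_filter, sobel
from skimage.feature import canny as _canny

__all__ = [
    "ConfidenceProfile",
    "DivParams",
    "GaborParams",
    "VanParams",
    "DummyParams",
    "profile_div",
    "profile_lin",
    "profile_gab",
    "profile_van",
    "van_lines",
    "rasterize_lines",
    "winner_takes_all",
    "dummy_estimate",
    "gabor_kernel_zero_mean",
]


@dataclass
class ConfidenceProfile:
    """One non-negative confidence value per image row."""

    values: np.ndarray
    channel_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("profile must be a non-empty 1-D array")

    def __len__(self) -> int:
        return self.values.size

    def to_csv(self, path) -> None:
        """Write the profile as CSV with columns (row_index, value)."""
        import csv
        from pathlib import Path

        with Path(path).open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["row_index", "value"])
            for r, v in enumerate(self.values):
                writer.writerow([r, repr(float(v))])


@dataclass
class DivParams:
    """``local_weight`` mixes the global light/dark concentration term
    (weight ``1 - local_weight``) with the local smoothed-gradient term."""

    smoothing_sigma: float = 1.0
    local_weight: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.local_weight <= 1.0:
            raise ValueError(
                f"local_weight must lie in [0, 1], got {self.local_weight}"
            )
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")


@dataclass
class GaborParams:
    wavelength: float = 8.0  # pixels per carrier cycle
    bandwidth: float = 1.0  # octaves
    selectivity: float = 0.5  # spatial aspect ratio (elongation along rows)

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError(f"wavelength must be > 0, got {self.wavelength}")
        if self.bandwidth <= 0 or self.selectivity <= 0:
            raise ValueError("bandwidth and selectivity must be > 0")


@dataclass
class VanParams:
    canny_sigma: float = 2.0
    canny_low: float = 1.0
    canny_high: float = 5.0
    hough_rho_resolution: float = 0.5  # pixels
    hough_theta_resolution: float = math.pi / 180  # radians
    n_lines: int = 20
    exponent_rho: float = 2.0
    vertical_exclusion_angle: float = 5.0  # degrees
    vote_smoothing: float = 1.5  # pixels; crossing tolerance in the vote map

    def __post_init__(self) -> None:
        if not self.canny_low < self.canny_high:
            raise ValueError(
                f"canny_low must be < canny_high, got "
                f"{self.canny_low} >= {self.canny_high}"
            )
        if self.exponent_rho < 1:
            raise ValueError(
                f"exponent_rho must be >= 1, got {self.exponent_rho}"
            )
        if self.hough_rho_resolution <= 0 or self.hough_theta_resolution <= 0:
            raise ValueError("Hough resolutions must be > 0")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")


@dataclass
class DummyParams:
    """Image-blind baseline: ``uniform`` draws from
    ``[center - spread, center + spread] ∩ [0, 1]``; ``normal`` draws from
    ``N(center, spread)`` clamped to [0, 1]."""

    kind: str = "uniform"
    center: float = 0.5
    spread: float = 0.25

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "normal"):
            raise ValueError(
                f"kind must be 'uniform' or 'normal', got {self.kind!r}"
            )
        if self.spread < 0:
            raise ValueError(f"spread must be >= 0, got {self.spread}")


def _conv1d(arr: np.ndarray, kernel: np.ndarray, axis: int) -> np.ndarray:
    return _conv1d_raw(arr, kernel, axis=axis, mode="reflect")


def _check_channel(channel: np.ndarray, min_rows: int = 2) -> np.ndarray:
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError(
            "profile operations consume exactly one channel: expected a 2-D "
            f"array, got shape {channel.shape}"
        )
    if channel.shape[0] < min_rows:
        raise ValueError(f"image must have at least {min_rows} rows")
    return channel


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi - lo == 0:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def profile_div(
    channel: np.ndarray,
    params: DivParams = DivParams(),
    polarity: str = "light_above",
) -> ConfidenceProfile:
    """Light-above/dark-below division score per row.

    For row ``r >= 1`` the global term is the difference of means above and
    below the row boundary, ``g(r) = mean(rows < r) - mean(rows >= r)``
    (sign flipped for ``dark_above``); the local term is the column-mean
    absolute vertical derivative at ``r`` after Gaussian smoothing. Both are
    min–max normalized to [0, 1] over rows before the linear mix, making the
    weighting scale-free. Row 0 has no division and scores 0.
    """
    if polarity not in ("light_above", "dark_above"):
        raise ValueError(
            f"polarity must be 'light_above' or 'dark_above', got {polarity!r}"
        )
    channel = _check_channel(channel)
    H = channel.shape[0]

    row_means = channel.mean(axis=1)
    csum = np.cumsum(row_means)
    total = csum[-1]
    r = np.arange(1, H, dtype=float)
    above = csum[:-1] / r
    below = (total - csum[:-1]) / (H - r)
    g = above - below
    if polarity == "dark_above":
        g = -g

    sm = (
        gaussian_filter(channel, params.smoothing_sigma, mode="reflect")
        if params.smoothing_sigma > 0
        else channel
    )
    local = np.abs(np.diff(sm, axis=0)).mean(axis=1)  # boundary r vs r-1

    w = params.local_weight
    score = np.zeros(H)
    score[1:] = (1.0 - w) * _minmax(g) + w * _minmax(local)
    return ConfidenceProfile(score)


def profile_lin(
    channel: np.ndarray, smoothing_sigma: float = 1.0
) -> ConfidenceProfile:
    """Summed absolute vertical (forward-difference) gradient per row.

    ``profile(r) = sum_c |sm(r+1, c) - sm(r, c)|``, assigned to row ``r``;
    the final row, with no row below it, is padded with 0.
    """
    channel = _check_channel(channel)
    sm = (
        gaussian_filter(channel, smoothing_sigma, mode="reflect")
        if smoothing_sigma > 0
        else channel
    )
    grad = np.abs(np.diff(sm, axis=0)).sum(axis=1)
    return ConfidenceProfile(np.concatenate([grad, [0.0]]))


def gabor_kernel_zero_mean(
    wavelength: float,
    bandwidth: float = 1.0,
    selectivity: float = 0.5,
    theta: float = 0.0,
    n_stds: float = 3.0,
) -> np.ndarray:
    """Complex Gabor kernel with an exactly DC-free even part.

    ``theta = 0`` gives a horizontally oriented filter (carrier along the
    vertical axis), responsive to horizontal lines and edges. The Gaussian
    envelope sigma follows the standard octave-bandwidth relation
    ``sigma = wavelength / pi * sqrt(ln 2 / 2) * (2^b + 1) / (2^b - 1)``;
    ``selectivity`` is the envelope aspect ratio (smaller = more elongated
    along the line direction). The cosine component's DC response is removed
    by subtracting an envelope-weighted constant, so constant inputs give a
    response of exactly zero.
    """
    sigma = (
        wavelength
        / math.pi
        * math.sqrt(math.log(2) / 2)
        * (2**bandwidth + 1)
        / (2**bandwidth - 1)
    )
    half = int(math.ceil(n_stds * sigma / min(1.0, selectivity)))
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    u = -x * math.sin(theta) + y * math.cos(theta)  # carrier axis
    v = x * math.cos(theta) + y * math.sin(theta)  # along-line axis
    envelope = np.exp(-(u**2 + (selectivity * v) ** 2) / (2 * sigma**2))
    carrier = np.exp(1j * 2 * math.pi * u / wavelength)
    kernel = envelope * carrier
    even = kernel.real
    even = even - envelope * (even.sum() / envelope.sum())
    return even + 1j * kernel.imag


def profile_gab(
    channel: np.ndarray, params: GaborParams = GaborParams()
) -> ConfidenceProfile:
    """Row-summed magnitude of a horizontal Gabor filter response.

    Convolution uses reflective boundary handling; the kernel's even part is
    DC-compensated so constant images yield an all-zero profile.
    """
    channel = _check_channel(channel)
    if params.wavelength > channel.shape[0]:
        raise ValueError(
            f"wavelength {params.wavelength} exceeds image height "
            f"{channel.shape[0]}"
        )
    # The horizontal (theta = 0) kernel is exactly separable: envelope along
    # columns, DC-corrected carrier along rows. Sequential 1-D convolutions
    # with reflective padding equal the dense 2-D convolution.
    wavelength, b, gamma = (
        params.wavelength, params.bandwidth, params.selectivity,
    )
    sigma = (
        wavelength
        / math.pi
        * math.sqrt(math.log(2) / 2)
        * (2**b + 1)
        / (2**b - 1)
    )
    half = int(math.ceil(3.0 * sigma / min(1.0, gamma)))
    t = np.arange(-half, half + 1, dtype=float)
    env_y = np.exp(-(t**2) / (2 * sigma**2))
    env_x = np.exp(-((gamma * t) ** 2) / (2 * sigma**2))
    even_y = env_y * np.cos(2 * math.pi * t / wavelength)
    even_y = even_y - env_y * (even_y.sum() / env_y.sum())
    odd_y = env_y * np.sin(2 * math.pi * t / wavelength)
    re = _conv1d(_conv1d(channel, even_y, axis=0), env_x, axis=1)
    im = _conv1d(_conv1d(channel, odd_y, axis=0), env_x, axis=1)
    magnitude = np.hypot(re, im)
    return ConfidenceProfile(magnitude.sum(axis=1))


_SUPPORT_DIST = 2.0  # px; edge pixels this close to an accepted line vote for it


def _iterative_hough(
    ys: np.ndarray,
    xs: np.ndarray,
    weights: np.ndarray,
    shape: tuple[int, int],
    params: "VanParams",
) -> list[tuple[float, float, float]]:
    """Iterative Hough with support removal: accept the global accumulator
    maximum, delete the edge pixels that support it (within a small
    distance of the line), and re-vote. This eliminates the broad
    "butterfly" ridge a finite segment spreads around its peak — without
    it the picker returns near-duplicates of the same physical line whose
    mutual crossings pile up at the segment midpoint instead of the
    vanishing point. Near-vertical lines (|theta| below the exclusion
    angle) are skipped since they intersect image rows almost uniformly
    and only add noise."""
    H, W = shape
    theta_res = params.hough_theta_resolution
    rho_res = params.hough_rho_resolution
    n_theta = max(int(round(math.pi / theta_res)), 4)
    thetas = -math.pi / 2 + theta_res * np.arange(n_theta)
    excluded = np.abs(thetas) < math.radians(params.vertical_exclusion_angle)
    diag = math.hypot(H, W)
    n_rho = 2 * int(math.ceil(diag / rho_res)) + 1
    rho0 = -int(math.ceil(diag / rho_res)) * rho_res
    cos_t, sin_t = np.cos(thetas), np.sin(thetas)

    out: list[tuple[float, float, float]] = []
    for _ in range(params.n_lines):
        if ys.size < 5:
            break
        acc = np.zeros((n_rho, n_theta))
        rho = xs[:, None] * cos_t + ys[:, None] * sin_t
        idx = np.round((rho - rho0) / rho_res).astype(int)
        for j in range(n_theta):
            np.add.at(acc[:, j], idx[:, j], weights)
        acc[:, excluded] = 0.0
        i, j = np.unravel_index(np.argmax(acc), acc.shape)
        strength = acc[i, j]
        if strength <= 0:
            break
        rho_v, theta_v = rho0 + rho_res * i, float(thetas[j])
        out.append((float(strength), float(rho_v), theta_v))
        dist = np.abs(
            xs * math.cos(theta_v) + ys * math.sin(theta_v) - rho_v
        )
        keep = dist > _SUPPORT_DIST
        ys, xs, weights = ys[keep], xs[keep], weights[keep]
    return out


def rasterize_lines(
    lines: list[tuple[float, float, float]], shape: tuple[int, int]
) -> np.ndarray:
    """Draw full-width lines into a voting image, one pixel per column,
    additive intensity proportional to line strength (normalized to a
    maximum of 1)."""
    H, W = shape
    votes = np.zeros((H, W))
    if not lines:
        return votes
    max_strength = max(s for s, _, _ in lines)
    xs = np.arange(W)
    for strength, rho, theta in lines:
        s = math.sin(theta)
        if abs(s) < 1e-12:
            continue
        ys = np.round((rho - xs * math.cos(theta)) / s).astype(int)
        ok = (ys >= 0) & (ys < H)
        np.add.at(votes, (ys[ok], xs[ok]), strength / max_strength)
    return votes


def van_lines(
    channel: np.ndarray, params: VanParams = VanParams()
) -> list[tuple[float, float, float]]:
    """Detected (strength, rho, theta) lines: Canny edges vote in a Hough
    accumulator weighted by gradient magnitude (so strength reflects both
    edge response and edge length); the strongest non-vertical lines are
    extracted iteratively with support removal."""
    channel = _check_channel(channel, min_rows=16)
    if channel.shape[1] < 16:
        raise ValueError("image must be at least 16 x 16 for [van]")
    edges = _canny(
        channel,
        sigma=params.canny_sigma,
        low_threshold=params.canny_low,
        high_threshold=params.canny_high,
    )
    gy = sobel(channel, axis=0)
    gx = sobel(channel, axis=1)
    magnitude = np.hypot(gx, gy)
    ys, xs = np.nonzero(edges)
    weights = magnitude[ys, xs].astype(float)
    return _iterative_hough(ys, xs, weights, channel.shape, params)


def profile_van(
    channel: np.ndarray, params: VanParams = VanParams()
) -> ConfidenceProfile:
    """Vanishing-point voting profile.

    The lines from :func:`van_lines` are redrawn across the full image
    width into a voting image, which is lightly Gaussian-smoothed (so
    crossings within quantization tolerance of each other register) before
    its pixels are emphasized by exponentiation and summed per row. Rows
    where many strong lines converge — candidate vanishing points, which
    lie on the horizon — score highest. Images with no Hough peaks yield
    an all-zero profile.
    """
    channel = _check_channel(channel, min_rows=16)
    lines = van_lines(channel, params)
    votes = rasterize_lines(lines, channel.shape)
    if params.vote_smoothing > 0:
        votes = gaussian_filter(votes, params.vote_smoothing, mode="constant")
    profile = (votes**params.exponent_rho).sum(axis=1)
    return ConfidenceProfile(profile)


def winner_takes_all(profile: ConfidenceProfile) -> float:
    """Point estimate from a confidence profile: center of the argmax row.

    Returns ``(argmax + 0.5) / H`` in full-window normalized coordinates.
    Ties are broken toward the row nearest the image center, then toward the
    smaller row index.
    """
    values = profile.values
    if not np.all(np.isfinite(values)):
        raise ValueError("profile contains non-finite values")
    H = values.size
    maxval = values.max()
    candidates = np.flatnonzero(values == maxval)
    center = (H - 1) / 2.0
    dist = np.abs(candidates - center)
    best = candidates[np.lexsort((candidates, dist))][0]
    return (best + 0.5) / H


def dummy_estimate(params: DummyParams, seed: int) -> float:
    """Image-blind random 'estimate' (the chance baseline)."""
    rng = np.random.default_rng(seed)
    if params.kind == "uniform":
        lo = max(params.center - params.spread, 0.0)
        hi = min(params.center + params.spread, 1.0)
        if lo > hi:
            raise ValueError(
                f"uniform interval [{params.center - params.spread}, "
                f"{params.center + params.spread}] does not intersect [0, 1]"
            )
        if lo == hi:
            return lo
        return float(rng.uniform(lo, hi))
    return float(np.clip(rng.normal(params.center, params.spread), 0.0, 1.0))
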