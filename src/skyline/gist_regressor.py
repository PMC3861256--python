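"""Spatial-envelope descriptor and EM-trained mixture of linear regressors.

The holistic pathway: instead of scoring individual rows, the whole image is
summarized by a spatial-envelope (GIST-style) descriptor — magnitudes of a
multi-scale, multi-orientation Gabor bank pooled over a coarse spatial grid,
concatenated over all three L*a*b* channels — and a mixture of linear
regressors maps the descriptor to a single horizon estimate. The mixture is
a cluster-weighted model: each component carries a mixing prior, a diagonal
Gaussian gate in a PCA-reduced descriptor space, and a linear regressor
with Gaussian noise; training is expectation-maximization with
ridge-stabilized weighted least squares in the M-step and restarts chosen
by final log-likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from scipy.special import logsumexp

from .estimators import gabor_kernel_zero_mean
from .imagery import LabImage

__all__ = [
    "GistDescriptor",
    "RegressorMixture",
    "gist_descriptor",
    "fit_mixture",
    "predict",
]


@dataclass
class GistDescriptor:
    """Fixed-length descriptor: 3 channels x scales x orientations x grid
    cells, plus a trailing constant 1 for the regression intercept."""

    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float).ravel()

    def __len__(self) -> int:
        return self.features.size


def _bank_kernels(scales: int, orientations: int) -> list[np.ndarray]:
    """Oriented band-pass bank: wavelengths 4 * 2**s pixels, orientations
    evenly spaced over [0, pi)."""
    kernels = []
    for s in range(scales):
        wavelength = 4.0 * 2**s
        for o in range(orientations):
            theta = o * math.pi / orientations
            kernels.append(
                gabor_kernel_zero_mean(
                    wavelength, bandwidth=1.0, selectivity=0.65, theta=theta
                )
            )
    return kernels


def _pool_grid(magnitude: np.ndarray, grid: int) -> np.ndarray:
    """Average response magnitude within each cell of a grid x grid layout."""
    H, W = magnitude.shape
    rows = np.linspace(0, H, grid + 1).astype(int)
    cols = np.linspace(0, W, grid + 1).astype(int)
    out = np.empty(grid * grid)
    k = 0
    for i in range(grid):
        for j in range(grid):
            out[k] = magnitude[rows[i] : rows[i + 1], cols[j] : cols[j + 1]].mean()
            k += 1
    return out


def gist_descriptor(
    lab: LabImage, scales: int = 4, orientations: int = 8, grid: int = 4
) -> GistDescriptor:
    """Spatial-envelope descriptor over all three L*a*b* channels.

    Descriptor length is ``3 * scales * orientations * grid**2 + 1``
    (the trailing 1 is the intercept). Deterministic.
    """
    H, W = lab.shape
    if H < 32 or W < 32:
        raise ValueError(f"image must be at least 32 x 32, got {H} x {W}")
    if grid > min(H, W):
        raise ValueError(f"grid {grid} larger than image ({H} x {W})")
    kernels = _bank_kernels(scales, orientations)
    feats: list[np.ndarray] = []
    for channel in (lab.L_channel, lab.a_channel, lab.b_channel):
        ch = np.asarray(channel, dtype=float)
        for kernel in kernels:
            # reflective padding keeps the zero-response contract for
            # constant images at the boundary
            half = kernel.shape[0] // 2
            padded = np.pad(ch, half, mode="reflect")
            resp = fftconvolve(padded, kernel, mode="same")[
                half:-half, half:-half
            ]
            feats.append(_pool_grid(np.abs(resp), grid))
    features = np.concatenate(feats + [np.ones(1)])
    return GistDescriptor(features)


@dataclass
class RegressorMixture:
    """K linear regressors with Gaussian gating in PCA descriptor space."""

    weights: np.ndarray  # K x (d + 1), last column multiplies the intercept
    noise_sd: np.ndarray  # K
    priors: np.ndarray  # K, positive, sums to 1
    centers: np.ndarray  # K x d gating means
    spreads: np.ndarray  # K x d gating standard deviations
    pca_mean: np.ndarray | None = None
    pca_components: np.ndarray | None = None  # d x raw_dim
    input_dim: int = 0
    loglik_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.priors <= 0) or abs(self.priors.sum() - 1.0) > 1e-8:
            raise ValueError("mixing priors must be positive and sum to 1")
        if np.any(self.noise_sd <= 0):
            raise ValueError("noise standard deviations must be > 0")

    @property
    def K(self) -> int:
        return self.priors.size

    def to_json_dict(self) -> dict:
        d = {
            "weights": self.weights.tolist(),
            "noise_sd": self.noise_sd.tolist(),
            "priors": self.priors.tolist(),
            "centers": self.centers.tolist(),
            "spreads": self.spreads.tolist(),
            "pca_mean": None if self.pca_mean is None
            else self.pca_mean.tolist(),
            "pca_components": None if self.pca_components is None
            else self.pca_components.tolist(),
            "input_dim": self.input_dim,
        }
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "RegressorMixture":
        return cls(
            weights=np.asarray(d["weights"]),
            noise_sd=np.asarray(d["noise_sd"]),
            priors=np.asarray(d["priors"]),
            centers=np.asarray(d["centers"]),
            spreads=np.asarray(d["spreads"]),
            pca_mean=None if d["pca_mean"] is None
            else np.asarray(d["pca_mean"]),
            pca_components=None if d["pca_components"] is None
            else np.asarray(d["pca_components"]),
            input_dim=d["input_dim"],
        )


def _as_matrix(descriptors) -> np.ndarray:
    rows = [
        d.features if isinstance(d, GistDescriptor) else np.asarray(d, float)
        for d in descriptors
    ]
    return np.vstack(rows)


def _transform(
    raw: np.ndarray,
    pca_mean: np.ndarray | None,
    pca_components: np.ndarray | None,
) -> np.ndarray:
    """Raw descriptors (intercept included) -> gated design matrix [Z, 1]."""
    body = raw[:, :-1]
    if pca_components is not None:
        body = (body - pca_mean) @ pca_components.T
    return np.hstack([body, np.ones((body.shape[0], 1))])


def _log_gauss_diag(
    z: np.ndarray, mu: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    return -0.5 * (
        np.sum(((z - mu) / sd) ** 2, axis=1)
        + 2 * np.sum(np.log(sd))
        + mu.size * math.log(2 * math.pi)
    )


_VAR_FLOOR = 1e-6
_NOISE_FLOOR = 1e-4


def fit_mixture(
    descriptors,
    targets,
    K: int = 4,
    n_restarts: int = 3,
    seed: int = 0,
    pca_dim: int | None = 64,
    ridge: float = 1e-6,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> RegressorMixture:
    """EM fit of the cluster-weighted mixture of linear regressors.

    Component responsibilities combine the mixing prior, a diagonal-Gaussian
    density over the PCA-reduced descriptor, and the target likelihood under
    the component's regressor. The M-step solves ridge-stabilized weighted
    least squares. The best of ``n_restarts`` runs by final log-likelihood
    is returned; deterministic for a fixed seed. For ``K = 1`` the fit
    reduces exactly to ridge least squares.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    raw = _as_matrix(descriptors)
    y = np.asarray(targets, dtype=float)
    n, raw_dim = raw.shape
    if y.size != n:
        raise ValueError("descriptors and targets must have equal length")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("targets must be normalized positions in [0, 1]")
    if n < 2 * K:
        raise ValueError(f"need at least {2 * K} training items for K={K}")
    if np.allclose(raw, raw[0]):
        raise ValueError("degenerate training set: all descriptors identical")

    body = raw[:, :-1]
    pca_mean = pca_components = None
    if pca_dim is not None and pca_dim < body.shape[1]:
        pca_mean = body.mean(axis=0)
        # PCA basis from the training descriptors only
        _, _, vt = np.linalg.svd(body - pca_mean, full_matrices=False)
        pca_components = vt[: min(pca_dim, n)]
    X = _transform(raw, pca_mean, pca_components)
    Z = X[:, :-1]
    d = Z.shape[1]
    rng = np.random.default_rng(seed)

    def m_step(resp: np.ndarray):
        nk = resp.sum(axis=0) + 1e-12
        priors = nk / nk.sum()
        centers = (resp.T @ Z) / nk[:, None]
        spreads = np.sqrt(
            np.maximum(
                (resp.T @ Z**2) / nk[:, None] - centers**2, _VAR_FLOOR
            )
        )
        weights = np.empty((K, d + 1))
        noise = np.empty(K)
        eye = np.eye(d + 1)
        for k in range(K):
            r = resp[:, k]
            A = X.T @ (r[:, None] * X) + ridge * eye
            b = X.T @ (r * y)
            weights[k] = np.linalg.solve(A, b)
            res = y - X @ weights[k]
            noise[k] = math.sqrt(
                max((r * res**2).sum() / nk[k], _NOISE_FLOOR**2)
            )
        return priors, centers, spreads, weights, noise

    def log_joint(priors, centers, spreads, weights, noise) -> np.ndarray:
        lj = np.empty((n, K))
        for k in range(K):
            pred = X @ weights[k]
            ly = -0.5 * (
                ((y - pred) / noise[k]) ** 2
                + math.log(2 * math.pi)
            ) - math.log(noise[k])
            lj[:, k] = (
                math.log(priors[k])
                + _log_gauss_diag(Z, centers[k], spreads[k])
                + ly
            )
        return lj

    best: RegressorMixture | None = None
    for _ in range(max(n_restarts, 1)):
        resp = rng.dirichlet(np.ones(K), size=n) if K > 1 else np.ones((n, 1))
        params = m_step(resp)
        trace: list[float] = []
        for _ in range(max_iter):
            lj = log_joint(*params)
            ll = float(logsumexp(lj, axis=1).sum())
            trace.append(ll)
            if len(trace) > 1 and trace[-1] - trace[-2] < tol:
                break
            resp = np.exp(lj - logsumexp(lj, axis=1, keepdims=True))
            params = m_step(resp)
        priors, centers, spreads, weights, noise = params
        mixture = RegressorMixture(
            weights=weights,
            noise_sd=noise,
            priors=priors,
            centers=centers,
            spreads=spreads,
            pca_mean=pca_mean,
            pca_components=pca_components,
            input_dim=raw_dim,
            loglik_trace=trace,
        )
        if best is None or trace[-1] > best.loglik_trace[-1]:
            best = mixture
    assert best is not None
    return best


def predict(
    mixture: RegressorMixture, descriptor, return_clamped: bool = False
):
    """Responsibility-weighted mixture prediction, clamped to [0, 1].

    Gating responsibilities come from the mixing priors and the gating
    Gaussians (the target is unknown at prediction time). With
    ``return_clamped=True`` returns ``(value, clamped_flag)``.
    """
    feats = (
        descriptor.features
        if isinstance(descriptor, GistDescriptor)
        else np.asarray(descriptor, float).ravel()
    )
    if feats.size != mixture.input_dim:
        raise ValueError(
            f"descriptor length {feats.size} does not match training "
            f"dimension {mixture.input_dim}"
        )
    x = _transform(
        feats[None, :], mixture.pca_mean, mixture.pca_components
    )[0]
    z = x[:-1]
    lg = np.array(
        [
            math.log(mixture.priors[k])
            + _log_gauss_diag(
                z[None, :], mixture.centers[k], mixture.spreads[k]
            )[0]
            for k in range(mixture.K)
        ]
    )
    resp = np.exp(lg - logsumexp(lg))
    value = float(resp @ (mixture.weights @ x))
    clamped = not 0.0 <= value <= 1.0
    value = min(max(value, 0.0), 1.0)
    return (value, clamped) if return_clamped else value
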