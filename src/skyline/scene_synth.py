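"""Synthetic outdoor-scene generator with exactly known horizons.

Real corpora for this task pair each photograph with a set of human horizon
estimates; neither the images nor the estimates are deposited anywhere, so
this module fabricates both. Scenes are rendered from per-class recipes that
reproduce the cue structure the estimators rely on — a sky/ground luminance
split at the horizon row, dark vertical occluders crossing it, and bundles of
perspective lines that converge on a vanishing point lying exactly on the
horizon. Simulated raters draw estimates from a truncated normal around the
true horizon with a class-dependent spread, contaminated by a small uniform
fraction, mirroring the observation that inter-rater agreement is far higher
on open coastal scenes than on closed natural ones.

Seven scene classes are supported: coast, open_country, forest,
enclosed_nature, non_urban_street, city and other. Default class proportions
follow the published stimulus counts 32/29/18/46/16/47/12.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import line as _draw_line

from ._records import SCENE_CLASSES, EstimateSet, ImageRecord

__all__ = [
    "SCENE_CLASSES",
    "DEFAULT_CLASS_COUNTS",
    "DEFAULT_CLASS_MIX",
    "DEFAULT_ESTIMATE_SD",
    "SceneSpec",
    "ImageRecord",
    "EstimateSet",
    "make_scene",
    "simulate_estimates",
    "make_corpus",
    "write_corpus",
    "row_mean_luminance",
]

# Published per-class stimulus counts (coast, open country, forest, enclosed
# nature, non-urban street, city, other); the default mix is proportional.
DEFAULT_CLASS_COUNTS = dict(
    zip(SCENE_CLASSES, (32, 29, 18, 46, 16, 47, 12))
)
_TOTAL = sum(DEFAULT_CLASS_COUNTS.values())
DEFAULT_CLASS_MIX = {c: n / _TOTAL for c, n in DEFAULT_CLASS_COUNTS.items()}

# Normalized spread of simulated rater estimates per scene class. Magnitudes
# are free generator parameters; their ordering encodes the reported pattern
# that agreement is highest for coast and lowest for closed natural scenes.
DEFAULT_ESTIMATE_SD = {
    "coast": 0.01,
    "non_urban_street": 0.02,
    "city": 0.025,
    "open_country": 0.04,
    "forest": 0.04,
    "enclosed_nature": 0.04,
    "other": 0.03,
}


@dataclass
class SceneSpec:
    """Recipe parameters for one synthetic scene.

    ``true_horizon`` is restricted to the middle third of the image,
    mirroring the stimulus-selection rule of the original corpus (labels in
    the middle third survive all subwindow manipulations).
    """

    scene_class: str
    true_horizon: float
    width: int = 128
    height: int = 96
    sky_ground_contrast: float = 0.8
    occluder_density: float = 0.0
    n_perspective_lines: int = 0
    texture_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scene_class not in SCENE_CLASSES:
            raise ValueError(
                f"scene_class must be one of {SCENE_CLASSES}, "
                f"got {self.scene_class!r}"
            )
        if not (1 / 3 <= self.true_horizon <= 2 / 3):
            raise ValueError(
                f"true_horizon must lie in [1/3, 2/3], got {self.true_horizon}"
            )
        if self.width <= 0 or self.height <= 0:
            raise ValueError(
                f"width and height must be positive, got "
                f"width={self.width}, height={self.height}"
            )
        if not 0.0 <= self.sky_ground_contrast <= 1.0:
            raise ValueError(
                f"sky_ground_contrast must lie in [0, 1], "
                f"got {self.sky_ground_contrast}"
            )
        if not 0.0 <= self.occluder_density <= 1.0:
            raise ValueError(
                f"occluder_density must lie in [0, 1], "
                f"got {self.occluder_density}"
            )
        if self.n_perspective_lines < 0:
            raise ValueError(
                f"n_perspective_lines must be >= 0, "
                f"got {self.n_perspective_lines}"
            )
        if self.texture_noise_sd < 0:
            raise ValueError(
                f"texture_noise_sd must be >= 0, got {self.texture_noise_sd}"
            )


def row_mean_luminance(pixels: np.ndarray) -> np.ndarray:
    """Mean luminance (channel average) of each pixel row.

    Inspection helper for asserting rendered cue geometry: for a clean
    two-tone scene the largest drop between consecutive entries sits at the
    horizon row.
    """
    return np.asarray(pixels, dtype=float).mean(axis=(1, 2))


def _base_split(
    spec: SceneSpec, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Render the sky/ground luminance split every recipe starts from."""
    H, W = spec.height, spec.width
    hr = int(np.floor(spec.true_horizon * H))
    hr = min(max(hr, 1), H - 1)  # keep both regions non-empty
    c = spec.sky_ground_contrast

    img = np.zeros((H, W, 3), dtype=float)
    rows = np.arange(H, dtype=float)

    # Sky: bright, bluish, gently darkening toward the horizon.
    sky_top, sky_bot = 235.0, 205.0
    if hr > 1:
        sky_lum = sky_top + (sky_bot - sky_top) * rows[:hr] / (hr - 1)
    else:
        sky_lum = np.full(1, sky_top)
    img[:hr, :, 0] = sky_lum[:, None] - 15.0
    img[:hr, :, 1] = sky_lum[:, None]
    img[:hr, :, 2] = np.minimum(sky_lum[:, None] + 15.0, 255.0)

    # Ground: dark, greenish-brown; separation from the sky scales with the
    # contrast parameter.
    g_top = sky_bot - 30.0 - 150.0 * c
    g_bot = g_top - 20.0
    n_ground = H - hr
    if n_ground > 1:
        g_lum = g_top + (g_bot - g_top) * np.arange(n_ground) / (n_ground - 1)
    else:
        g_lum = np.full(1, g_top)
    g_lum = np.clip(g_lum, 5.0, 255.0)
    img[hr:, :, 0] = g_lum[:, None] + 5.0
    img[hr:, :, 1] = g_lum[:, None] + 10.0
    img[hr:, :, 2] = g_lum[:, None] - 10.0
    return img, hr


def _undulate_ground(
    img: np.ndarray, hr: int, rng: np.random.Generator
) -> None:
    """Low-amplitude sinusoidal wiggle of the sky/ground boundary."""
    H, W, _ = img.shape
    amp = min(2, hr - 1, H - hr - 1)
    if amp <= 0:
        return
    phase = rng.uniform(0, 2 * np.pi)
    ground_color = img[min(hr + 1, H - 1), 0].copy()
    sky_color = img[max(hr - 1, 0), 0].copy()
    for x in range(W):
        d = int(round(amp * np.sin(2 * np.pi * x / W * 3 + phase)))
        if d > 0:  # boundary moves down: sky paints over ground rows
            img[hr : hr + d, x] = sky_color
        elif d < 0:  # boundary moves up
            img[hr + d : hr, x] = ground_color


def _add_occluders(
    img: np.ndarray, hr: int, density: float, rng: np.random.Generator
) -> None:
    """Dark vertical strips (tree trunks, walls) crossing the horizon."""
    H, W, _ = img.shape
    n = int(round(density * W / 6))
    for _ in range(n):
        x0 = int(rng.integers(0, W))
        w = int(rng.integers(1, 4))
        top = max(0, hr - int(rng.integers(H // 8, max(H // 3, H // 8 + 1))))
        base = min(H - 1, hr + int(rng.integers(2, max(H // 6, 3))))
        shade = rng.uniform(15, 45)
        img[top : base + 1, x0 : min(x0 + w, W), :] = shade


def _add_perspective_bundle(
    img: np.ndarray, hr: int, n_lines: int, strong: bool,
    rng: np.random.Generator,
) -> tuple[tuple[int, int], list[tuple[int, int, int, int]]]:
    """Line segments that all pass exactly through a vanishing point on the
    horizon row; extensions of every drawn segment meet there by construction.

    Returns the vanishing point ``(vx, vy)`` and the drawn segments as
    ``(y0, x0, y1, x1)`` tuples so rendered geometry can be inspected.
    """
    H, W, _ = img.shape
    vx = int(rng.integers(W // 4, 3 * W // 4))
    vy = hr
    shade = 10.0 if strong else 60.0
    segments: list[tuple[int, int, int, int]] = []
    for i in range(n_lines):
        # Endpoints on the lower/side borders so the bundle converges from
        # below, like road and facade edges do.
        angle = rng.uniform(np.pi * 0.15, np.pi * 0.85)
        dx, dy = np.cos(angle), np.sin(angle)
        # March from the vanishing point to the image border.
        ts = []
        if dy > 1e-9:
            ts.append((H - 1 - vy) / dy)
        if dx > 1e-9:
            ts.append((W - 1 - vx) / dx)
        elif dx < -1e-9:
            ts.append((0 - vx) / dx)
        t = min(t for t in ts if t > 0) if ts else 0.0
        x1 = int(round(vx + t * dx))
        y1 = int(round(vy + t * dy))
        x1 = min(max(x1, 0), W - 1)
        y1 = min(max(y1, 0), H - 1)
        rr, cc = _draw_line(vy, vx, y1, x1)
        ok = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
        img[rr[ok], cc[ok], :] = shade
        segments.append((vy, vx, y1, x1))
    return (vx, vy), segments


def make_scene(spec: SceneSpec) -> ImageRecord:
    """Render one synthetic outdoor scene from its recipe.

    Deterministic for a fixed spec (including seed). The sky/ground boundary,
    occluder strips and any perspective bundle are all placed consistently
    with ``spec.true_horizon``.
    """
    rng = np.random.default_rng(spec.seed)
    img, hr = _base_split(spec, rng)

    cls = spec.scene_class
    if cls == "other":
        cls = str(
            rng.choice([c for c in SCENE_CLASSES if c != "other"])
        )

    if cls == "open_country":
        _undulate_ground(img, hr, rng)
    if cls in ("forest", "enclosed_nature"):
        density = spec.occluder_density
        if density == 0.0 and spec.scene_class in ("forest", "enclosed_nature"):
            density = 0.7 if cls == "forest" else 0.5
        _add_occluders(img, hr, density, rng)
    elif spec.occluder_density > 0:
        _add_occluders(img, hr, spec.occluder_density, rng)
    if cls in ("non_urban_street", "city") or spec.n_perspective_lines > 0:
        n_lines = spec.n_perspective_lines
        if n_lines == 0:
            n_lines = 8 if cls == "city" else 4
        _add_perspective_bundle(img, hr, n_lines, cls == "city", rng)

    if spec.texture_noise_sd > 0:
        img = img + rng.normal(0.0, spec.texture_noise_sd, size=img.shape)

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return ImageRecord(
        id=f"{spec.scene_class}_{spec.seed}",
        pixels=pixels,
        scene_class=spec.scene_class,
        true_horizon=spec.true_horizon,
    )


def simulate_estimates(
    true_horizon: float,
    sd: float,
    n: int,
    contamination: float = 0.0,
    seed: int = 0,
    image_id: str = "",
) -> EstimateSet:
    """Simulate a set of rater horizon estimates for one image.

    Each estimate is, with probability ``1 - contamination``, drawn from a
    Normal(true_horizon, sd) truncated to [0, 1] (by rejection), otherwise
    from Uniform[0, 1]. ``sd = 0`` yields exact copies of the true horizon.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1 (a density is fitted later), got {n}")
    if sd < 0:
        raise ValueError(f"sd must be >= 0, got {sd}")
    if not 0.0 <= contamination <= 1.0:
        raise ValueError(f"contamination must lie in [0, 1], got {contamination}")
    rng = np.random.default_rng(seed)
    out: list[float] = []
    for _ in range(n):
        if contamination > 0 and rng.uniform() < contamination:
            out.append(float(rng.uniform()))
        elif sd == 0:
            out.append(float(true_horizon))
        else:
            while True:  # truncated-normal rejection sampling
                y = rng.normal(true_horizon, sd)
                if 0.0 <= y <= 1.0:
                    out.append(float(y))
                    break
    return EstimateSet(image_id=image_id, estimates=out)


def _largest_remainder(n: int, proportions: np.ndarray) -> np.ndarray:
    quota = n * proportions
    counts = np.floor(quota).astype(int)
    frac = quota - counts
    short = n - counts.sum()
    # break remainder ties by class order
    order = np.argsort(-frac, kind="stable")
    counts[order[:short]] += 1
    return counts


def make_corpus(
    n_images: int,
    class_mix: dict[str, float] | None = None,
    width: int = 128,
    height: int = 96,
    seed: int = 0,
    n_raters: int = 12,
    contamination: float = 0.0075,
) -> list[tuple[ImageRecord, EstimateSet]]:
    """Generate a corpus of scenes, each with a simulated estimate set.

    Class counts follow ``class_mix`` after largest-remainder rounding; the
    default mix is proportional to the published stimulus counts. True
    horizons are uniform over the middle third of the image height. The
    default contamination (0.75% uniform responses) is calibrated so the
    downstream 3-sigma outlier filter removes about 0.3% of estimates, the
    removal rate reported for real unlimited-time raters.
    """
    if class_mix is None:
        class_mix = DEFAULT_CLASS_MIX
    props = np.array([class_mix.get(c, 0.0) for c in SCENE_CLASSES], float)
    if (props < 0).any():
        raise ValueError("class proportions must be non-negative")
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1, got {props.sum()}")
    n_nonzero = int((props > 0).sum())
    if n_images < n_nonzero:
        raise ValueError(
            f"n_images={n_images} is smaller than the number of classes "
            f"with nonzero proportion ({n_nonzero})"
        )
    counts = _largest_remainder(n_images, props)

    rng = np.random.default_rng(seed)
    corpus: list[tuple[ImageRecord, EstimateSet]] = []
    idx = 0
    for cls, count in zip(SCENE_CLASSES, counts):
        for _ in range(count):
            th = float(rng.uniform(1 / 3, 2 / 3))
            spec = SceneSpec(
                scene_class=cls,
                true_horizon=th,
                width=width,
                height=height,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            rec = make_scene(spec)
            rec.id = f"img{idx:04d}_{cls}"
            est = simulate_estimates(
                th,
                DEFAULT_ESTIMATE_SD[cls],
                n=n_raters,
                contamination=contamination,
                seed=int(rng.integers(0, 2**31 - 1)),
                image_id=rec.id,
            )
            corpus.append((rec, est))
            idx += 1
    return corpus


def write_corpus(corpus, out_dir) -> None:
    """Write images as PNG plus manifest and estimates CSVs."""
    import pandas as pd

    from .imagery import write_image
    from pathlib import Path

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    manifest, est_rows = [], []
    for rec, est in corpus:
        path = out / "images" / f"{rec.id}.png"
        write_image(rec, path)
        manifest.append(
            dict(
                id=rec.id,
                path=str(path.relative_to(out)),
                scene_class=rec.scene_class,
                true_horizon=rec.true_horizon,
            )
        )
        for i, (pos, dnk) in enumerate(zip(est.estimates, est.do_not_know_flags)):
            est_rows.append(
                dict(image_id=rec.id, rater_index=i, position=pos,
                     do_not_know=dnk)
            )
    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
    pd.DataFrame(est_rows).to_csv(out / "estimates.csv", index=False)
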