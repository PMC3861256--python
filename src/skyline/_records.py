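"""Core record types shared across the pipeline.

These are defined here (privately) to avoid import cycles between the
scene-synthesis and imagery modules; the public homes are
:mod:`skyline.scene_synth` (ImageRecord, EstimateSet) and
:mod:`skyline.imagery` (LabImage, ConditionedImage, CoordinateMap).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageRecord", "EstimateSet"]

SCENE_CLASSES = (
    "coast",
    "open_country",
    "forest",
    "enclosed_nature",
    "non_urban_street",
    "city",
    "other",
)


@dataclass
class ImageRecord:
    """An 8-bit sRGB image with its scene class and true horizon.

    ``true_horizon`` is the normalized vertical position of the horizon in
    the full upright image: 0 is the top edge, 1 the bottom edge; the center
    of pixel row ``r`` of an ``H``-row image sits at ``(r + 0.5) / H``.
    """

    id: str
    pixels: np.ndarray  # H x W x 3, uint8
    scene_class: str
    true_horizon: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"pixels must be H x W x 3, got shape {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {self.pixels.dtype}")
        if not 0.0 <= self.true_horizon <= 1.0:
            raise ValueError(
                f"true_horizon must lie in [0, 1], got {self.true_horizon}"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class EstimateSet:
    """A set of per-rater horizon estimates for one image.

    Positions are normalized to the full upright image. Raters could decline
    to answer; such "do-not-know" responses carry no position information and
    are excluded from the positions used downstream.
    """

    image_id: str
    estimates: list[float]
    do_not_know_flags: list[bool] = field(default_factory=list)
    warning: str | None = None

    def __post_init__(self) -> None:
        if not self.do_not_know_flags:
            self.do_not_know_flags = [False] * len(self.estimates)
        if len(self.do_not_know_flags) != len(self.estimates):
            raise ValueError("one do-not-know flag is required per response")

    @property
    def positions(self) -> np.ndarray:
        """Positions of the responses that are actual estimates."""
        return np.asarray(
            [e for e, dnk in zip(self.estimates, self.do_not_know_flags) if not dnk],
            dtype=float,
        )

    def __len__(self) -> int:
        return len(self.positions)
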