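"""Containers for tilt series, marker observations and linked trails."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["TiltSeries", "MarkerObservation", "MarkerTrail", "center_trails"]


@dataclass
class TiltSeries:
    """A stack of 2D tilt images plus the minimal acquisition metadata.

    ``images`` is (n_img, h, w); ``nominal_tilt_angles`` holds one stage
    angle per image (degrees, any order). ``pixel_size`` is in Angstrom
    per pixel and ``fiducial_diameter`` in nanometres — together they set
    every detection parameter that is not overridden explicitly.
    """

    images: np.ndarray
    nominal_tilt_angles: np.ndarray
    pixel_size: float = 1.0
    fiducial_diameter: float = 10.0

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3:
            raise ValueError("images must be a (n_img, h, w) stack")
        self.nominal_tilt_angles = np.asarray(
            self.nominal_tilt_angles, dtype=float
        ).reshape(-1)
        if len(self.nominal_tilt_angles) != len(self.images):
            raise ValueError("need exactly one tilt angle per image")

    @property
    def n_images(self) -> int:
        return len(self.images)

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    @property
    def center(self) -> np.ndarray:
        """Image center in (x, y) pixel coordinates."""
        h, w = self.image_shape
        return np.array([(w - 1) / 2.0, (h - 1) / 2.0])

    @property
    def fiducial_radius_px(self) -> int:
        """Bead radius in pixels (>= 2) from diameter (nm) and pixel size (A)."""
        return max(2, int(round(self.fiducial_diameter * 10.0 / self.pixel_size / 2.0)))


@dataclass
class MarkerObservation:
    """One detected bead position in one tilt image (x, y pixels)."""

    image_index: int
    position_2d: np.ndarray
    cc_score: float = 0.0
    marker_id: Optional[int] = None

    def __post_init__(self) -> None:
        self.position_2d = np.asarray(self.position_2d, dtype=float).reshape(2)


@dataclass
class MarkerTrail:
    """Ordered observations of one physical marker across tilt images."""

    observations: list = field(default_factory=list)
    marker_id: int = -1

    def __post_init__(self) -> None:
        self.sort()

    def sort(self) -> None:
        self.observations.sort(key=lambda o: o.image_index)
        seen = set()
        for o in self.observations:
            if o.image_index in seen:
                raise ValueError(
                    f"trail has two observations in image {o.image_index}"
                )
            seen.add(o.image_index)
            o.marker_id = self.marker_id

    def __len__(self) -> int:
        return len(self.observations)

    @property
    def image_indices(self) -> np.ndarray:
        return np.array([o.image_index for o in self.observations], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([o.position_2d for o in self.observations], dtype=float)


def center_trails(trails, center) -> list["MarkerTrail"]:
    """Copies of trails with positions shifted into center-relative coords.

    Detection and patch work use pixel coordinates (origin at pixel 0, 0);
    the projection model is solved about the image center, so trails are
    re-expressed before every solve.
    """
    center = np.asarray(center, dtype=float).reshape(2)
    out = []
    for t in trails:
        obs = [
            MarkerObservation(o.image_index, o.position_2d - center, o.cc_score,
                              t.marker_id)
            for o in t.observations
        ]
        out.append(MarkerTrail(observations=obs, marker_id=t.marker_id))
    return out
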