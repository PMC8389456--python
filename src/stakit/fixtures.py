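"""Deterministic synthetic-data generation.

Everything here is a pure function of its seed/recipe: simulated tilt
series with gold-bead fiducials (ground truth returned alongside),
regular lattice pose sets with known neighbour structure, and randomized
grammar-valid STAR / Dynamo-table / mdoc documents for round-trip
property testing. No external dataset is ever required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_formats import DynamoTable, MdocDocument, MdocSection, StarDocument, StarLoop
from .picking import ParticlePoseSet, seed_sphere
from .tilt_alignment.model import Marker3DModel, ProjectionModel, project_points
from .tilt_alignment.series import TiltSeries

__all__ = [
    "SimulationRecipe",
    "simulate_tilt_series",
    "make_lattice_poses",
    "random_star",
    "random_dynamo_table",
    "random_mdoc",
]


@dataclass
class SimulationRecipe:
    """Study conditions for a simulated fiducial tilt series.

    Defaults model a typical binned cryo-ET acquisition: a symmetric
    -60..+60 degree series in 3-degree steps, 15 gold beads of 4 px
    radius in a 512-pixel field, tilt-axis angle 85.3 degrees, random
    per-image stage shifts up to 20 px, and SNR 2 (peak bead contrast
    over noise sigma).
    """

    n_tilts: int = 41
    tilt_range: tuple[float, float] = (-60.0, 60.0)
    true_axis_angle: float = 85.3
    true_shifts: np.ndarray | None = None     # (n_tilts, 2) px, or drawn
    shift_amplitude: float = 20.0
    n_beads: int = 15
    bead_radius_px: float = 4.0
    image_size: int = 512
    snr: float = 2.0
    rng_seed: int = 0

    @property
    def tilt_angles(self) -> np.ndarray:
        if self.n_tilts < 1:
            raise ValueError("need at least one tilt")
        if self.n_tilts == 1:
            return np.array([0.5 * sum(self.tilt_range)])
        return np.linspace(self.tilt_range[0], self.tilt_range[1], self.n_tilts)


def _render_bead(
    image: np.ndarray, xy: np.ndarray, radius: float, blur_sigma: float = 1.0
) -> None:
    """Add one dark bead (depth 1) at a subpixel position, in place.

    The disc is rasterized at 4x supersampling and box-downscaled so
    subpixel positions shift the rendered mass honestly, then blurred.
    """
    h, w = image.shape
    half = int(np.ceil(radius + 4 * blur_sigma)) + 2
    cx, cy = xy
    x0, y0 = int(np.floor(cx)) - half, int(np.floor(cy)) - half
    x1, y1 = x0 + 2 * half + 1, y0 + 2 * half + 1
    if x1 <= 0 or y1 <= 0 or x0 >= w or y0 >= h:
        return
    side = 2 * half + 1
    ss = 4
    yy, xx = np.mgrid[: side * ss, : side * ss]
    # supersampled pixel centers in image coordinates
    xs = x0 + (xx + 0.5) / ss - 0.5
    ys = y0 + (yy + 0.5) / ss - 0.5
    d = np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2)
    disc = np.clip((radius - d) * ss + 0.5, 0.0, 1.0)
    patch = disc.reshape(side, ss, side, ss).mean(axis=(1, 3))
    patch = gaussian_filter(patch, blur_sigma)
    ix0, iy0 = max(x0, 0), max(y0, 0)
    ix1, iy1 = min(x1, w), min(y1, h)
    image[iy0:iy1, ix0:ix1] -= patch[iy0 - y0 : iy1 - y0, ix0 - x0 : ix1 - x0]


def simulate_tilt_series(
    recipe: SimulationRecipe,
) -> tuple[TiltSeries, ProjectionModel, Marker3DModel]:
    """Render a bead tilt series and return it with its exact ground truth.

    Beads are placed uniformly in a slab (zero-mean by construction so the
    model gauge is fixed), projected through the single-axis model, drawn
    as Gaussian-blurred discs of unit contrast and overlaid with Gaussian
    noise of sigma ``1 / snr``. Before noise, rendered bead centers
    satisfy the projection equation exactly.
    """
    if recipe.n_tilts < 1:
        raise ValueError("recipe requests zero tilt images")
    rng = np.random.default_rng(recipe.rng_seed)
    tilts = recipe.tilt_angles
    n = recipe.n_tilts
    size = recipe.image_size

    if recipe.true_shifts is None:
        shifts = rng.uniform(-recipe.shift_amplitude, recipe.shift_amplitude, (n, 2))
    else:
        shifts = np.asarray(recipe.true_shifts, dtype=float).reshape(n, 2)
    model = ProjectionModel(recipe.true_axis_angle, shifts, tilts)

    margin = 4 * recipe.bead_radius_px + 8
    half_xy = 0.35 * size
    half_z = size / 8.0
    center = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    beads = None
    for _ in range(200):
        cand = np.column_stack([
            rng.uniform(-half_xy, half_xy, recipe.n_beads),
            rng.uniform(-half_xy, half_xy, recipe.n_beads),
            rng.uniform(-half_z, half_z, recipe.n_beads),
        ])
        cand -= cand.mean(axis=0)
        proj = project_points(model, cand) + center
        if proj.min() >= margin and proj.max() <= size - 1 - margin:
            beads = cand
            break
    if beads is None:
        raise ValueError(
            "could not place beads so that every projection stays in frame; "
            "reduce shifts, bead count or tilt range"
        )

    proj = project_points(model, beads) + center      # (n, m, 2)
    images = np.zeros((n, size, size))
    for i in range(n):
        for j in range(recipe.n_beads):
            _render_bead(images[i], proj[i, j], recipe.bead_radius_px)
    if np.isfinite(recipe.snr) and recipe.snr > 0:
        images += rng.normal(0.0, 1.0 / recipe.snr, images.shape)

    series = TiltSeries(
        images=images,
        nominal_tilt_angles=tilts,
        pixel_size=10.0,
        fiducial_diameter=2.0 * recipe.bead_radius_px,  # nm at 10 A/px
    )
    markers = Marker3DModel(
        coordinates={j: beads[j] for j in range(recipe.n_beads)},
        rmsd={j: 0.0 for j in range(recipe.n_beads)},
    )
    return series, model, markers


def make_lattice_poses(
    kind: str,
    spacing: float,
    extent: float,
    seed: int = 0,
    tomogram_id: int = 1,
) -> ParticlePoseSet:
    """Deterministic lattices with known neighbour structure.

    ``grid``: square 2D grid in the z=0 plane with identity orientations;
    ``hexagonal``: triangular lattice whose interior sites have exactly 6
    neighbours at ``spacing``; ``sphere``: Fibonacci shell of radius
    ``extent`` with radial orientations.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if kind == "sphere":
        return seed_sphere(
            np.zeros(3), extent, spacing, rng=seed, tomogram_id=tomogram_id
        )
    if kind == "grid":
        k = int(np.floor(extent / spacing)) + 1
        xs, ys = np.meshgrid(np.arange(k) * spacing, np.arange(k) * spacing)
        pos = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(k * k)])
    elif kind == "hexagonal":
        rows = int(np.floor(extent / (spacing * np.sqrt(3) / 2))) + 1
        cols = int(np.floor(extent / spacing)) + 1
        pts = []
        for r in range(rows):
            xoff = 0.5 * spacing if r % 2 else 0.0
            for c in range(cols):
                pts.append([c * spacing + xoff, r * spacing * np.sqrt(3) / 2, 0.0])
        pos = np.asarray(pts)
    else:
        raise ValueError(f"unknown lattice kind {kind!r}")
    n = len(pos)
    return ParticlePoseSet(
        pos, np.repeat(np.eye(3)[None], n, axis=0), tomogram_id,
        np.arange(1, n + 1),
    )


_WORDS = ("alpha", "beta", "gamma", "delta", "eps", "zeta", "theta", "kappa")


def _random_token(rng: np.random.Generator) -> str:
    kind = rng.integers(0, 3)
    if kind == 0:
        return str(int(rng.integers(-1000, 1000)))
    if kind == 1:
        return repr(float(np.round(rng.normal(0, 100), 6)))
    return _WORDS[rng.integers(0, len(_WORDS))] + str(int(rng.integers(0, 100)))


def random_star(seed: int, size: int = 3) -> StarDocument:
    """Grammar-valid randomized STAR document with ``size`` blocks."""
    rng = np.random.default_rng(seed)
    doc = StarDocument()
    for b in range(size):
        name = f"block_{b}"
        if rng.random() < 0.4:
            tags = {
                f"_tag{t}": _random_token(rng)
                for t in range(int(rng.integers(1, 8)))
            }
            doc.blocks[name] = tags
        else:
            n_cols = int(rng.integers(1, 6))
            n_rows = int(rng.integers(0, 20))
            cols = [f"_col{c}" for c in range(n_cols)]
            rows = [
                [_random_token(rng) for _ in range(n_cols)] for _ in range(n_rows)
            ]
            doc.blocks[name] = StarLoop(columns=cols, rows=rows)
    return doc


def random_dynamo_table(seed: int, size: int = 10) -> DynamoTable:
    """Randomized table with ``size`` rows and 26-40 columns."""
    rng = np.random.default_rng(seed)
    if size == 0:
        return DynamoTable(np.empty((0, 0)))
    n_cols = int(rng.integers(26, 41))
    data = np.round(rng.normal(0, 100, (size, n_cols)), 6)
    data[:, 0] = rng.permutation(np.arange(1, size + 1))          # tags
    data[:, 1:3] = rng.integers(0, 2, (size, 2))                  # flags
    data[:, 19] = rng.integers(1, 5, size)                        # tomogram
    return DynamoTable(data)


def random_mdoc(seed: int, size: int = 5) -> MdocDocument:
    """Randomized mdoc with ``size`` sections and a plausible header."""
    rng = np.random.default_rng(seed)
    doc = MdocDocument(
        header={
            "PixelSpacing": repr(float(np.round(rng.uniform(0.5, 3.0), 4))),
            "Voltage": "300",
            "ImageFile": f"series_{seed}.mrc",
        },
        titles=["SerialEM: synthetic fixture"],
    )
    tilts = np.round(rng.uniform(-60, 60, size), 2)
    for z in range(size):
        doc.sections.append(
            MdocSection(
                zvalue=z,
                entries={
                    "TiltAngle": repr(float(tilts[z])),
                    "SubFramePath": f"X:\\frames\\img_{z:03d}.mrc",
                    "ExposureDose": repr(float(np.round(rng.uniform(2, 4), 3))),
                },
            )
        )
    return doc
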