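"""End-to-end automated fiducial-based tilt-series alignment.

``align_tilt_series`` chains every stage — synthetic template, two-pass
detection, symmetry filtering, trail indexing, initial model estimation,
robust projection-model solving, reprojection reindexing and
reintegration, per-marker center refinement, and RMSD pruning — deriving
all stage parameters from two physical inputs (fiducial diameter and
pixel size) unless overridden. The whole chain is deterministic: equal
input produces equal output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .detection import (
    build_data_template,
    detect_candidates,
    extract_patch,
    rotational_symmetry_filter,
    synthetic_bead_template,
)
from .imod import write_imod_alignment
from .model import (
    AlignmentResult,
    Marker3DModel,
    ProjectionModel,
    estimate_initial_model,
    residual_norms,
    solve_projection_model,
    triangulate_markers,
)
from .series import MarkerObservation, TiltSeries, center_trails
from .trails import (
    index_trails,
    merge_close_markers,
    refine_marker_centers,
    reindex_by_reprojection,
    reintegrate_missing,
)

__all__ = ["AlignmentParams", "align_tilt_series", "prune_by_rmsd", "write_report"]


@dataclass
class AlignmentParams:
    """Stage parameters; None means "derive from the fiducial radius".

    Defaults follow simple multiples of the bead radius r: detection
    exclusion 2r (one synthetic-template width), reprojection/search radii
    5r, RMSD pruning threshold 1.5r.
    """

    n_candidates: int = 50
    symmetry_threshold: float = 0.4
    link_radius_px: Optional[float] = None
    reindex_threshold_px: Optional[float] = None
    reintegrate_radius_px: Optional[float] = None
    prune_rmsd_px: Optional[float] = None
    min_trail_fraction: float = 0.33
    psi_grid_step: float = 3.0
    robust: bool = True

    def derived(self, radius_px: int) -> "AlignmentParams":
        d = AlignmentParams(**self.__dict__)
        if d.reindex_threshold_px is None:
            d.reindex_threshold_px = 5.0 * radius_px
        if d.reintegrate_radius_px is None:
            d.reintegrate_radius_px = 5.0 * radius_px
        if d.prune_rmsd_px is None:
            d.prune_rmsd_px = 1.5 * radius_px
        return d


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the failing stage name."""
    class _ctx:
        def __enter__(self):
            return self
        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"tilt alignment failed in stage '{name}': {exc}") from exc
            return False
    return _ctx()


class _StageError(RuntimeError):
    pass


def align_tilt_series(
    tilt_series: TiltSeries,
    params: Optional[AlignmentParams] = None,
) -> AlignmentResult:
    """Run the full automated alignment chain on one tilt series."""
    params = (params or AlignmentParams()).derived(tilt_series.fiducial_radius_px)
    radius = tilt_series.fiducial_radius_px
    patch_side = 4 * radius + 1

    with _stage("synthetic template"):
        template = synthetic_bead_template(radius)

    with _stage("first-pass detection"):
        first_pass: list[MarkerObservation] = []
        for i, image in enumerate(tilt_series.images):
            first_pass.extend(
                detect_candidates(image, template, params.n_candidates, image_index=i)
            )
        if not first_pass:
            raise ValueError("no bead candidates found in any image")

    with _stage("data template"):
        data_template = build_data_template(
            tilt_series, first_pass, template_side=patch_side
        )

    with _stage("second-pass detection"):
        candidates: list[MarkerObservation] = []
        for i, image in enumerate(tilt_series.images):
            candidates.extend(
                detect_candidates(
                    image, data_template, params.n_candidates, image_index=i
                )
            )

    with _stage("rotational symmetry filter"):
        patches = [
            extract_patch(tilt_series.images[o.image_index], o.position_2d, patch_side)
            for o in candidates
        ]
        keep = [i for i, p in enumerate(patches) if p is not None]
        candidates = [candidates[i] for i in keep]
        patches = [patches[i] for i in keep]
        candidates = rotational_symmetry_filter(
            candidates, patches, params.symmetry_threshold,
            smooth_sigma=max(1.0, radius / 2.0),
        )

    with _stage("trail indexing"):
        trails = index_trails(tilt_series, candidates, params.link_radius_px)
        min_len = max(3, int(params.min_trail_fraction * tilt_series.n_images))
        long_trails = [t for t in trails if len(t) >= min_len]
        if len(long_trails) < 3:
            long_trails = trails[:max(3, len(trails))]
        if len(long_trails) < 3:
            raise ValueError(
                f"only {len(long_trails)} marker trails found; need >= 3"
            )

    with _stage("initial model"):
        solver_trails = center_trails(long_trails, tilt_series.center)
        model, markers = estimate_initial_model(
            solver_trails, tilt_series, psi_step=params.psi_grid_step
        )

    with _stage("projection model"):
        model, markers = solve_projection_model(
            solver_trails, markers, tilt_series, robust=params.robust, initial=model
        )

    with _stage("reindex by reprojection"):
        trails, model, markers = reindex_by_reprojection(
            model, markers, candidates, tilt_series, params.reindex_threshold_px
        )
        markers, trails = merge_close_markers(markers, trails, 3.0 * radius)
        model, markers = solve_projection_model(
            center_trails(trails, tilt_series.center), markers, tilt_series,
            robust=params.robust, initial=model,
        )

    with _stage("reintegrate missing"):
        trails = reintegrate_missing(
            model, markers, tilt_series, candidates, trails,
            params.reintegrate_radius_px,
        )
        model, markers = solve_projection_model(
            center_trails(trails, tilt_series.center), markers, tilt_series,
            robust=params.robust, initial=model,
        )

    with _stage("marker center refinement"):
        trails = refine_marker_centers(tilt_series, trails)
        model, markers = solve_projection_model(
            center_trails(trails, tilt_series.center), markers, tilt_series,
            robust=params.robust, initial=model,
        )

    with _stage("residuals"):
        centered = center_trails(trails, tilt_series.center)
        res = residual_norms(centered, model, markers)
        result = AlignmentResult(model, markers, res, pruned_marker_ids=[])

    with _stage("RMSD pruning"):
        result = prune_by_rmsd(
            result, params.prune_rmsd_px, trails, tilt_series,
            robust=params.robust,
        )
    return result


def prune_by_rmsd(
    result: AlignmentResult,
    max_rmsd_px: float,
    trails,
    tilt_series: TiltSeries,
    robust: bool = True,
) -> AlignmentResult:
    """Drop markers whose reprojection RMSD exceeds the threshold.

    The model is re-solved once on the surviving markers. If pruning would
    leave fewer than 3 markers, nothing is pruned and an error is raised.
    """
    rmsd = {
        m: float(np.sqrt(np.mean(r**2))) for m, r in result.residuals.items()
    }
    bad = [m for m, v in rmsd.items() if v > max_rmsd_px]
    if not bad:
        return result
    if len(rmsd) - len(bad) < 3:
        raise ValueError(
            f"pruning at RMSD {max_rmsd_px} px would leave "
            f"{len(rmsd) - len(bad)} markers; at least 3 are required"
        )
    kept_trails = [t for t in trails if t.marker_id not in bad]
    markers = Marker3DModel(
        coordinates={
            m: c for m, c in result.marker_model.coordinates.items() if m not in bad
        },
        rmsd={m: v for m, v in rmsd.items() if m not in bad},
    )
    model, markers = solve_projection_model(
        center_trails(kept_trails, tilt_series.center), markers, tilt_series,
        robust=robust, initial=result.projection_model,
    )
    res = residual_norms(
        center_trails(kept_trails, tilt_series.center), model, markers
    )
    pruned = sorted(set(result.pruned_marker_ids) | set(bad))
    return AlignmentResult(model, markers, res, pruned_marker_ids=pruned)


def write_report(
    result: AlignmentResult,
    directory: Union[str, Path],
    basename: str = "alignment",
) -> dict[str, Path]:
    """Write .xf, .tlt, a plain-text residual report and a JSON result."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "xf": directory / f"{basename}.xf",
        "tlt": directory / f"{basename}.tlt",
        "report": directory / f"{basename}_report.txt",
        "json": directory / f"{basename}.json",
    }
    write_imod_alignment(result, paths["xf"], paths["tlt"])
    model = result.projection_model
    lines = [
        f"tilt axis angle (deg): {model.tilt_axis_angle:.4f}",
        f"images: {model.n_images}",
        f"markers: {len(result.marker_model)}",
        f"pruned markers: {result.pruned_marker_ids}",
        f"global residual RMSD (px): {result.global_rmsd:.4f}",
        "",
        "marker   n_obs   rmsd_px",
    ]
    for m in result.marker_model.ids():
        r = result.residuals.get(m, np.array([]))
        rmsd = float(np.sqrt(np.mean(r**2))) if len(r) else float("nan")
        lines.append(f"{m:6d}   {len(r):5d}   {rmsd:7.3f}")
    paths["report"].write_text("\n".join(lines) + "\n", encoding="utf-8")
    payload = {
        "tilt_axis_angle": model.tilt_axis_angle,
        "shifts": model.shifts.tolist(),
        "tilt_angles": model.tilt_angles.tolist(),
        "markers": {
            str(m): c.tolist() for m, c in result.marker_model.coordinates.items()
        },
        "pruned_marker_ids": result.pruned_marker_ids,
        "global_rmsd": result.global_rmsd,
    }
    paths["json"].write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return paths
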