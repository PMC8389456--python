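"""Linking bead observations across tilt images and refining them.

``index_trails`` chains observations of the same physical marker through
neighbouring images (mutual-best local-patch correlation, after coarse
phase-correlation pre-alignment of consecutive images). Once a projection
model exists, ``reindex_by_reprojection`` and ``reintegrate_missing`` grow
the assignment set from the candidate cloud, and
``refine_marker_centers`` polishes each observation against a per-marker
reference averaged over the whole series.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import fourier_shift, gaussian_filter
from skimage.registration import phase_cross_correlation

from .detection import extract_patch, register_patch
from .model import (
    Marker3DModel,
    ProjectionModel,
    project_points,
    solve_projection_model,
    triangulate_markers,
)
from .series import MarkerObservation, MarkerTrail, TiltSeries, center_trails

__all__ = [
    "index_trails",
    "reindex_by_reprojection",
    "reintegrate_missing",
    "refine_marker_centers",
    "merge_close_markers",
]


def _chain_offsets(images: np.ndarray, smooth_sigma: float = 2.0) -> np.ndarray:
    """(n-1, 2) coarse x/y offsets between consecutive images.

    Phase correlation between neighbouring tilts captures the stage shift
    plus mean geometric motion; compensating it keeps the linking search
    radius small even for series with large random shifts. Images are
    low-passed first — the correlation peak of sparse bead constellations
    is otherwise easily buried in pixel noise.
    """
    offsets = np.zeros((len(images) - 1, 2))
    prev = gaussian_filter(images[0], smooth_sigma)
    for i in range(len(images) - 1):
        nxt = gaussian_filter(images[i + 1], smooth_sigma)
        shift, *_ = phase_cross_correlation(
            prev, nxt, normalization=None, upsample_factor=1
        )
        # returned as (row, col) displacement of image i+1 relative to i
        offsets[i] = [-shift[1], -shift[0]]
        prev = nxt
    return offsets


def _patch_corr(a: Optional[np.ndarray], b: Optional[np.ndarray]) -> float:
    if a is None or b is None:
        return -1.0
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return -1.0
    return float((a * b).sum() / denom)


def index_trails(
    tilt_series: TiltSeries,
    observations: Sequence[MarkerObservation],
    search_radius_px: Optional[float] = None,
) -> list[MarkerTrail]:
    """Link observations of the same marker across neighbouring images.

    For each observation in image i the candidates in image i+1 within the
    (offset-compensated) search radius are scored by local-patch
    correlation with a small distance penalty; links require mutual best
    agreement. Connected chains become trails, returned longest first.
    """
    per_image: dict[int, list[MarkerObservation]] = {}
    for obs in observations:
        per_image.setdefault(obs.image_index, []).append(obs)
    if len(per_image) < 2:
        return []
    if search_radius_px is None:
        search_radius_px = max(5.0 * tilt_series.fiducial_radius_px,
                               0.035 * tilt_series.image_shape[0])
    patch_side = 4 * tilt_series.fiducial_radius_px + 1
    offsets = _chain_offsets(tilt_series.images)

    obj: dict[int, MarkerObservation] = {}
    successor: dict[int, int] = {}
    predecessor: dict[int, int] = {}

    for i in range(tilt_series.n_images - 1):
        left = per_image.get(i, [])
        right = per_image.get(i + 1, [])
        if not left or not right:
            continue
        lp = [extract_patch(tilt_series.images[i], o.position_2d, patch_side) for o in left]
        rp = [extract_patch(tilt_series.images[i + 1], o.position_2d, patch_side) for o in right]
        lpos = np.array([o.position_2d for o in left]) + offsets[i]
        rpos = np.array([o.position_2d for o in right])
        d = np.linalg.norm(lpos[:, None, :] - rpos[None, :, :], axis=2)
        score = np.full(d.shape, -np.inf)
        for a in range(len(left)):
            for b in range(len(right)):
                if d[a, b] <= search_radius_px:
                    score[a, b] = (
                        _patch_corr(lp[a], rp[b]) - 0.25 * d[a, b] / search_radius_px
                    )
        if not np.isfinite(score).any():
            continue
        best_r = np.argmax(score, axis=1)
        best_l = np.argmax(score, axis=0)
        for a in range(len(left)):
            b = best_r[a]
            if np.isfinite(score[a, b]) and best_l[b] == a:
                successor[id(left[a])] = id(right[b])
                predecessor[id(right[b])] = id(left[a])
        for o in left + right:
            obj[id(o)] = o

    for obs in observations:
        obj.setdefault(id(obs), obs)

    trails: list[MarkerTrail] = []
    visited: set[int] = set()
    for obs in observations:
        key = id(obs)
        if key in visited or key in predecessor:
            continue
        chain = [obj[key]]
        visited.add(key)
        while key in successor:
            key = successor[key]
            chain.append(obj[key])
            visited.add(key)
        if len(chain) >= 2:
            trails.append(MarkerTrail(observations=chain))
    trails.sort(key=len, reverse=True)
    for mid, trail in enumerate(trails):
        trail.marker_id = mid
        for o in trail.observations:
            o.marker_id = mid
    return trails


def _assign(
    model: ProjectionModel,
    markers: Marker3DModel,
    observations: Sequence[MarkerObservation],
    center: np.ndarray,
    threshold: float,
) -> dict[tuple[int, int], MarkerObservation]:
    """Greedy nearest assignment of observations to reprojected markers.

    Returns {(marker_id, image_index): observation}; each observation and
    each (marker, image) slot is used at most once, closest pairs first.
    """
    ids = markers.ids()
    if not ids or threshold <= 0:
        return {}
    coords = markers.as_array(ids)
    proj = project_points(model, coords) + center   # (n_img, m, 2)
    pairs = []
    for oi, obs in enumerate(observations):
        pred = proj[obs.image_index]                 # (m, 2)
        dist = np.linalg.norm(pred - obs.position_2d, axis=1)
        for mi in np.nonzero(dist <= threshold)[0]:
            pairs.append((dist[mi], oi, ids[mi]))
    pairs.sort(key=lambda t: t[0])
    taken_obs: set[int] = set()
    taken_slot: set[tuple[int, int]] = set()
    out: dict[tuple[int, int], MarkerObservation] = {}
    for dist, oi, marker in pairs:
        obs = observations[oi]
        slot = (marker, obs.image_index)
        if oi in taken_obs or slot in taken_slot:
            continue
        taken_obs.add(oi)
        taken_slot.add(slot)
        out[slot] = obs
    return out


def _trails_from_assignment(
    assignment: dict[tuple[int, int], MarkerObservation]
) -> list[MarkerTrail]:
    grouped: dict[int, list[MarkerObservation]] = {}
    for (marker, _img), obs in assignment.items():
        grouped.setdefault(marker, []).append(obs)
    trails = []
    for marker, obs_list in sorted(grouped.items()):
        if len(obs_list) >= 2:
            trails.append(MarkerTrail(observations=obs_list, marker_id=marker))
    return trails


def reindex_by_reprojection(
    model: ProjectionModel,
    marker_model: Marker3DModel,
    observations: Sequence[MarkerObservation],
    tilt_series: TiltSeries,
    distance_threshold_px: float,
    max_rounds: int = 10,
) -> tuple[list[MarkerTrail], ProjectionModel, Marker3DModel]:
    """Grow marker trails by reprojection until the assignment is stable.

    Observations within the distance threshold of a reprojected marker
    join that marker's trail (closest marker wins, one observation per
    marker per image); the model is re-solved and the cycle repeats until
    the assignment set stops changing.
    """
    center = tilt_series.center
    prev_keys: Optional[set] = None
    trails: list[MarkerTrail] = []
    for _ in range(max_rounds):
        assignment = _assign(
            model, marker_model, observations, center, distance_threshold_px
        )
        keys = {(m, i, id(o)) for (m, i), o in assignment.items()}
        trails = _trails_from_assignment(assignment)
        if prev_keys is not None and keys == prev_keys:
            break
        prev_keys = keys
        if distance_threshold_px <= 0 or len(trails) < 3:
            break
        model, marker_model = solve_projection_model(
            center_trails(trails, center), marker_model, tilt_series, initial=model
        )
    return trails, model, marker_model


def reintegrate_missing(
    model: ProjectionModel,
    marker_model: Marker3DModel,
    tilt_series: TiltSeries,
    initial_observations: Sequence[MarkerObservation],
    trails: Sequence[MarkerTrail],
    search_radius_px: Optional[float] = None,
) -> list[MarkerTrail]:
    """Recover marker/image slots with no assigned observation.

    For each image, the reprojected constellation of markers missing in
    that image is compared against the unassigned initial candidates:
    a least-squares 2D offset between constellation and candidates is
    estimated from provisional matches, then matches within the search
    radius are accepted. Never removes observations, so the total
    observation count cannot decrease.
    """
    if search_radius_px is None:
        search_radius_px = 5.0 * tilt_series.fiducial_radius_px
    center = tilt_series.center
    assigned_ids = set()
    slots_filled = set()
    grouped: dict[int, list[MarkerObservation]] = {}
    for trail in trails:
        grouped[trail.marker_id] = list(trail.observations)
        for o in trail.observations:
            assigned_ids.add(id(o))
            slots_filled.add((trail.marker_id, o.image_index))

    free_by_image: dict[int, list[MarkerObservation]] = {}
    for obs in initial_observations:
        if id(obs) not in assigned_ids:
            free_by_image.setdefault(obs.image_index, []).append(obs)

    ids = marker_model.ids()
    if not ids:
        return list(trails)
    proj = project_points(model, marker_model.as_array(ids)) + center

    for img in range(tilt_series.n_images):
        missing = [m for m in ids if (m, img) not in slots_filled]
        cands = free_by_image.get(img, [])
        if not missing or not cands:
            continue
        pred = np.array([proj[img][ids.index(m)] for m in missing])
        cpos = np.array([o.position_2d for o in cands])
        d = np.linalg.norm(pred[:, None, :] - cpos[None, :, :], axis=2)
        # provisional matches estimate a residual constellation offset
        prov = d.min(axis=1) <= search_radius_px
        if not prov.any():
            continue
        nearest = d.argmin(axis=1)
        offset = np.mean(cpos[nearest[prov]] - pred[prov], axis=0)
        d2 = np.linalg.norm(
            (pred + offset)[:, None, :] - cpos[None, :, :], axis=2
        )
        order = np.dstack(np.unravel_index(np.argsort(d2, axis=None), d2.shape))[0]
        used_m: set[int] = set()
        used_c: set[int] = set()
        for mi, ci in order:
            if d2[mi, ci] > search_radius_px:
                break
            if mi in used_m or ci in used_c:
                continue
            used_m.add(mi)
            used_c.add(ci)
            obs = cands[ci]
            marker = missing[mi]
            obs.marker_id = marker
            grouped.setdefault(marker, []).append(obs)
            slots_filled.add((marker, img))

    out = []
    for marker in sorted(grouped):
        obs_list = grouped[marker]
        if len(obs_list) >= 2:
            out.append(MarkerTrail(observations=obs_list, marker_id=marker))
    return out


def _dark_center_of_mass(patch: np.ndarray) -> Optional[np.ndarray]:
    """(x, y) center of mass of the dark blob in a patch, or None if flat."""
    w = np.clip(np.median(patch) - patch, 0.0, None)
    total = w.sum()
    if total <= 0:
        return None
    yy, xx = np.mgrid[: patch.shape[0], : patch.shape[1]]
    return np.array([(w * xx).sum() / total, (w * yy).sum() / total])


def refine_marker_centers(
    tilt_series: TiltSeries,
    trails: Sequence[MarkerTrail],
    max_iter: int = 5,
    tol: float = 0.05,
) -> list[MarkerTrail]:
    """Iteratively re-center each observation against a per-marker reference.

    Each marker's subimages are averaged into a reference; every
    observation is then re-localized by least-squares registration of its
    local window against that reference (:func:`register_patch`), which
    avoids the pixel-locking bias of correlation-peak interpolation. The
    loop stops after ``max_iter`` passes or when the largest position
    update drops below ``tol`` pixels. Single-observation markers are
    returned unchanged.
    """
    patch_side = 4 * tilt_series.fiducial_radius_px + 1
    out: list[MarkerTrail] = []
    for trail in trails:
        if len(trail) < 2:
            out.append(trail)
            continue
        new_obs = [
            MarkerObservation(o.image_index, o.position_2d.copy(), o.cc_score,
                              trail.marker_id)
            for o in trail.observations
        ]
        for _ in range(max_iter):
            patches = [
                extract_patch(tilt_series.images[o.image_index], o.position_2d,
                              patch_side)
                for o in new_obs
            ]
            # subpixel-align patches on the current estimates before
            # averaging, so the reference is not broadened by the jitter
            # of the integer extraction grid
            aligned = []
            for o, p in zip(new_obs, patches):
                if p is None:
                    continue
                frac = o.position_2d - np.round(o.position_2d)
                aligned.append(
                    np.fft.ifft2(
                        fourier_shift(np.fft.fft2(p), (-frac[1], -frac[0]))
                    ).real
                )
            if len(aligned) < 2:
                break
            reference = np.mean(aligned, axis=0)
            # anchor the reference on the bead's center of mass: without
            # this, a common-mode error in the estimates feeds back into
            # the reference and never decays
            com = _dark_center_of_mass(reference)
            if com is not None:
                c = (patch_side - 1) / 2.0
                reference = np.fft.ifft2(
                    fourier_shift(np.fft.fft2(reference),
                                  (c - com[1], c - com[0]))
                ).real
            max_delta = 0.0
            for o, patch in zip(new_obs, patches):
                if patch is None:
                    continue
                delta = register_patch(patch, reference)
                if not np.all(np.isfinite(delta)):
                    continue
                new_pos = np.round(o.position_2d) + delta
                max_delta = max(
                    max_delta, float(np.linalg.norm(new_pos - o.position_2d))
                )
                o.position_2d = new_pos
            if max_delta < tol:
                break
        out.append(MarkerTrail(observations=new_obs, marker_id=trail.marker_id))
    return out


def merge_close_markers(
    marker_model: Marker3DModel,
    trails: Sequence[MarkerTrail],
    merge_radius_px: float,
) -> tuple[Marker3DModel, list[MarkerTrail]]:
    """Merge markers whose 3D positions coincide within ``merge_radius_px``.

    Trail indexing occasionally splits one physical bead into two partial
    trails; after triangulation these land on (nearly) the same 3D point
    and would bias the model gauge. Clusters are merged into the
    lowest-id marker; where two trails observe the same image, the higher
    scoring observation wins.
    """
    ids = sorted(marker_model.coordinates)
    if not ids:
        return marker_model, list(trails)
    coords = np.array([marker_model.coordinates[m] for m in ids])
    parent = {m: m for m in ids}

    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m

    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            if np.linalg.norm(coords[a] - coords[b]) <= merge_radius_px:
                ra, rb = find(ids[a]), find(ids[b])
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    grouped: dict[int, dict[int, MarkerObservation]] = {}
    for trail in trails:
        if trail.marker_id not in parent:
            continue
        root = find(trail.marker_id)
        slots = grouped.setdefault(root, {})
        for o in trail.observations:
            cur = slots.get(o.image_index)
            if cur is None or o.cc_score > cur.cc_score:
                slots[o.image_index] = o
    merged_trails = []
    merged_model = Marker3DModel()
    for root in sorted(grouped):
        obs = list(grouped[root].values())
        if len(obs) < 2:
            continue
        merged_trails.append(MarkerTrail(observations=obs, marker_id=root))
        merged_model.coordinates[root] = marker_model.coordinates[root].copy()
        merged_model.rmsd[root] = marker_model.rmsd.get(root, 0.0)
    return merged_model, merged_trails
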