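"""Projection model and robust solvers for fiducial-based tilt alignment.

The geometry solved here is the single-axis model: one in-plane tilt-axis
angle psi for the whole series, per-image 2D shifts, and tilt angles fixed
at their nominal (goniometer) values — they are never refined. A 3D marker
``r`` observed in tilt image ``i`` projects to::

    predicted(i, j) = Rot2(psi) @ P @ Ry(theta_i) @ r_j + d_i

where ``P`` is orthographic projection onto (x, y), ``theta_i`` the nominal
tilt, and ``d_i`` the image shift. Coordinates are pixels relative to the
image center; psi is measured counter-clockwise from the image x-axis
toward y (i.e. the standard mathematical angle of the projected rotation
axis).

Because replacing ``(psi, r)`` by ``(psi + 180, -r)`` leaves every
prediction unchanged, the model has an exact twofold degeneracy; solvers
canonicalize psi into [0, 180).

Fitting is a damped Gauss-Newton refinement of all parameters jointly
(the problem is linear in everything but psi), wrapped in iteratively
reweighted least squares with Tukey bisquare weights for robustness to
gross outlier observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "ProjectionModel",
    "Marker3DModel",
    "AlignmentResult",
    "rot2",
    "project_points",
    "triangulate_markers",
    "solve_projection_model",
    "estimate_initial_model",
    "canonicalize",
    "shift_gauge_residuals",
    "TUKEY_C",
]

# standard Tukey bisquare tuning constant (95% efficiency at the normal)
TUKEY_C = 4.685


@dataclass
class ProjectionModel:
    """Single tilt-axis angle (deg), per-image shifts (px), nominal tilts."""

    tilt_axis_angle: float
    shifts: np.ndarray          # (n_img, 2)
    tilt_angles: np.ndarray     # (n_img,) degrees, fixed at nominal values

    def __post_init__(self) -> None:
        self.shifts = np.asarray(self.shifts, dtype=float).reshape(-1, 2)
        self.tilt_angles = np.asarray(self.tilt_angles, dtype=float).reshape(-1)
        if len(self.shifts) != len(self.tilt_angles):
            raise ValueError("one shift per tilt image required")

    @property
    def n_images(self) -> int:
        return len(self.tilt_angles)

    def copy(self) -> "ProjectionModel":
        return ProjectionModel(
            self.tilt_axis_angle, self.shifts.copy(), self.tilt_angles.copy()
        )


@dataclass
class Marker3DModel:
    """3D fiducial coordinates (px, tomogram frame) and per-marker RMSD."""

    coordinates: dict[int, np.ndarray] = field(default_factory=dict)
    rmsd: dict[int, float] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.coordinates)

    def ids(self) -> list[int]:
        return list(self.coordinates)

    def as_array(self, ids: Optional[Iterable[int]] = None) -> np.ndarray:
        ids = self.ids() if ids is None else list(ids)
        return np.array([self.coordinates[i] for i in ids], dtype=float)


@dataclass
class AlignmentResult:
    projection_model: ProjectionModel
    marker_model: Marker3DModel
    residuals: dict[int, np.ndarray]     # marker id -> (k,) residual norms
    pruned_marker_ids: list[int] = field(default_factory=list)

    @property
    def global_rmsd(self) -> float:
        all_res = np.concatenate([v for v in self.residuals.values()]) if self.residuals else np.array([0.0])
        return float(np.sqrt(np.mean(all_res**2)))


def rot2(psi_deg: float) -> np.ndarray:
    """2x2 CCW rotation."""
    c, s = np.cos(np.deg2rad(psi_deg)), np.sin(np.deg2rad(psi_deg))
    return np.array([[c, -s], [s, c]])


def _tilt_rows(tilt_deg: np.ndarray) -> np.ndarray:
    """(n, 2, 3) matrices P @ Ry(theta) mapping 3D points to unrotated 2D."""
    t = np.deg2rad(np.asarray(tilt_deg, dtype=float))
    a = np.zeros((len(t), 2, 3))
    a[:, 0, 0] = np.cos(t)
    a[:, 0, 2] = np.sin(t)
    a[:, 1, 1] = 1.0
    return a


def project_points(model: ProjectionModel, points: np.ndarray) -> np.ndarray:
    """Predicted center-relative 2D positions, shape (n_img, n_points, 2)."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    a = _tilt_rows(model.tilt_angles)                     # (n, 2, 3)
    q = np.einsum("nij,mj->nmi", a, points)               # (n, m, 2)
    r = rot2(model.tilt_axis_angle)
    return np.einsum("ij,nmj->nmi", r, q) + model.shifts[:, None, :]


def _gather(trails) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten trails to (image_index, marker_id, observed xy) arrays."""
    img, mid, xy = [], [], []
    for trail in trails:
        for obs in trail.observations:
            img.append(obs.image_index)
            mid.append(trail.marker_id)
            xy.append(obs.position_2d)
    return (
        np.asarray(img, dtype=int),
        np.asarray(mid, dtype=int),
        np.asarray(xy, dtype=float).reshape(-1, 2),
    )


def triangulate_markers(
    trails,
    model: ProjectionModel,
    weights: Optional[np.ndarray] = None,
) -> Marker3DModel:
    """Per-marker linear least-squares 3D positions under a fixed model.

    Each observation contributes two rows ``P Ry(theta) r = Rot2(-psi) (p - d)``.
    Markers observed in fewer than two distinct tilts (rank-deficient) are
    skipped.
    """
    img, mid, xy = _gather(trails)
    if len(img) == 0:
        return Marker3DModel()
    rinv = rot2(-model.tilt_axis_angle)
    rows = _tilt_rows(model.tilt_angles)                  # per image (2, 3)
    rhs_all = np.einsum("ij,nj->ni", rinv, xy - model.shifts[img])
    w = np.ones(len(img)) if weights is None else np.asarray(weights, dtype=float)

    out = Marker3DModel()
    for marker in np.unique(mid):
        sel = mid == marker
        if len(np.unique(np.round(model.tilt_angles[img[sel]], 9))) < 2:
            continue
        a = rows[img[sel]].reshape(-1, 3)                 # (2k, 3)
        b = rhs_all[sel].reshape(-1)
        ww = np.repeat(np.sqrt(np.maximum(w[sel], 1e-12)), 2)
        sol, *_ = np.linalg.lstsq(a * ww[:, None], b * ww, rcond=None)
        out.coordinates[int(marker)] = sol
        pred = (rows[img[sel]] @ sol)
        res = np.linalg.norm(rhs_all[sel] - pred, axis=1)
        out.rmsd[int(marker)] = float(np.sqrt(np.mean(res**2)))
    return out


def residual_norms(
    trails, model: ProjectionModel, markers: Marker3DModel
) -> dict[int, np.ndarray]:
    """Per-marker observation residual norms (px) under a model."""
    out: dict[int, np.ndarray] = {}
    for trail in trails:
        if trail.marker_id not in markers.coordinates:
            continue
        r = markers.coordinates[trail.marker_id]
        img = np.array([o.image_index for o in trail.observations])
        xy = np.array([o.position_2d for o in trail.observations])
        pred = np.einsum(
            "ij,nj->ni", rot2(model.tilt_axis_angle),
            np.einsum("nij,j->ni", _tilt_rows(model.tilt_angles[img]), r),
        ) + model.shifts[img]
        out[trail.marker_id] = np.linalg.norm(xy - pred, axis=1)
    return out


def _tukey_weights(res: np.ndarray) -> np.ndarray:
    scale = 1.4826 * np.median(np.abs(res - np.median(res)))
    scale = max(scale, 1e-8)
    u = res / (TUKEY_C * scale)
    w = (1.0 - u**2) ** 2
    w[np.abs(u) >= 1.0] = 0.0
    return w


def solve_projection_model(
    trails,
    marker_model: Marker3DModel,
    tilt_series,
    robust: bool = True,
    initial: Optional[ProjectionModel] = None,
    max_iter: int = 50,
    tol: float = 1e-4,
) -> tuple[ProjectionModel, Marker3DModel]:
    """Joint Gauss-Newton refinement of psi, shifts and markers with IRLS.

    All parameters of the projection model (the shared tilt-axis angle,
    the per-image shifts, and the 3D marker positions) are refined
    simultaneously; the problem is linear in everything but psi, so a few
    damped Gauss-Newton steps converge to machine precision. When
    ``robust``, Tukey bisquare weights on the observation residual norms
    (rescaled by the normalized MAD each iteration) suppress gross
    outliers. Nominal tilt angles are copied through untouched. The
    returned model is canonicalized to psi in [0, 180) with zero-mean
    markers.
    """
    tilt_angles = np.asarray(tilt_series.nominal_tilt_angles, dtype=float)
    n_images = len(tilt_angles)
    marker_ids = sorted(
        set(marker_model.coordinates) & {t.marker_id for t in trails}
    )
    used = [t for t in trails if t.marker_id in marker_ids]
    img, mid, xy = _gather(used)
    if len(used) < 3 or len(np.unique(img)) < 3:
        raise ValueError(
            "solving the projection model requires >= 3 markers observed in "
            ">= 3 tilt images"
        )
    m_index = {m: k for k, m in enumerate(marker_ids)}
    midx = np.array([m_index[m] for m in mid])
    n_mark = len(marker_ids)
    n_obs = len(img)

    psi = float(initial.tilt_axis_angle) if initial is not None else 0.0
    shifts = (
        np.asarray(initial.shifts, dtype=float).copy()
        if initial is not None
        else np.zeros((n_images, 2))
    )
    coords = np.array([marker_model.coordinates[m] for m in marker_ids], dtype=float)
    rows = _tilt_rows(tilt_angles)

    def residuals(psi_, shifts_, coords_):
        q = np.einsum("nij,nj->ni", rows[img], coords_[midx])
        pred = np.einsum("ij,nj->ni", rot2(psi_), q) + shifts_[img]
        return xy - pred, q

    w = np.ones(n_obs)
    prev_obj = np.inf
    for _ in range(max_iter):
        res, q = residuals(psi, shifts, coords)
        norms = np.linalg.norm(res, axis=1)
        if robust:
            w = _tukey_weights(norms)
            if w.sum() < 4:            # scale collapse: keep the best half
                w = (norms <= np.median(norms)).astype(float)
        obj = float(np.average(norms, weights=np.maximum(w, 1e-12)))

        # Gauss-Newton step on (psi, shifts, markers)
        psi_rad = np.deg2rad(psi)
        dr = np.array(
            [[-np.sin(psi_rad), -np.cos(psi_rad)],
             [np.cos(psi_rad), -np.sin(psi_rad)]]
        )
        jac = np.zeros((2 * n_obs, 1 + 2 * n_images + 3 * n_mark))
        rhs = res.reshape(-1)
        jac[0::2, 0] = np.einsum("ij,nj->ni", dr, q)[:, 0]
        jac[1::2, 0] = np.einsum("ij,nj->ni", dr, q)[:, 1]
        obs_idx = np.arange(n_obs)
        jac[2 * obs_idx, 1 + 2 * img] = 1.0
        jac[2 * obs_idx + 1, 1 + 2 * img + 1] = 1.0
        ra = np.einsum("ij,njk->nik", rot2(psi), rows[img])   # (n, 2, 3)
        for a in range(2):
            for b in range(3):
                jac[2 * obs_idx + a, 1 + 2 * n_images + 3 * midx + b] = ra[:, a, b]
        sw = np.repeat(np.sqrt(np.maximum(w, 1e-12)), 2)
        upd, *_ = np.linalg.lstsq(jac * sw[:, None], rhs * sw, rcond=None)

        psi_new = psi + np.rad2deg(upd[0])
        shifts_new = shifts + upd[1 : 1 + 2 * n_images].reshape(n_images, 2)
        coords_new = coords + upd[1 + 2 * n_images :].reshape(n_mark, 3)
        res_new, _ = residuals(psi_new, shifts_new, coords_new)
        norms_new = np.linalg.norm(res_new, axis=1)
        obj_new = float(np.average(norms_new, weights=np.maximum(w, 1e-12)))
        if obj_new > obj:              # damp on overshoot
            for _damp in range(8):
                upd *= 0.5
                psi_new = psi + np.rad2deg(upd[0])
                shifts_new = shifts + upd[1 : 1 + 2 * n_images].reshape(n_images, 2)
                coords_new = coords + upd[1 + 2 * n_images :].reshape(n_mark, 3)
                res_new, _ = residuals(psi_new, shifts_new, coords_new)
                norms_new = np.linalg.norm(res_new, axis=1)
                obj_new = float(np.average(norms_new, weights=np.maximum(w, 1e-12)))
                if obj_new <= obj:
                    break
        psi, shifts, coords = psi_new, shifts_new, coords_new
        if abs(prev_obj - obj_new) < tol and np.abs(upd).max() < 1e-6:
            break
        prev_obj = obj_new

    model = ProjectionModel(psi, shifts, tilt_angles)
    markers = Marker3DModel(
        coordinates={m: coords[m_index[m]] for m in marker_ids},
    )
    res, _ = residuals(psi, shifts, coords)
    norms = np.linalg.norm(res, axis=1)
    for m in marker_ids:
        sel = mid == m
        markers.rmsd[m] = float(np.sqrt(np.mean(norms[sel] ** 2)))
    model, markers = canonicalize(model, markers)
    return model, markers


def shift_gauge_residuals(
    estimated: ProjectionModel, reference: ProjectionModel
) -> np.ndarray:
    """Per-image shift differences after removing the marker-centroid gauge.

    Shifts are only defined up to the equivalence
    ``(r, d) ~ (r + c, d - Rot2(psi) P Ry(theta) c)``: two solutions whose
    marker sets differ (e.g. one bead missed) sit in different gauges even
    when they describe identical projections. This fits the single 3D
    gauge vector ``c`` that best explains the shift difference and returns
    the per-image residual norms, which compare the models fairly.
    """
    if estimated.n_images != reference.n_images:
        raise ValueError("models describe different numbers of images")
    diff = estimated.shifts - reference.shifts            # (n, 2)
    basis = np.einsum(
        "ij,njk->nik", rot2(estimated.tilt_axis_angle),
        _tilt_rows(estimated.tilt_angles),
    )                                                      # (n, 2, 3)
    a = basis.reshape(-1, 3)
    c, *_ = np.linalg.lstsq(a, diff.reshape(-1), rcond=None)
    residual = diff - np.einsum("nij,j->ni", basis, c)
    return np.linalg.norm(residual, axis=1)


def canonicalize(
    model: ProjectionModel, markers: Marker3DModel
) -> tuple[ProjectionModel, Marker3DModel]:
    """Fix the model gauge: psi in [0, 180), markers centered at the origin.

    Uses the exact equivalences (psi, r) ~ (psi + 180, -r) and
    (r, d) ~ (r + c, d - Rot2(psi) P Ry(theta) c).
    """
    psi = float(np.mod(model.tilt_axis_angle, 360.0))
    coords = {k: v.copy() for k, v in markers.coordinates.items()}
    flip = False
    if psi >= 180.0:
        psi -= 180.0
        flip = True
    shifts = model.shifts.copy()
    if coords:
        arr = np.array(list(coords.values()))
        if flip:
            arr = -arr
        mean = arr.mean(axis=0)
        arr -= mean
        # fold the centroid into the shifts so predictions are unchanged
        comp = np.einsum(
            "ij,nj->ni", rot2(psi), _tilt_rows(model.tilt_angles) @ mean
        )
        shifts = shifts + comp
        coords = {k: a for k, a in zip(coords, arr)}
    out_model = ProjectionModel(psi, shifts, model.tilt_angles.copy())
    return out_model, Marker3DModel(coords, dict(markers.rmsd))


def estimate_initial_model(
    trails,
    tilt_series,
    psi_step: float = 3.0,
    refine_rounds: int = 4,
) -> tuple[ProjectionModel, Marker3DModel]:
    """Coarse grid search over the tilt-axis angle to seed the solver.

    For each candidate psi in [0, 180) the markers and shifts are fitted by
    a few alternating linear steps; the psi with the lowest residual wins.
    """
    tilt_angles = np.asarray(tilt_series.nominal_tilt_angles, dtype=float)
    n_images = len(tilt_angles)
    img, mid, xy = _gather(trails)
    if len(img) == 0:
        raise ValueError("no observations to estimate a model from")
    rows = _tilt_rows(tilt_angles)

    best = (np.inf, None, None)
    for psi0 in np.arange(0.0, 180.0, psi_step):
        model = ProjectionModel(psi0, np.zeros((n_images, 2)), tilt_angles)
        markers = triangulate_markers(trails, model)
        ok = np.array([m in markers.coordinates for m in mid])
        if ok.sum() < 6:
            continue
        for _ in range(refine_rounds):
            coords = np.array(
                [markers.coordinates[m] for m in mid[ok]]
            )
            q = np.einsum("nij,nj->ni", rows[img[ok]], coords)
            # shifts only; psi stays on the grid point during the scan
            r = rot2(model.tilt_axis_angle)
            pr = np.einsum("ij,nj->ni", r, q)
            sums = np.zeros((n_images, 1))
            np.add.at(sums, img[ok], np.ones((ok.sum(), 1)))
            sums = np.maximum(sums, 1e-12)
            mean_d = np.zeros((n_images, 2))
            np.add.at(mean_d, img[ok], xy[ok] - pr)
            model = ProjectionModel(
                model.tilt_axis_angle, mean_d / sums, tilt_angles
            )
            markers = triangulate_markers(trails, model)
            ok = np.array([m in markers.coordinates for m in mid])
        coords = np.array([markers.coordinates[m] for m in mid[ok]])
        pred = np.einsum(
            "ij,nj->ni",
            rot2(model.tilt_axis_angle),
            np.einsum("nij,nj->ni", rows[img[ok]], coords),
        ) + model.shifts[img[ok]]
        res = np.linalg.norm(xy[ok] - pred, axis=1)
        obj = float(np.median(res))
        if obj < best[0]:
            best = (obj, model, markers)
    if best[1] is None:
        raise ValueError("initial model estimation failed: too few usable markers")
    return best[1], best[2]
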