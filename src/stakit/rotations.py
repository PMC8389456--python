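"""Batch conversion between Euler angles and rotation matrices under any
right-handed convention.

Cryo-EM packages disagree on what an Euler triplet means. A convention here
is fully specified by four choices (:class:`EulerConvention`):

* ``axes`` — the three rotation axes, e.g. ``"zyz"`` (proper Euler) or
  ``"zyx"`` (Tait-Bryan); 12 valid strings exist.
* ``intrinsic`` — axes rotate with the body (intrinsic) or stay fixed in
  the world (extrinsic).
* ``positive_ccw`` — a positive angle is counter-clockwise looking down
  the axis toward the origin.
* ``rotates_reference`` — the triplet rotates the reference onto the
  particle, or the particle onto the reference (the transpose).

Matrices are active rotations acting on column vectors in a right-handed
world frame. Angles cross the API boundary in degrees, matching RELION and
Dynamo metadata files. All operations are vectorized over ``(n, 3)`` angle
arrays and ``(n, 3, 3)`` matrix stacks.

The registry ships the two presets this package needs for interchange:
``"relion"`` (zyz, intrinsic, ccw, reference -> particle) and ``"dynamo"``
(zxz, extrinsic, ccw, particle -> reference).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EulerConvention",
    "CONVENTIONS",
    "get_convention",
    "axis_rotation",
    "euler_to_matrix",
    "matrix_to_euler",
    "convert_eulers",
]

_AXES = {"x": 0, "y": 1, "z": 2}

#: all valid 3-axis strings (no two consecutive axes equal)
VALID_AXIS_STRINGS = tuple(
    a + b + c
    for a in "xyz" for b in "xyz" for c in "xyz"
    if a != b and b != c
)

# middle angle within this many degrees of a degenerate value is treated
# as gimbal-locked: the third angle is set to 0 and the first absorbs the
# free sum/difference
GIMBAL_TOL_DEG = 1e-6


@dataclass(frozen=True)
class EulerConvention:
    """Declarative description of one Euler-angle formulation."""

    axes: str
    intrinsic: bool = True
    positive_ccw: bool = True
    rotates_reference: bool = True

    def __post_init__(self) -> None:
        if self.axes not in VALID_AXIS_STRINGS:
            raise ValueError(
                f"invalid axis string {self.axes!r}; must be one of the 12 "
                "three-letter combinations over xyz with no repeat neighbours"
            )

    @property
    def is_proper(self) -> bool:
        """True for proper-Euler axes (first == third, e.g. zxz)."""
        return self.axes[0] == self.axes[2]


CONVENTIONS: dict[str, EulerConvention] = {
    "relion": EulerConvention("zyz", intrinsic=True, positive_ccw=True,
                              rotates_reference=True),
    "dynamo": EulerConvention("zxz", intrinsic=False, positive_ccw=True,
                              rotates_reference=False),
}


def get_convention(conv: "EulerConvention | str") -> EulerConvention:
    if isinstance(conv, EulerConvention):
        return conv
    try:
        return CONVENTIONS[conv]
    except KeyError:
        raise KeyError(
            f"unknown convention {conv!r}; registered: {sorted(CONVENTIONS)}"
        ) from None


def axis_rotation(axis: str, angles, positive_ccw: bool = True) -> np.ndarray:
    """Elementary active rotation matrices about x, y or z.

    Parameters
    ----------
    axis : one of "x", "y", "z"
    angles : scalar or (n,) array, degrees
    positive_ccw : if False the angle sense is clockwise (angles negated)

    Returns
    -------
    (n, 3, 3) array (n = 1 for scalar input)
    """
    if axis not in _AXES:
        raise ValueError(f"invalid axis {axis!r}; expected one of x, y, z")
    ang = np.atleast_1d(np.asarray(angles, dtype=float))
    if not np.all(np.isfinite(ang)):
        raise ValueError("non-finite angles")
    if not positive_ccw:
        ang = -ang
    return _elementary(_AXES[axis], np.deg2rad(ang))


def _elementary(axis_index: int, angles_rad: np.ndarray) -> np.ndarray:
    """(n, 3, 3) CCW active rotations about a coordinate axis (radians)."""
    n = angles_rad.shape[0]
    c, s = np.cos(angles_rad), np.sin(angles_rad)
    m = np.zeros((n, 3, 3))
    i = axis_index
    j, k = (i + 1) % 3, (i + 2) % 3
    m[:, i, i] = 1.0
    m[:, j, j] = c
    m[:, k, k] = c
    m[:, k, j] = s
    m[:, j, k] = -s
    return m


def euler_to_matrix(conv: "EulerConvention | str", triplets) -> np.ndarray:
    """Convert (n, 3) Euler triplets (degrees) to (n, 3, 3) matrices.

    Intrinsic composition is R(axis1) @ R(axis2) @ R(axis3); extrinsic is
    the reverse order. Conventions with ``rotates_reference=False`` return
    the transpose of the reference-rotating matrix.
    """
    conv = get_convention(conv)
    ang = np.atleast_2d(np.asarray(triplets, dtype=float))
    if ang.ndim != 2 or ang.shape[1] != 3:
        raise ValueError(f"expected (n, 3) angles, got shape {ang.shape}")
    bad = ~np.all(np.isfinite(ang), axis=1)
    if np.any(bad):
        raise ValueError(f"non-finite angles at indices {np.nonzero(bad)[0].tolist()}")
    if not conv.positive_ccw:
        ang = -ang
    rad = np.deg2rad(ang)
    mats = [_elementary(_AXES[a], rad[:, i]) for i, a in enumerate(conv.axes)]
    if conv.intrinsic:
        out = mats[0] @ mats[1] @ mats[2]
    else:
        out = mats[2] @ mats[1] @ mats[0]
    if not conv.rotates_reference:
        out = np.transpose(out, (0, 2, 1))
    return out


def _check_rotation_matrices(m: np.ndarray, tol: float = 1e-6) -> None:
    eye = np.eye(3)
    defect = np.abs(np.transpose(m, (0, 2, 1)) @ m - eye).max(axis=(1, 2))
    det = np.linalg.det(m)
    bad = (defect > tol) | (np.abs(det - 1.0) > tol)
    if np.any(bad):
        idx = np.nonzero(bad)[0]
        raise ValueError(
            f"matrices at indices {idx.tolist()} are not proper rotations "
            f"(orthonormality defect up to {defect[idx].max():.2e})"
        )


def _extract_single_axis_angle(q: np.ndarray, axis: int) -> np.ndarray:
    """Angle (rad) of near-single-axis rotations about ``axis``."""
    e = np.eye(3)
    j = (axis + 1) % 3
    l = 3 - axis - j
    rho = float(np.cross(e[axis], e[j])[l])
    return np.arctan2(rho * q[:, l, j], q[:, j, j])


def _intrinsic_ccw_angles(m: np.ndarray, axes: str) -> np.ndarray:
    """Solve R = R1(a) @ R2(b) @ R3(c) for (a, b, c) in radians.

    Proper-Euler middle angle lands in [0, pi]; Tait-Bryan in
    [-pi/2, pi/2]. Near gimbal lock the third angle is set to 0.
    """
    e = np.eye(3)
    i, j, k = (_AXES[a] for a in axes)
    n = m.shape[0]
    out = np.empty((n, 3))
    sin_tol = np.sin(np.deg2rad(GIMBAL_TOL_DEG))

    if i == k:  # proper Euler
        l = 3 - i - j
        sigma = float(np.cross(e[j], e[i])[l])
        tau = float(np.cross(e[i], e[l])[j])
        b = np.arccos(np.clip(m[:, i, i], -1.0, 1.0))
        locked = np.abs(np.sin(b)) < sin_tol
        a = np.arctan2(sigma * tau * m[:, j, i], sigma * m[:, l, i])
        c = np.arctan2(sigma * tau * m[:, i, j], -sigma * m[:, i, l])
    else:  # Tait-Bryan
        mu = float(np.cross(e[j], e[k])[i])
        nu = float(np.cross(e[i], e[k])[j])
        b = np.arcsin(np.clip(mu * m[:, i, k], -1.0, 1.0))
        locked = np.abs(np.cos(b)) < sin_tol
        a = np.arctan2(nu * m[:, j, k], m[:, k, k])
        c = np.arctan2(nu * m[:, i, j], m[:, i, i])

    if np.any(locked):
        # with the first and third axes coaxial only a +/- c is determined;
        # put it all in the first angle
        sub = np.nonzero(locked)[0]
        b_lock = b[sub]
        r2 = _elementary(j, b_lock)
        q = m[sub] @ np.transpose(r2, (0, 2, 1))
        a_lock = _extract_single_axis_angle(q, i)
        a[sub] = a_lock
        c[sub] = 0.0
    out[:, 0], out[:, 1], out[:, 2] = a, b, c
    return out


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    """Wrap to (-180, 180]."""
    w = np.mod(a, 360.0)
    w[w > 180.0] -= 360.0
    w[w == -180.0] = 180.0
    return w


def matrix_to_euler(conv: "EulerConvention | str", matrices) -> np.ndarray:
    """Convert (n, 3, 3) rotation matrices to (n, 3) Euler angles (degrees).

    The returned triplets reproduce the input matrices under
    :func:`euler_to_matrix` (the matrix, not the triplet, is the contract:
    at gimbal lock many triplets encode one matrix). The middle angle is
    returned in [0, 180] for proper-Euler axes and [-90, 90] for
    Tait-Bryan axes.
    """
    conv = get_convention(conv)
    m = np.asarray(matrices, dtype=float)
    if m.ndim == 2:
        m = m[None]
    if m.ndim != 3 or m.shape[1:] != (3, 3):
        raise ValueError(f"expected (n, 3, 3) matrices, got shape {m.shape}")
    _check_rotation_matrices(m)

    m_eff = m if conv.rotates_reference else np.transpose(m, (0, 2, 1))
    axes_eff = conv.axes if conv.intrinsic else conv.axes[::-1]
    trip = np.rad2deg(_intrinsic_ccw_angles(m_eff, axes_eff))
    if not conv.intrinsic:
        trip = trip[:, ::-1]
    if not conv.positive_ccw:
        trip = -trip
    trip = _wrap_deg(trip)

    # canonical middle-angle branch; flipping branch preserves the matrix
    mid = trip[:, 1]
    if conv.is_proper:
        flip = mid < 0.0
    else:
        flip = np.abs(mid) > 90.0
    if np.any(flip):
        t = trip[flip]
        if conv.is_proper:
            t = np.column_stack([t[:, 0] + 180.0, -t[:, 1], t[:, 2] + 180.0])
        else:
            t = np.column_stack([t[:, 0] + 180.0, 180.0 - t[:, 1], t[:, 2] + 180.0])
        trip[flip] = _wrap_deg(t)

    trip = _normalize_gimbal(conv, trip, m)
    return _wrap_deg(trip)


def _normalize_gimbal(
    conv: EulerConvention, trip: np.ndarray, m: np.ndarray
) -> np.ndarray:
    """At gimbal lock force third angle to 0, first absorbing the freedom."""
    mid = trip[:, 1]
    if conv.is_proper:
        locked = np.minimum(np.abs(_wrap_deg(mid)), np.abs(180.0 - np.abs(_wrap_deg(mid))))
        locked = locked < GIMBAL_TOL_DEG
    else:
        locked = np.abs(np.abs(_wrap_deg(mid)) - 90.0) < GIMBAL_TOL_DEG
    locked &= np.abs(trip[:, 2]) > 0.0
    if not np.any(locked):
        return trip
    sub = np.nonzero(locked)[0]
    t = trip[sub]
    # the free angle enters as first +/- third depending on axes and branch;
    # try both signs and keep whichever reproduces the matrix
    cand_plus = np.column_stack([t[:, 0] + t[:, 2], t[:, 1], np.zeros(len(sub))])
    cand_minus = np.column_stack([t[:, 0] - t[:, 2], t[:, 1], np.zeros(len(sub))])
    err_plus = _reproduction_error(conv, cand_plus, m[sub])
    err_minus = _reproduction_error(conv, cand_minus, m[sub])
    choice = np.where((err_plus <= err_minus)[:, None], cand_plus, cand_minus)
    trip[sub] = choice
    return trip


def _reproduction_error(
    conv: EulerConvention, trip: np.ndarray, m: np.ndarray
) -> np.ndarray:
    r = euler_to_matrix(conv, trip)
    return np.abs(r - m).max(axis=(1, 2))


def convert_eulers(
    src: "EulerConvention | str", dst: "EulerConvention | str", triplets
) -> np.ndarray:
    """Re-express Euler triplets from one convention in another.

    The underlying rotation matrices are preserved exactly (including
    across ``rotates_reference`` mismatches, where a transpose is
    inserted); the numeric triplets generally differ.
    """
    return matrix_to_euler(dst, euler_to_matrix(src, triplets))
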