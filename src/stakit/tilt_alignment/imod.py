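"""IMOD-compatible alignment output (.xf transform and .tlt angle files)."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np

from .model import AlignmentResult, rot2

__all__ = ["write_imod_alignment", "xf_matrix"]


def xf_matrix(tilt_axis_angle: float, shift: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 matrix A and translation t of the aligning transform.

    The transform undoes the solved in-plane rotation and shift, i.e. for
    a center-relative image point p it evaluates A @ p + t with
    A = Rot2(-psi) and t = -A @ d, mapping measured positions back onto
    the unrotated projection frame.
    """
    a = rot2(-tilt_axis_angle)
    t = -a @ np.asarray(shift, dtype=float)
    return a, t


def write_imod_alignment(
    result: AlignmentResult,
    xf_path: Union[str, Path],
    tlt_path: Union[str, Path],
) -> None:
    """Write the .xf (6 floats per image) and .tlt (one angle per line).

    Nominal tilt angles pass through bit-identically: the .tlt file is
    formatted from the exact input values, never from refined ones.
    """
    model = result.projection_model
    xf_lines = []
    for shift in model.shifts:
        a, t = xf_matrix(model.tilt_axis_angle, shift)
        xf_lines.append(
            f"{a[0, 0]:12.7f}{a[0, 1]:12.7f}{a[1, 0]:12.7f}{a[1, 1]:12.7f}"
            f"{t[0]:12.3f}{t[1]:12.3f}"
        )
    Path(xf_path).write_text("\n".join(xf_lines) + "\n", encoding="utf-8")
    tlt_lines = [repr(float(angle)) for angle in model.tilt_angles]
    Path(tlt_path).write_text("\n".join(tlt_lines) + "\n", encoding="utf-8")
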