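"""Gold-bead detection: templates, normalized cross-correlation, peaks.

Detection proceeds in two passes. A binary synthetic disc matching the
bead contrast (dark on neutral) finds first candidates; subimages at the
strongest peaks are averaged into a data-derived template which drives a
second, cleaner pass. A rotational-symmetry statistic then discards
peaks caused by straight edges (carbon film, ice cracks), which correlate
poorly with their own 90-degree rotations.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import fourier_shift, gaussian_filter, maximum_filter
from skimage.feature import match_template

from .series import MarkerObservation, TiltSeries

__all__ = [
    "synthetic_bead_template",
    "detect_candidates",
    "build_data_template",
    "rotational_symmetry_filter",
    "extract_patch",
    "parabolic_subpixel",
    "register_patch",
]


def synthetic_bead_template(radius_px: int) -> np.ndarray:
    """Binary dark disc of the given radius on a neutral background.

    The side length is ``4 * radius + 1`` so the template carries enough
    background for normalized correlation to be discriminative.
    """
    if radius_px < 1:
        raise ValueError("bead radius must be >= 1 px")
    r = int(radius_px)
    side = 4 * r + 1
    yy, xx = np.mgrid[:side, :side] - (side - 1) / 2.0
    template = np.zeros((side, side))
    template[xx**2 + yy**2 <= r**2] = -1.0
    return template


def parabolic_subpixel(score_map: np.ndarray, peak_rc: tuple[int, int]) -> np.ndarray:
    """3-point parabolic interpolation of a correlation peak.

    Returns the (x, y) peak position with subpixel refinement along each
    axis independently; peaks on the map border are returned unrefined.
    """
    r, c = peak_rc
    h, w = score_map.shape
    dr = dc = 0.0
    if 0 < r < h - 1:
        denom = score_map[r - 1, c] - 2 * score_map[r, c] + score_map[r + 1, c]
        if denom < 0:
            dr = 0.5 * (score_map[r - 1, c] - score_map[r + 1, c]) / denom
            dr = float(np.clip(dr, -0.5, 0.5))
    if 0 < c < w - 1:
        denom = score_map[r, c - 1] - 2 * score_map[r, c] + score_map[r, c + 1]
        if denom < 0:
            dc = 0.5 * (score_map[r, c - 1] - score_map[r, c + 1]) / denom
            dc = float(np.clip(dc, -0.5, 0.5))
    return np.array([c + dc, r + dr])


def register_patch(
    window: np.ndarray,
    reference: np.ndarray,
    max_iter: int = 12,
    crop: int = 3,
    max_step: float = 1.5,
    tol: float = 1e-3,
) -> np.ndarray:
    """Subpixel (dx, dy) such that the shifted reference matches the window.

    Gauss-Newton least squares on ``window ~ a * shift(reference, d) + b``
    with Fourier-domain shifts and spectral derivatives. Unlike parabolic
    interpolation of a correlation peak, this estimator has no
    pixel-locking bias for wide, flat-topped bead correlations; with white
    noise it is the maximum-likelihood translation. A ``crop`` border is
    ignored to suppress wrap-around artifacts of the periodic shift.
    """

    if window.shape != reference.shape:
        raise ValueError("window and reference must have equal shape")
    delta = np.zeros(2)
    f = np.fft.fft2(reference)
    n0, n1 = reference.shape
    ky = 2j * np.pi * np.fft.fftfreq(n0)[:, None]
    kx = 2j * np.pi * np.fft.fftfreq(n1)[None, :]
    sl = (slice(crop, -crop), slice(crop, -crop)) if crop else (slice(None), slice(None))
    for _ in range(max_iter):
        fs = fourier_shift(f, (delta[1], delta[0]))
        rs = np.fft.ifft2(fs).real
        gx = np.fft.ifft2(fs * kx).real
        gy = np.fft.ifft2(fs * ky).real
        w, r = window[sl], rs[sl]
        basis = np.column_stack([r.ravel(), np.ones(r.size)])
        (a, b), *_ = np.linalg.lstsq(basis, w.ravel(), rcond=None)
        if a <= 0:
            a = 1.0
        res = (w - a * r - b).ravel()
        jac = np.column_stack([-a * gx[sl].ravel(), -a * gy[sl].ravel()])
        upd, *_ = np.linalg.lstsq(jac, res, rcond=None)
        norm = float(np.linalg.norm(upd))
        if norm > max_step:
            upd *= max_step / norm
        delta += upd
        if norm < tol:
            break
    return delta


def detect_candidates(
    image: np.ndarray,
    template: np.ndarray,
    n_peaks: int = 50,
    exclusion_radius: Optional[float] = None,
    image_index: int = 0,
    min_score: float = 0.0,
) -> list[MarkerObservation]:
    """Peaks of the normalized cross-correlation of image and template.

    Up to ``n_peaks`` local maxima are returned greedily, strongest first,
    suppressing anything within ``exclusion_radius`` (default one template
    width) of an accepted peak. A flat image yields no observations.
    Positions are subpixel-refined by parabolic interpolation.
    """
    if template.shape[0] >= image.shape[0] or template.shape[1] >= image.shape[1]:
        raise ValueError("template must be smaller than the image")
    if np.ptp(image) == 0:
        return []
    if exclusion_radius is None:
        exclusion_radius = float(template.shape[0])
    ncc = match_template(image, template, pad_input=True, mode="reflect")
    # local maxima within the exclusion footprint
    size = max(3, int(exclusion_radius) | 1)
    local_max = ncc == maximum_filter(ncc, size=size, mode="nearest")
    rr, cc = np.nonzero(local_max & (ncc > min_score))
    if len(rr) == 0:
        return []
    order = np.argsort(ncc[rr, cc])[::-1]
    rr, cc = rr[order], cc[order]
    accepted: list[MarkerObservation] = []
    accepted_rc: list[tuple[int, int]] = []
    excl2 = exclusion_radius**2
    for r, c in zip(rr, cc):
        if any((r - ar) ** 2 + (c - ac) ** 2 < excl2 for ar, ac in accepted_rc):
            continue
        accepted_rc.append((r, c))
        accepted.append(
            MarkerObservation(
                image_index=image_index,
                position_2d=parabolic_subpixel(ncc, (r, c)),
                cc_score=float(ncc[r, c]),
            )
        )
        if len(accepted) >= n_peaks:
            break
    return accepted


def extract_patch(
    image: np.ndarray, center_xy: np.ndarray, side: int
) -> Optional[np.ndarray]:
    """Square patch around a (x, y) position, or None if it leaves the image."""
    x, y = int(round(center_xy[0])), int(round(center_xy[1]))
    half = side // 2
    if y - half < 0 or x - half < 0 or y + half + 1 > image.shape[0] or x + half + 1 > image.shape[1]:
        return None
    return image[y - half : y + half + 1, x - half : x + half + 1]


def build_data_template(
    tilt_series: TiltSeries,
    candidates: Sequence[MarkerObservation],
    template_side: int,
    n_subimages: int = 300,
) -> np.ndarray:
    """Average of the highest-scoring candidate subimages.

    Up to ``n_subimages`` (300 by default) subimages are extracted at the
    strongest correlation peaks and averaged into a second-pass template
    that looks like the beads actually present in the data.
    """
    if not candidates:
        raise ValueError("need at least one candidate to build a data template")
    ranked = sorted(candidates, key=lambda o: -o.cc_score)
    patches = []
    for obs in ranked:
        patch = extract_patch(
            tilt_series.images[obs.image_index], obs.position_2d, template_side
        )
        if patch is not None:
            patches.append(patch)
        if len(patches) >= n_subimages:
            break
    if not patches:
        raise ValueError("no candidate subimage lies fully inside its image")
    return np.mean(patches, axis=0)


def rotational_symmetry_filter(
    observations: Sequence[MarkerObservation],
    subimages: Sequence[np.ndarray],
    threshold: float = 0.4,
    smooth_sigma: Optional[float] = None,
) -> list[MarkerObservation]:
    """Keep observations whose subimage is rotationally symmetric.

    The statistic is the mean Pearson correlation of each subimage with
    its own 90/180/270-degree rotations; beads are close to fourfold
    symmetric while straight-edge artifacts anticorrelate. ``threshold``
    of -1 retains everything. ``smooth_sigma`` optionally low-passes the
    subimages first, which stabilizes the statistic at low SNR.
    """
    if len(observations) != len(subimages):
        raise ValueError("one subimage per observation required")
    kept = []
    for obs, patch in zip(observations, subimages):
        if patch is None:
            continue
        p = gaussian_filter(patch, smooth_sigma) if smooth_sigma else patch
        p = p - p.mean()
        denom = np.sqrt((p**2).sum())
        if denom == 0:
            continue
        corr = []
        for k in (1, 2, 3):
            q = np.rot90(p, k)
            corr.append((p * q).sum() / denom**2)
        if float(np.mean(corr)) >= threshold:
            kept.append(obs)
    return kept
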