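"""Batch and watch-folder alignment: a thin poller over the pipeline.

On-the-fly processing during data collection is just "align every new
tilt series that appears in a directory". A series is a stack file
(``.npy``/``.npz``/``.tif``) with a sibling ``.tlt`` holding nominal
tilt angles; results land next to it and a processed series is skipped
on later passes.
"""

from __future__ import annotations

import time
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .pipeline import AlignmentParams, align_tilt_series, write_report
from .series import TiltSeries

__all__ = ["find_unprocessed_series", "align_directory", "watch_directory"]

_STACK_SUFFIXES = (".npy", ".npz", ".tif", ".tiff")


def _load_stack(path: Path) -> np.ndarray:
    if path.suffix == ".npy":
        return np.load(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            return data[list(data.files)[0]]
    import tifffile

    return tifffile.imread(path)


def find_unprocessed_series(directory: Path) -> list[tuple[Path, Path]]:
    """(stack, tlt) pairs in a directory that have no alignment JSON yet."""
    directory = Path(directory)
    pairs = []
    for stack in sorted(directory.iterdir()):
        if stack.suffix.lower() not in _STACK_SUFFIXES:
            continue
        tlt = stack.with_suffix(".tlt")
        done = stack.with_name(stack.stem + ".json")
        if tlt.exists() and not done.exists():
            pairs.append((stack, tlt))
    return pairs


def align_directory(
    directory: Path,
    pixel_size: float,
    fiducial_diameter: float,
    params: Optional[AlignmentParams] = None,
    on_result: Optional[Callable] = None,
) -> int:
    """Align every unprocessed series in a directory; returns the count."""
    n = 0
    for stack, tlt in find_unprocessed_series(directory):
        series = TiltSeries(
            _load_stack(stack), np.loadtxt(tlt, ndmin=1),
            pixel_size=pixel_size, fiducial_diameter=fiducial_diameter,
        )
        result = align_tilt_series(series, params)
        write_report(result, stack.parent, basename=stack.stem)
        if on_result is not None:
            on_result(stack, result)
        n += 1
    return n


def watch_directory(
    directory: Path,
    pixel_size: float,
    fiducial_diameter: float,
    poll_seconds: float = 30.0,
    stop_after_passes: Optional[int] = None,
    params: Optional[AlignmentParams] = None,
    on_result: Optional[Callable] = None,
) -> int:
    """Poll a directory, aligning series as they appear (on-the-fly mode).

    Runs until interrupted, or for ``stop_after_passes`` polls when given.
    Returns the total number of series aligned.
    """
    total = 0
    passes = 0
    while True:
        total += align_directory(
            directory, pixel_size, fiducial_diameter, params, on_result
        )
        passes += 1
        if stop_after_passes is not None and passes >= stop_after_passes:
            return total
        time.sleep(poll_seconds)
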