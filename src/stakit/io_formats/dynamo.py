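"""Reading and writing of Dynamo particle tables (.tbl).

A Dynamo table is a whitespace-separated numeric matrix with one particle
per row and fixed 1-based column semantics. The columns this package
interprets are::

    1       tag (positive integer, unique per table)
    2, 3    aligned / averaged flags
    4-6     dx, dy, dz   shifts (px)
    7-9     tdrot, tilt, narot   Euler angles (deg, zxz extrinsic)
    10      cc           cross-correlation score
    20      tomogram     tomogram/volume index
    24-26   x, y, z      particle position (px)

All other columns are carried opaquely, so tables written by any Dynamo
tool survive a read/write cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from ._text import TextSource, slurp

__all__ = ["DynamoTable", "DynamoTableError", "read_dynamo_table", "write_dynamo_table"]

MIN_COLUMNS = 26

# 1-based column index -> accessor name
COLUMN_NAMES = {
    1: "tag", 2: "aligned", 3: "averaged",
    4: "dx", 5: "dy", 6: "dz",
    7: "tdrot", 8: "tilt", 9: "narot",
    10: "cc", 20: "tomogram",
    24: "x", 25: "y", 26: "z",
}


class DynamoTableError(ValueError):
    """Raised for malformed tables (ragged rows, too few columns, bad tags)."""


@dataclass
class DynamoTable:
    """Per-particle rows under the fixed Dynamo column-index semantics."""

    data: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.size == 0:
            self.data = self.data.reshape(0, self.data.shape[1] if self.data.ndim == 2 else 0)
            return
        if self.data.shape[1] < MIN_COLUMNS:
            raise DynamoTableError(
                f"table has {self.data.shape[1]} columns, minimum is {MIN_COLUMNS}"
            )
        tags = self.data[:, 0]
        if np.any(tags <= 0) or np.any(tags != np.round(tags)):
            raise DynamoTableError("tags (column 1) must be positive integers")
        if len(np.unique(tags)) != len(tags):
            raise DynamoTableError("tags (column 1) must be unique within a table")

    def __len__(self) -> int:
        return self.data.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DynamoTable):
            return NotImplemented
        if len(self) == 0 and len(other) == 0:
            return True
        return self.data.shape == other.data.shape and np.array_equal(
            self.data, other.data
        )

    def column(self, index: int) -> np.ndarray:
        """1-based column access."""
        if not 1 <= index <= self.data.shape[1]:
            raise IndexError(f"column {index} out of range 1..{self.data.shape[1]}")
        return self.data[:, index - 1]

    @property
    def tags(self) -> np.ndarray:
        return self.column(1).astype(int)

    @property
    def shifts(self) -> np.ndarray:
        """(n, 3) dx, dy, dz."""
        return self.data[:, 3:6]

    @property
    def angles(self) -> np.ndarray:
        """(n, 3) tdrot, tilt, narot in degrees."""
        return self.data[:, 6:9]

    @property
    def cc(self) -> np.ndarray:
        return self.column(10)

    @property
    def tomogram(self) -> np.ndarray:
        return self.column(20).astype(int)

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) x, y, z."""
        return self.data[:, 23:26]

    def to_dataframe(self) -> pd.DataFrame:
        names = [COLUMN_NAMES.get(i, f"col{i}") for i in range(1, self.data.shape[1] + 1)]
        return pd.DataFrame(self.data, columns=names)


def read_dynamo_table(source: TextSource) -> DynamoTable:
    """Parse a whitespace table; empty input yields an empty table."""
    text = slurp(source)
    rows: list[list[float]] = []
    width: int | None = None
    for i, raw in enumerate(text.splitlines()):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            values = [float(tok) for tok in line.split()]
        except ValueError as exc:
            raise DynamoTableError(f"row {len(rows)}: non-numeric field ({exc})") from None
        if width is None:
            width = len(values)
        elif len(values) != width:
            raise DynamoTableError(
                f"row {len(rows)} has {len(values)} columns, expected {width}"
            )
        rows.append(values)
    if not rows:
        return DynamoTable(np.empty((0, 0)))
    return DynamoTable(np.array(rows, dtype=float))


def _format(x: float) -> str:
    if x == np.round(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def write_dynamo_table(
    table: DynamoTable, destination: Union[str, Path, None] = None
) -> str:
    """Emit one space-separated particle per line.

    Integers are written exactly; reals with full ``repr`` precision, so a
    read/write cycle is value-exact.
    """
    lines = [" ".join(_format(v) for v in row) for row in table.data]
    text = "\n".join(lines)
    if lines:
        text += "\n"
    if destination is not None:
        Path(destination).write_text(text, encoding="utf-8")
    return text
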