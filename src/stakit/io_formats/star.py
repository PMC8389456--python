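"""Reading and writing of STAR files.

STAR is the text metadata format used by RELION: a file is an ordered
sequence of named ``data_`` blocks, each of which is either *simple*
(``_tag value`` pairs) or a *loop* (a ``loop_`` table with named columns).
Values are kept as strings internally so that any dialect round-trips at
value level; typed access is provided through :meth:`StarLoop.to_dataframe`
and :func:`as_number`.

Limitations (deliberate): full-line ``#`` comments are skipped on read and
not preserved; fields containing whitespace are not quoted, matching the
behaviour of RELION's own writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd

from ._text import TextSource, slurp

__all__ = [
    "StarDocument",
    "StarLoop",
    "StarParseError",
    "read_star",
    "write_star",
    "as_number",
]


class StarParseError(ValueError):
    """Raised when a STAR source violates the block/loop grammar."""


@dataclass
class StarLoop:
    """A ``loop_`` table: ordered column names and rows of string cells."""

    columns: list[str] = field(default_factory=list)
    rows: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.columns)) != len(self.columns):
            raise StarParseError("duplicate column names in loop block")
        for r in self.rows:
            if len(r) != len(self.columns):
                raise StarParseError(
                    f"loop row has {len(r)} fields, expected {len(self.columns)}"
                )

    def __len__(self) -> int:
        return len(self.rows)

    def to_dataframe(self) -> pd.DataFrame:
        """Return the table with numeric-looking columns converted."""
        df = pd.DataFrame(self.rows, columns=self.columns, dtype=object)
        for c in df.columns:
            converted = pd.to_numeric(df[c], errors="coerce")
            if not converted.isna().any() or (df[c] == "nan").any():
                df[c] = converted
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "StarLoop":
        rows = [[_format_cell(v) for v in row] for row in df.itertuples(index=False)]
        return cls(columns=[str(c) for c in df.columns], rows=rows)


# a block is either a simple tag->value map or a loop table
StarBlock = Union[dict, StarLoop]


@dataclass
class StarDocument:
    """Ordered, named data blocks of a STAR file."""

    blocks: dict[str, StarBlock] = field(default_factory=dict)

    def __getitem__(self, name: str) -> StarBlock:
        return self.blocks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.blocks

    def __len__(self) -> int:
        return len(self.blocks)

    def block_names(self) -> list[str]:
        return list(self.blocks)

    def first_loop(self) -> tuple[str, StarLoop]:
        """Name and table of the first loop block (KeyError if none)."""
        for name, block in self.blocks.items():
            if isinstance(block, StarLoop):
                return name, block
        raise KeyError("document contains no loop block")


def as_number(value: str) -> float:
    """Interpret a STAR cell as a number (int-valued floats stay exact)."""
    return float(value)


def _format_cell(value: object) -> str:
    if isinstance(value, str):
        return value
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, float):
        return repr(value)
    return str(value)


def read_star(source: TextSource) -> StarDocument:
    """Parse a STAR document from text, a path, or an open text handle.

    Empty input yields an empty document. Malformed loops (row width not
    matching the column count) raise :class:`StarParseError` naming the
    offending line number.
    """
    text = slurp(source)
    doc = StarDocument()

    lines = text.splitlines()
    current_name: str | None = None
    current_simple: dict | None = None
    current_loop: StarLoop | None = None
    in_loop_header = False

    def flush() -> None:
        nonlocal current_name, current_simple, current_loop
        if current_name is None:
            return
        if current_name in doc.blocks:
            raise StarParseError(f"duplicate block name {current_name!r}")
        if current_loop is not None:
            doc.blocks[current_name] = current_loop
        else:
            doc.blocks[current_name] = current_simple if current_simple else {}
        current_name, current_simple, current_loop = None, None, None

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("data_"):
            flush()
            current_name = line[len("data_"):]
            in_loop_header = False
            continue
        if current_name is None:
            raise StarParseError(f"line {lineno}: content before any data_ block")
        if line == "loop_":
            if current_simple:
                raise StarParseError(
                    f"line {lineno}: loop_ after simple tags in one block"
                )
            current_loop = StarLoop()
            in_loop_header = True
            continue
        if line.startswith("_"):
            tokens = line.split()
            if current_loop is not None and in_loop_header:
                # loop column declaration, optionally "#n" numbered
                col = tokens[0]
                if col in current_loop.columns:
                    raise StarParseError(f"line {lineno}: duplicate column {col!r}")
                current_loop.columns.append(col)
                continue
            if current_loop is not None:
                raise StarParseError(f"line {lineno}: tag line inside loop data")
            if len(tokens) < 2:
                raise StarParseError(f"line {lineno}: tag {tokens[0]!r} without value")
            if current_simple is None:
                current_simple = {}
            current_simple[tokens[0]] = tokens[1]
            continue
        # data row
        if current_loop is None:
            raise StarParseError(f"line {lineno}: unexpected data outside a loop")
        in_loop_header = False
        fields = line.split()
        if len(fields) != len(current_loop.columns):
            raise StarParseError(
                f"line {lineno}: row has {len(fields)} fields, "
                f"expected {len(current_loop.columns)}"
            )
        current_loop.rows.append(fields)

    flush()
    return doc


def write_star(doc: StarDocument, destination: Union[str, Path, None] = None) -> str:
    """Serialize a document to STAR text (and optionally to a file).

    Loop headers are numbered ``#1..#n`` and data columns are whitespace
    aligned; output is deterministic for equal input.
    """
    out: list[str] = []
    for name, block in doc.blocks.items():
        out.append(f"data_{name}")
        out.append("")
        if isinstance(block, StarLoop):
            if not block.columns:
                raise ValueError(f"loop block {name!r} has zero columns")
            out.append("loop_")
            for i, col in enumerate(block.columns, start=1):
                out.append(f"{col} #{i}")
            widths = [
                max([len(col)] + [len(r[i]) for r in block.rows])
                for i, col in enumerate(block.columns)
            ]
            for row in block.rows:
                out.append("  ".join(v.rjust(w) for v, w in zip(row, widths)))
        else:
            if block:
                tag_w = max(len(t) for t in block)
                for tag, value in block.items():
                    out.append(f"{tag.ljust(tag_w)}  {value}")
        out.append("")
        out.append("")
    text = "\n".join(out)
    if destination is not None:
        Path(destination).write_text(text, encoding="utf-8")
    return text
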