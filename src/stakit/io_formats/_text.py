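"""Shared text-source handling for the metadata readers."""

from __future__ import annotations

import io
from pathlib import Path
from typing import Union

TextSource = Union[str, Path, io.TextIOBase]


def slurp(source: TextSource) -> str:
    """Return the full text of a path, open handle, or raw string."""
    if isinstance(source, io.TextIOBase):
        return source.read()
    if isinstance(source, Path):
        return source.read_text(encoding="utf-8")
    if isinstance(source, str):
        # a str is treated as a path when it names an existing file
        if "\n" not in source and Path(source).is_file():
            return Path(source).read_text(encoding="utf-8")
        return source
    raise TypeError(f"cannot read text from {type(source)!r}")
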