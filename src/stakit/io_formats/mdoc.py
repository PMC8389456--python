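"""Reading and writing of SerialEM .mdoc tilt-series metadata files.

An mdoc file carries global ``key = value`` header entries followed by one
``[ZValue = n]`` section per tilt image, each with its own entries
(``TiltAngle``, ``SubFramePath``, dose, ...). Values are stored verbatim as
strings; :attr:`MdocSection.tilt_angle` converts on access. Files are
written with CRLF line endings (SerialEM native) and read accepting both.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

from ._text import TextSource, slurp

__all__ = ["MdocDocument", "MdocSection", "MdocParseError", "read_mdoc", "write_mdoc"]

_SECTION_RE = re.compile(r"^\[(?P<key>[^=\]]+?)\s*=\s*(?P<value>[^\]]+?)\s*\]$")


class MdocParseError(ValueError):
    pass


@dataclass
class MdocSection:
    """One tilt image: its ZValue index plus arbitrary tag -> value entries."""

    zvalue: int
    entries: dict[str, str] = field(default_factory=dict)

    @property
    def tilt_angle(self) -> float:
        return float(self.entries["TiltAngle"])

    @property
    def sub_frame_path(self) -> str:
        return self.entries["SubFramePath"]


@dataclass
class MdocDocument:
    header: dict[str, str] = field(default_factory=dict)
    titles: list[str] = field(default_factory=list)
    sections: list[MdocSection] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sections)

    @property
    def tilt_angles(self) -> list[float]:
        return [s.tilt_angle for s in self.sections]


def read_mdoc(source: TextSource) -> MdocDocument:
    """Parse an mdoc document.

    Global entries before the first section go to the header; ``[T = ...]``
    title lines are collected separately. A section header that is not a
    ZValue raises :class:`MdocParseError`.
    """
    text = slurp(source)
    doc = MdocDocument()
    current: dict[str, str] = doc.header

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("["):
            m = _SECTION_RE.match(line)
            if m is None:
                raise MdocParseError(f"line {lineno}: malformed section header {line!r}")
            key, value = m.group("key").strip(), m.group("value").strip()
            if key == "T":
                doc.titles.append(value)
                continue
            if key != "ZValue":
                raise MdocParseError(
                    f"line {lineno}: section header {key!r} is not ZValue"
                )
            section = MdocSection(zvalue=int(value))
            doc.sections.append(section)
            current = section.entries
            continue
        if "=" not in line:
            raise MdocParseError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        current[key.strip()] = value.strip()
    return doc


def write_mdoc(doc: MdocDocument, destination: Union[str, Path, None] = None) -> str:
    """Serialize with CRLF endings; sections are renumbered 0..n-1 in order."""
    lines: list[str] = []
    for key, value in doc.header.items():
        lines.append(f"{key} = {value}")
    if doc.header:
        lines.append("")
    for title in doc.titles:
        lines.append(f"[T = {title}]")
        lines.append("")
    for z, section in enumerate(doc.sections):
        section.zvalue = z
        lines.append(f"[ZValue = {z}]")
        for key, value in section.entries.items():
            lines.append(f"{key} = {value}")
        lines.append("")
    text = "\r\n".join(lines)
    if lines:
        text += "\r\n"
    if destination is not None:
        Path(destination).write_text(text, encoding="utf-8", newline="")
    return text
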