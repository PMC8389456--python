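"""Bidirectional metadata conversion between Dynamo and the Warp/RELION
world, plus mdoc generation for Tomography 5 filename listings.

The conversions move particle positions and orientations between the two
primary subtomogram-averaging metadata systems:

* Dynamo tables store positions (columns 24-26) plus residual shifts
  (4-6) and zxz-extrinsic Euler angles rotating the particle onto the
  reference.
* RELION STAR files store coordinates and zyz-intrinsic Euler angles
  rotating the reference onto the particle.

Orientation conversion goes through rotation matrices, so the underlying
rotation is preserved exactly. Dynamo shifts are consumed (added to the
positions) on export and emitted as zero on import, so downstream
refinement can never double-count them. Coordinate scaling between
binned annotation tomograms and unbinned extraction volumes is always
explicit — there is no silent inference.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_formats import (
    DynamoTable,
    MdocDocument,
    MdocSection,
    StarDocument,
    StarLoop,
)
from .rotations import convert_eulers

__all__ = [
    "ConversionConfig",
    "TiltImageFilenameInfo",
    "dynamo_to_relion",
    "relion_to_dynamo",
    "star_downgrade",
    "parse_tomo5_filename",
    "spoof_mdoc",
    "write_catalogue_manifest",
]

COORDINATE_TAGS = ("_rlnCoordinateX", "_rlnCoordinateY", "_rlnCoordinateZ")
ANGLE_TAGS = ("_rlnAngleRot", "_rlnAngleTilt", "_rlnAnglePsi")
ORIGIN_TAGS = ("_rlnOriginX", "_rlnOriginY", "_rlnOriginZ")
MICROGRAPH_TAG = "_rlnMicrographName"


@dataclass
class ConversionConfig:
    """How to map between Dynamo tables and STAR particle blocks.

    ``coordinate_scale`` multiplies positions (e.g. 4.0 when annotations
    were made in 4x-binned tomograms); ``tomogram_map`` maps Dynamo
    tomogram indices to micrograph/tomostar names. With no map, names are
    generated as ``<id>.tomostar`` and inverted by enumeration.
    """

    coordinate_scale: float = 1.0
    source_convention: str = "dynamo"
    target_convention: str = "relion"
    tomogram_map: Optional[dict[int, str]] = None

    def __post_init__(self) -> None:
        if self.coordinate_scale <= 0:
            raise ValueError("coordinate_scale must be positive")

    def micrograph_name(self, tomogram_id: int) -> str:
        if self.tomogram_map is None:
            return f"{tomogram_id}.tomostar"
        try:
            return self.tomogram_map[int(tomogram_id)]
        except KeyError:
            raise KeyError(
                f"tomogram id {tomogram_id} missing from tomogram_map"
            ) from None


def _fmt(x: float) -> str:
    # 8 decimals keep re-derived rotation matrices within 1e-10 of the
    # source through a text round trip
    return f"{x:.8f}"


def dynamo_to_relion(
    table: DynamoTable, config: Optional[ConversionConfig] = None
) -> StarDocument:
    """Convert a Dynamo table to a flat RELION-3.0-style particle STAR.

    Positions become ``(x, y, z) + (dx, dy, dz)`` scaled by
    ``coordinate_scale``; angles are re-expressed from the Dynamo to the
    RELION convention with matrix-level equality; tomogram indices map to
    micrograph names. Unmapped tomogram ids raise, listing the offenders.
    """
    config = config or ConversionConfig()
    if config.tomogram_map is not None:
        missing = sorted(
            set(table.tomogram.tolist()) - set(config.tomogram_map)
        )
        if missing:
            raise KeyError(f"tomogram ids not in tomogram_map: {missing}")
    positions = (table.positions + table.shifts) * config.coordinate_scale
    angles = convert_eulers(
        config.source_convention, config.target_convention, table.angles
    ) if len(table) else np.empty((0, 3))

    columns = list(COORDINATE_TAGS + ANGLE_TAGS) + [MICROGRAPH_TAG]
    rows = []
    for i in range(len(table)):
        rows.append(
            [_fmt(v) for v in positions[i]]
            + [_fmt(v) for v in angles[i]]
            + [config.micrograph_name(table.tomogram[i])]
        )
    doc = StarDocument()
    doc.blocks[""] = StarLoop(columns=columns, rows=rows)
    return doc


def relion_to_dynamo(
    doc: StarDocument, config: Optional[ConversionConfig] = None
) -> DynamoTable:
    """Convert a STAR particle block back to a Dynamo table.

    The inverse of :func:`dynamo_to_relion`: origins (if any) are
    subtracted from coordinates, shifts are emitted as zero, positions are
    divided by the coordinate scale, and fresh sequential tags assigned.
    Missing coordinate or angle tags raise an error naming them.
    """
    config = config or ConversionConfig()
    block = _find_particle_block(doc)
    missing = [
        t for t in COORDINATE_TAGS + ANGLE_TAGS if t not in block.columns
    ]
    if missing:
        raise KeyError(f"STAR document lacks required tags: {missing}")
    df = block.to_dataframe()
    n = len(df)
    coords = df[list(COORDINATE_TAGS)].to_numpy(dtype=float)
    for origin_tag, k in zip(ORIGIN_TAGS, range(3)):
        if origin_tag in df.columns:
            coords[:, k] -= df[origin_tag].to_numpy(dtype=float)
    coords /= config.coordinate_scale
    angles = convert_eulers(
        config.target_convention, config.source_convention,
        df[list(ANGLE_TAGS)].to_numpy(dtype=float),
    ) if n else np.empty((0, 3))

    if MICROGRAPH_TAG in df.columns:
        names = df[MICROGRAPH_TAG].astype(str)
        if config.tomogram_map is not None:
            inverse = {v: k for k, v in config.tomogram_map.items()}
            try:
                tomo = np.array([inverse[v] for v in names])
            except KeyError as exc:
                raise KeyError(f"micrograph name {exc} not in tomogram_map") from None
        else:
            order = {v: i + 1 for i, v in enumerate(dict.fromkeys(names))}
            tomo = np.array([order[v] for v in names])
    else:
        tomo = np.ones(n, dtype=int)

    data = np.zeros((n, 26))
    data[:, 0] = np.arange(1, n + 1)      # fresh sequential tags
    data[:, 6:9] = angles
    data[:, 19] = tomo
    data[:, 23:26] = coords
    if n == 0:
        return DynamoTable(np.empty((0, 0)))
    return DynamoTable(data)


def _find_particle_block(doc: StarDocument) -> StarLoop:
    for name in ("particles", ""):
        if name in doc and isinstance(doc[name], StarLoop):
            return doc[name]
    for name, block in doc.blocks.items():
        if isinstance(block, StarLoop) and COORDINATE_TAGS[0] in block.columns:
            return block
    raise KeyError("STAR document contains no particle loop block")


# Optics fields copied into each particle row on downgrade, with the
# renames a Warp-1.0.x-era consumer expects. rlnImagePixelSize maps to
# the detector-pixel-size/magnification pair at nominal 10000x.
_OPTICS_COPY = {
    "_rlnVoltage": "_rlnVoltage",
    "_rlnSphericalAberration": "_rlnSphericalAberration",
    "_rlnAmplitudeContrast": "_rlnAmplitudeContrast",
    "_rlnImageSize": "_rlnImageSize",
    "_rlnImageDimensionality": "_rlnImageDimensionality",
}
_ANGST_ORIGINS = {
    "_rlnOriginXAngst": "_rlnOriginX",
    "_rlnOriginYAngst": "_rlnOriginY",
    "_rlnOriginZAngst": "_rlnOriginZ",
}
_DROPPED_31_TAGS = ("_rlnOpticsGroup", "_rlnOpticsGroupName")


def star_downgrade(doc: StarDocument) -> StarDocument:
    """Flatten a RELION-3.1 optics-grouped STAR to the 3.0 dialect.

    Each particle's optics-group reference is resolved by copying that
    group's acquisition fields into the particle row; Angstrom origins
    become pixel origins using the group pixel size; the optics block and
    3.1-only tags disappear. Documents without an optics block are
    returned unchanged, which makes the operation idempotent.
    """
    if "optics" not in doc or not isinstance(doc.blocks.get("optics"), StarLoop):
        return doc
    optics = doc["optics"].to_dataframe()
    if "_rlnOpticsGroup" not in optics.columns:
        raise KeyError("optics block lacks _rlnOpticsGroup")
    optics = optics.set_index(optics["_rlnOpticsGroup"].astype(int))

    particles = None
    for name, block in doc.blocks.items():
        if name != "optics" and isinstance(block, StarLoop):
            particles = block
            break
    if particles is None:
        raise KeyError("document has an optics block but no particle loop")
    df = particles.to_dataframe()
    if "_rlnOpticsGroup" not in df.columns:
        raise KeyError("particle block lacks _rlnOpticsGroup")
    groups = df["_rlnOpticsGroup"].astype(int)
    unknown = sorted(set(groups) - set(optics.index))
    if unknown:
        raise KeyError(f"particles reference absent optics groups: {unknown}")

    px = None
    if "_rlnImagePixelSize" in optics.columns:
        px = optics["_rlnImagePixelSize"].astype(float)
    for src, dst in _OPTICS_COPY.items():
        if src in optics.columns and dst not in df.columns:
            df[dst] = optics.loc[groups, src].to_numpy()
    if px is not None:
        df["_rlnDetectorPixelSize"] = px.loc[groups].to_numpy()
        df["_rlnMagnification"] = 10000.0
    for src, dst in _ANGST_ORIGINS.items():
        if src in df.columns:
            if px is None:
                raise KeyError(
                    "Angstrom origins present but optics block has no "
                    "_rlnImagePixelSize"
                )
            df[dst] = df[src].astype(float) / px.loc[groups].to_numpy()
            df = df.drop(columns=[src])
    df = df.drop(columns=[c for c in _DROPPED_31_TAGS if c in df.columns])

    out = StarDocument()
    out.blocks[""] = StarLoop.from_dataframe(df)
    return out


_TOMO5_RE = re.compile(
    r"^(?P<base>.+)_(?P<count>\d{1,4})\[(?P<tilt>[+\-−]?\d+(?:\.\d+)?)\]"
    r"_fractions\.(?P<ext>\w+)$"
)


@dataclass
class TiltImageFilenameInfo:
    """Parsed Tomography 5 micrograph filename."""

    basename: str
    count: int
    tilt_angle: float
    original_name: str
    _count_token: str = field(default="", repr=False)
    _tilt_token: str = field(default="", repr=False)
    _extension: str = field(default="mrc", repr=False)

    def render(self) -> str:
        """Re-render the pattern; reproduces the original name exactly."""
        return (
            f"{self.basename}_{self._count_token}[{self._tilt_token}]"
            f"_fractions.{self._extension}"
        )


def parse_tomo5_filename(name: str) -> TiltImageFilenameInfo:
    """Parse ``<basename>_<count>[<tilt_angle>]_fractions.mrc`` names.

    Both the ASCII hyphen-minus and the Unicode minus are accepted in the
    tilt angle; counts may have 1-4 digits.
    """
    m = _TOMO5_RE.match(name)
    if m is None:
        raise ValueError(
            f"filename {name!r} does not match the Tomography 5 grammar "
            "<basename>_<count>[<tilt_angle>]_fractions.<ext>"
        )
    tilt_token = m.group("tilt")
    tilt = float(tilt_token.replace("−", "-"))
    return TiltImageFilenameInfo(
        basename=m.group("base"),
        count=int(m.group("count")),
        tilt_angle=tilt,
        original_name=name,
        _count_token=m.group("count"),
        _tilt_token=tilt_token,
        _extension=m.group("ext"),
    )


def spoof_mdoc(
    directory_listing: Sequence[str],
    pixel_spacing: float = 1.0,
    voltage: float = 300.0,
    dose_per_image: float = 3.0,
) -> dict[str, MdocDocument]:
    """Generate one mdoc per tilt series from Tomography 5 filenames.

    Files are grouped by basename and ordered by their count field within
    each group; every section carries the tilt angle parsed from the
    bracketed token, the source file as SubFramePath, and sequential
    ZValues from 0. Unparseable files are skipped with a warning.
    """
    groups: dict[str, list[TiltImageFilenameInfo]] = {}
    skipped = []
    for name in directory_listing:
        try:
            info = parse_tomo5_filename(name)
        except ValueError:
            skipped.append(name)
            continue
        groups.setdefault(info.basename, []).append(info)
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} file(s) not matching the Tomography 5 "
            f"grammar: {skipped[:5]}{'...' if len(skipped) > 5 else ''}",
            stacklevel=2,
        )
    out: dict[str, MdocDocument] = {}
    for basename in sorted(groups):
        infos = sorted(groups[basename], key=lambda i: i.count)
        doc = MdocDocument(
            header={
                "PixelSpacing": repr(float(pixel_spacing)),
                "Voltage": repr(float(voltage)),
                "ImageFile": f"{basename}.mrc",
            },
            titles=["generated from Tomography 5 filenames"],
        )
        for z, info in enumerate(infos):
            doc.sections.append(
                MdocSection(
                    zvalue=z,
                    entries={
                        "TiltAngle": info._tilt_token.replace("−", "-"),
                        "SubFramePath": info.original_name,
                        "ExposureDose": repr(float(dose_per_image)),
                    },
                )
            )
        out[basename] = doc
    return out


def write_catalogue_manifest(
    pairs: Sequence[tuple[str, str]],
) -> str:
    """Plain-text manifest pairing each filtered visualization volume with
    its unfiltered extraction counterpart (one tab-separated pair per
    line): annotation happens on deconvolved tomograms while particle
    extraction uses the corresponding raw reconstruction."""
    lines = ["# visualization_volume\textraction_volume"]
    for vis, extract in pairs:
        lines.append(f"{vis}\t{extract}")
    return "\n".join(lines) + "\n"
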