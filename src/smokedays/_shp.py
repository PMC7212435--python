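"""Minimal ESRI Shapefile polygon I/O for the HMS daily smoke dialect.

Implements just the subset the HMS archive uses: a ``.shp`` of Null (type 0)
or Polygon (type 5) records, a ``.shx`` index, and a dBASE III ``.dbf`` with
character ('C') and numeric ('N') fields.  Zipped file sets are accepted and
unpacked to a temporary directory.  Coordinates are geographic degrees and
pass through untouched; ring orientation is preserved but carries no meaning
downstream (containment uses the even-odd rule).

A polygon geometry is represented as a tuple of rings, each ring a tuple of
``(x, y)`` float pairs with the shapefile's explicit closure (first vertex
repeated last) retained on read and added on write if missing.
"""

from __future__ import annotations

import datetime
import struct
import tempfile
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

Ring = tuple[tuple[float, float], ...]
Rings = tuple[Ring, ...]

_SHAPE_NULL = 0
_SHAPE_POLYGON = 5


@dataclass(frozen=True)
class FieldDef:
    """One dBASE field descriptor: name (<=10 chars), 'C' or 'N', width, decimals."""

    name: str
    ftype: str
    length: int
    decimals: int = 0


@dataclass
class ShapeRecord:
    rings: Rings  # empty tuple for Null shapes
    attrs: dict[str, object]


# ---------------------------------------------------------------------------
# reading


def read_shapefile(source: str | Path) -> tuple[list[ShapeRecord], list[FieldDef]]:
    """Read a polygon shapefile set.

    ``source`` may be the ``.shp`` path, a basename without extension, a
    directory containing exactly one ``.shp``, or a ``.zip`` of the set.
    """
    source = Path(source)
    if source.suffix.lower() == ".zip":
        with tempfile.TemporaryDirectory() as tmp:
            with zipfile.ZipFile(source) as zf:
                zf.extractall(tmp)
            return read_shapefile(_find_shp(Path(tmp)))
    if source.is_dir():
        return read_shapefile(_find_shp(source))
    shp = source if source.suffix.lower() == ".shp" else source.with_suffix(".shp")
    if not shp.exists():
        raise FileNotFoundError(shp)
    dbf = _sibling(shp, ".dbf")
    geoms = _read_shp(shp)
    fields, rows = _read_dbf(dbf) if dbf is not None else ([], [{} for _ in geoms])
    if len(rows) != len(geoms):
        raise ValueError(
            f"{shp.name}: .shp has {len(geoms)} records but .dbf has {len(rows)}"
        )
    return [ShapeRecord(g, r) for g, r in zip(geoms, rows)], fields


def _find_shp(directory: Path) -> Path:
    shps = sorted(directory.rglob("*.shp"))
    if not shps:
        raise FileNotFoundError(f"no .shp file under {directory}")
    return shps[0]


def _sibling(shp: Path, ext: str) -> Path | None:
    for cand in (shp.with_suffix(ext), shp.with_suffix(ext.upper())):
        if cand.exists():
            return cand
    return None


def _read_shp(path: Path) -> list[Rings]:
    data = path.read_bytes()
    if len(data) < 100 or struct.unpack(">i", data[:4])[0] != 9994:
        raise ValueError(f"{path.name}: not a shapefile (bad file code)")
    file_len = struct.unpack(">i", data[24:28])[0] * 2  # 16-bit words -> bytes
    shapes: list[Rings] = []
    pos = 100
    while pos + 8 <= min(file_len, len(data)):
        (_recno, content_len) = struct.unpack(">ii", data[pos : pos + 8])
        pos += 8
        content = data[pos : pos + content_len * 2]
        pos += content_len * 2
        shapes.append(_parse_polygon_record(content, path.name))
    return shapes


def _parse_polygon_record(content: bytes, name: str) -> Rings:
    if len(content) < 4:
        raise ValueError(f"{name}: truncated record")
    (stype,) = struct.unpack("<i", content[:4])
    if stype == _SHAPE_NULL:
        return ()
    if stype != _SHAPE_POLYGON:
        raise ValueError(f"{name}: unsupported shape type {stype}")
    num_parts, num_points = struct.unpack("<ii", content[36:44])
    parts = struct.unpack(f"<{num_parts}i", content[44 : 44 + 4 * num_parts])
    pts_off = 44 + 4 * num_parts
    flat = struct.unpack(
        f"<{2 * num_points}d", content[pts_off : pts_off + 16 * num_points]
    )
    points = [(flat[2 * i], flat[2 * i + 1]) for i in range(num_points)]
    bounds = list(parts) + [num_points]
    return tuple(
        tuple(points[bounds[i] : bounds[i + 1]]) for i in range(num_parts)
    )


def _read_dbf(path: Path) -> tuple[list[FieldDef], list[dict[str, object]]]:
    data = path.read_bytes()
    n_records = struct.unpack("<i", data[4:8])[0]
    header_size, record_size = struct.unpack("<hh", data[8:12])
    fields: list[FieldDef] = []
    pos = 32
    while pos < header_size - 1 and data[pos] != 0x0D:
        raw = data[pos : pos + 32]
        fname = raw[:11].split(b"\x00")[0].decode("ascii")
        ftype = chr(raw[11])
        flen = raw[16]
        fdec = raw[17]
        fields.append(FieldDef(fname, ftype, flen, fdec))
        pos += 32
    rows: list[dict[str, object]] = []
    pos = header_size
    for _ in range(n_records):
        rec = data[pos : pos + record_size]
        pos += record_size
        if not rec or rec[0:1] == b"*":  # deleted
            continue
        row: dict[str, object] = {}
        off = 1
        for f in fields:
            cell = rec[off : off + f.length].decode("ascii", "replace").strip()
            off += f.length
            row[f.name] = _decode_cell(cell, f)
        rows.append(row)
    return fields, rows


def _decode_cell(cell: str, f: FieldDef) -> object:
    if f.ftype != "N":
        return cell
    if cell == "":
        return None
    return float(cell) if f.decimals or "." in cell else int(cell)


# ---------------------------------------------------------------------------
# writing


def write_shapefile(
    path: str | Path,
    records: Iterable[ShapeRecord],
    fields: Sequence[FieldDef],
) -> Path:
    """Write ``.shp``/``.shx``/``.dbf`` for polygon records; returns the .shp path."""
    records = list(records)
    shp = Path(path).with_suffix(".shp")
    shp.parent.mkdir(parents=True, exist_ok=True)

    contents = [_encode_polygon_record(r.rings) for r in records]
    bbox = _total_bbox(records)

    shp_body = b""
    shx_body = b""
    offset = 50  # header length in 16-bit words
    for i, content in enumerate(contents, start=1):
        clen = len(content) // 2
        shp_body += struct.pack(">ii", i, clen) + content
        shx_body += struct.pack(">ii", offset, clen)
        offset += 4 + clen

    shp.write_bytes(_main_header(50 + len(shp_body) // 2, bbox) + shp_body)
    shp.with_suffix(".shx").write_bytes(
        _main_header(50 + len(shx_body) // 2, bbox) + shx_body
    )
    shp.with_suffix(".dbf").write_bytes(_encode_dbf(records, fields))
    return shp


def _total_bbox(records: list[ShapeRecord]) -> tuple[float, float, float, float]:
    xs = [x for r in records for ring in r.rings for x, _ in ring]
    ys = [y for r in records for ring in r.rings for _, y in ring]
    if not xs:
        return (0.0, 0.0, 0.0, 0.0)
    return (min(xs), min(ys), max(xs), max(ys))


def _main_header(length_words: int, bbox: tuple[float, float, float, float]) -> bytes:
    return (
        struct.pack(">i", 9994)
        + b"\x00" * 20
        + struct.pack(">i", length_words)
        + struct.pack("<ii", 1000, _SHAPE_POLYGON)
        + struct.pack("<4d", *bbox)
        + struct.pack("<4d", 0.0, 0.0, 0.0, 0.0)
    )


def _close(ring: Ring) -> Ring:
    return ring if ring and ring[0] == ring[-1] else ring + (ring[0],)


def _encode_polygon_record(rings: Rings) -> bytes:
    if not rings:
        return struct.pack("<i", _SHAPE_NULL)
    closed = [_close(r) for r in rings]
    xs = [x for r in closed for x, _ in r]
    ys = [y for r in closed for _, y in r]
    parts: list[int] = []
    total = 0
    for r in closed:
        parts.append(total)
        total += len(r)
    out = struct.pack("<i", _SHAPE_POLYGON)
    out += struct.pack("<4d", min(xs), min(ys), max(xs), max(ys))
    out += struct.pack("<ii", len(closed), total)
    out += struct.pack(f"<{len(parts)}i", *parts)
    for r in closed:
        for x, y in r:
            out += struct.pack("<2d", x, y)
    return out


def _encode_dbf(records: list[ShapeRecord], fields: Sequence[FieldDef]) -> bytes:
    today = datetime.date.today()
    n = len(records)
    header_size = 32 + 32 * len(fields) + 1
    record_size = 1 + sum(f.length for f in fields)
    out = struct.pack(
        "<B3BihhB",
        0x03,
        today.year - 1900,
        today.month,
        today.day,
        n,
        header_size,
        record_size,
        0,
    )
    out += b"\x00" * 19
    for f in fields:
        name = f.name.encode("ascii")[:10]
        out += name + b"\x00" * (11 - len(name))
        out += f.ftype.encode("ascii")
        out += b"\x00" * 4
        out += struct.pack("<BB", f.length, f.decimals)
        out += b"\x00" * 14
    out += b"\x0d"
    for rec in records:
        out += b" "
        for f in fields:
            out += _encode_cell(rec.attrs.get(f.name), f)
    out += b"\x1a"
    return out


def _encode_cell(value: object, f: FieldDef) -> bytes:
    if f.ftype == "N":
        if value is None:
            text = ""
        elif f.decimals:
            text = f"{float(value):.{f.decimals}f}"
        else:
            text = str(int(value))
        text = text.rjust(f.length)
    else:
        text = "" if value is None else str(value)
        text = text.ljust(f.length)
    if len(text) > f.length:
        raise ValueError(f"value {value!r} exceeds width {f.length} of field {f.name}")
    return text.encode("ascii")
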