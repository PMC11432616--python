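"""Minimal ASCII VTK XML PolyData (.vtp) reader/writer.

Supports points plus either triangles (``<Polys>``) or polylines
(``<Lines>``), with optional scalar point data — enough to exchange surfaces,
isoline contours and centerlines with standard visualisation tools.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

__all__ = ["write_polydata", "read_polydata", "write_polylines", "read_polylines"]


def _data_array(parent, name, values, dtype, ncomp=None):
    el = ET.SubElement(parent, "DataArray", {
        "type": dtype, "format": "ascii",
        **({"Name": name} if name else {}),
        **({"NumberOfComponents": str(ncomp)} if ncomp else {}),
    })
    el.text = " ".join(map(str, np.asarray(values).ravel().tolist()))
    return el


def _write(path, points, cells, cell_tag, count_attr, point_scalars=None):
    points = np.asarray(points, dtype=np.float64)
    root = ET.Element("VTKFile", {"type": "PolyData", "version": "0.1",
                                  "byte_order": "LittleEndian"})
    poly = ET.SubElement(root, "PolyData")
    piece = ET.SubElement(poly, "Piece", {
        "NumberOfPoints": str(len(points)),
        count_attr: str(len(cells)),
    })
    pts = ET.SubElement(piece, "Points")
    _data_array(pts, None, points, "Float64", ncomp=3)
    if point_scalars:
        pd = ET.SubElement(piece, "PointData")
        for name, values in point_scalars.items():
            _data_array(pd, name, np.asarray(values, dtype=np.float64), "Float64")
    cell_el = ET.SubElement(piece, cell_tag)
    connectivity = np.concatenate([np.asarray(c).ravel() for c in cells]) \
        if cells else np.empty(0, dtype=np.int64)
    offsets = np.cumsum([len(np.asarray(c).ravel()) for c in cells]) \
        if cells else np.empty(0, dtype=np.int64)
    _data_array(cell_el, "connectivity", connectivity.astype(np.int64), "Int64")
    _data_array(cell_el, "offsets", offsets.astype(np.int64), "Int64")
    ET.indent(root)
    Path(path).write_bytes(ET.tostring(root, xml_declaration=True))


def write_polydata(path, points, polys, point_scalars=None):
    """Write points + triangles."""
    polys = np.asarray(polys, dtype=np.int64)
    _write(path, points, list(polys), "Polys", "NumberOfPolys", point_scalars)


def write_polylines(path, points, lines, point_scalars=None):
    """Write points + polylines (``lines`` is a list of index arrays)."""
    _write(path, points, [np.asarray(l, dtype=np.int64) for l in lines],
           "Lines", "NumberOfLines", point_scalars)


def _read(path):
    root = ET.parse(str(path)).getroot()
    piece = root.find("./PolyData/Piece")
    if piece is None:
        raise ValueError(f"{path}: not a VTP PolyData file")
    pts_el = piece.find("./Points/DataArray")
    points = _parse_floats(pts_el.text).reshape(-1, 3)
    return piece, points


def _parse_floats(text):
    return np.array((text or "").split(), dtype=np.float64)


def _read_cells(piece, tag):
    el = piece.find(f"./{tag}")
    if el is None:
        return None
    arrays = {a.get("Name"): _parse_floats(a.text).astype(np.int64)
              for a in el.findall("DataArray")}
    conn, offs = arrays.get("connectivity"), arrays.get("offsets")
    if conn is None or offs is None or len(offs) == 0:
        return None
    cells, start = [], 0
    for off in offs:
        cells.append(conn[start:off])
        start = off
    return cells


def read_polydata(path):
    """Return ``(points, faces)``; ``faces`` is None if the file has no polys."""
    piece, points = _read(path)
    cells = _read_cells(piece, "Polys")
    if cells is None:
        return points, None
    if any(len(c) != 3 for c in cells):
        raise ValueError(f"{path}: non-triangular polys are not supported")
    return points, np.vstack(cells)


def read_polylines(path):
    """Return ``(points, lines)`` where lines is a list of index arrays."""
    piece, points = _read(path)
    return points, (_read_cells(piece, "Lines") or [])
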