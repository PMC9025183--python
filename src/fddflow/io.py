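"""File formats: VTU meshes/fields, waveform CSV, JSON reports.

Meshes travel as ASCII VTU (VTK unstructured grid XML): triangles carry the
``region`` cell array, and every labelled boundary or measurement facet is
written as an additional line cell with a ``label`` code and, for oriented
surfaces, a ``surface_normal`` vector.  The writer embeds the mesh metadata
as a JSON comment that the reader restores and any other VTK tool ignores,
so files stay viewable in ParaView while round-tripping losslessly here.

Waveforms are two-column CSV (time s, velocity m/s).  Pipeline reports are
JSON validated against a small declarative schema.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import (AXISYMMETRIC, GeometrySpec, Mesh, PLANAR_2D, Scenario)
from .hemodynamics import FlowField, Waveform

_LABEL_CODES = {"INLET": 10, "OUTLET": 11, "WALL": 12, "AXIS": 13,
                "NECK": 20, "STENT_SURFACE": 21}
_CODE_LABELS = {v: k for k, v in _LABEL_CODES.items()}
_SURFACE_LABELS = {"NECK", "STENT_SURFACE"}


class FormatError(ValueError):
    """Malformed file content."""


def _fmt(a: np.ndarray) -> str:
    return " ".join(repr(x) if isinstance(x, float) else str(x)
                    for x in np.asarray(a).ravel().tolist())


def _meta_to_json(meta: dict) -> str:
    out = {}
    for k, v in meta.items():
        if isinstance(v, GeometrySpec):
            d = {f: getattr(v, f) for f in (
                "parent_radius", "parent_length", "dome_radius",
                "neck_width", "stent_thickness", "resolution",
                "stent_extent")}
            d["scenario"] = v.scenario.name
            out[k] = {"__geometry_spec__": d}
        elif isinstance(v, (tuple, list)):
            out[k] = list(v)
        else:
            out[k] = v
    return json.dumps(out)


def _meta_from_json(s: str) -> dict:
    raw = json.loads(s)
    out = {}
    for k, v in raw.items():
        if isinstance(v, dict) and "__geometry_spec__" in v:
            d = dict(v["__geometry_spec__"])
            d["scenario"] = Scenario[d["scenario"]]
            out[k] = GeometrySpec(**d)
        elif k == "x_neck" and isinstance(v, list):
            out[k] = tuple(v)
        else:
            out[k] = v
    return out


def write_mesh(path, mesh: Mesh, flow: FlowField | None = None) -> None:
    """Write mesh (and optionally a flow snapshot) as ASCII VTU."""
    path = Path(path)
    ntri = mesh.n_cells
    lines = []
    for group in (mesh.boundary, mesh.surfaces):
        for label, facets in sorted(group.items()):
            normals = mesh.surface_normals.get(label)
            for i, (a, b) in enumerate(facets):
                n = (0.0, 0.0) if normals is None else tuple(normals[i])
                lines.append((int(a), int(b), _LABEL_CODES[label], n))
    ncell = ntri + len(lines)

    conn = [" ".join(map(str, tri)) for tri in mesh.cells]
    conn += [f"{a} {b}" for a, b, _, _ in lines]
    offsets = np.concatenate([3 * np.arange(1, ntri + 1),
                              3 * ntri + 2 * np.arange(1, len(lines) + 1)])
    types = np.concatenate([np.full(ntri, 5), np.full(len(lines), 3)])
    region = np.concatenate([mesh.cell_region, np.full(len(lines), -1)])
    label = np.concatenate([np.full(ntri, -1),
                            np.array([c for _, _, c, _ in lines], dtype=int)
                            if lines else np.empty(0, dtype=int)])
    normals3 = np.zeros((ncell, 3))
    for i, (_, _, _, n) in enumerate(lines):
        normals3[ntri + i, :2] = n
    pts3 = np.column_stack([mesh.nodes, np.zeros(len(mesh.nodes))])

    mode_code = 1 if mesh.mode == AXISYMMETRIC else 0
    parts = [
        '<?xml version="1.0"?>',
        f'<!--fddflow:meta {_meta_to_json(mesh.meta)}-->',
        f'<!--fddflow:mode {mode_code}-->',
        '<VTKFile type="UnstructuredGrid" version="0.1" '
        'byte_order="LittleEndian">',
        ' <UnstructuredGrid>',
        f'  <Piece NumberOfPoints="{mesh.n_nodes}" '
        f'NumberOfCells="{ncell}">',
        '   <Points>',
        '    <DataArray type="Float64" NumberOfComponents="3" '
        f'format="ascii">{_fmt(pts3)}</DataArray>',
        '   </Points>',
        '   <Cells>',
        '    <DataArray type="Int64" Name="connectivity" format="ascii">'
        + " ".join(conn) + '</DataArray>',
        '    <DataArray type="Int64" Name="offsets" format="ascii">'
        + _fmt(offsets) + '</DataArray>',
        '    <DataArray type="UInt8" Name="types" format="ascii">'
        + _fmt(types) + '</DataArray>',
        '   </Cells>',
        '   <CellData>',
        '    <DataArray type="Int64" Name="region" format="ascii">'
        + _fmt(region) + '</DataArray>',
        '    <DataArray type="Int64" Name="label" format="ascii">'
        + _fmt(label) + '</DataArray>',
        '    <DataArray type="Float64" Name="surface_normal" '
        'NumberOfComponents="3" format="ascii">'
        + _fmt(normals3) + '</DataArray>',
        '   </CellData>',
    ]
    if flow is not None:
        vel3 = np.column_stack([flow.u[:mesh.n_nodes],
                                np.zeros(mesh.n_nodes)])
        parts += [
            '   <PointData>',
            '    <DataArray type="Float64" Name="velocity" '
            'NumberOfComponents="3" format="ascii">'
            + _fmt(vel3) + '</DataArray>',
            '    <DataArray type="Float64" Name="pressure" format="ascii">'
            + _fmt(flow.p) + '</DataArray>',
            '   </PointData>',
        ]
        # quadratic edge dofs + viscosity, for lossless reload (ignored by
        # generic VTK readers; edge ordering is reproducible from cells)
        parts.insert(2, '<!--fddflow:time ' + repr(float(flow.t)) + '-->')
        parts.insert(2, '<!--fddflow:edge_velocity '
                     + _fmt(flow.u[mesh.n_nodes:]) + '-->')
        if flow.mu_cell is not None:
            parts.insert(2, '<!--fddflow:mu_cell '
                         + _fmt(flow.mu_cell) + '-->')
    parts += ['  </Piece>', ' </UnstructuredGrid>', '</VTKFile>', '']
    path.write_text("\n".join(parts))


def _get_array(text: str, name: str) -> np.ndarray:
    m = re.search(rf'Name="{name}"[^>]*>(.*?)</DataArray>', text, re.S)
    if m is None:
        raise FormatError(f"missing DataArray {name!r}")
    return np.fromstring(m.group(1), sep=" ")


def read_mesh(path) -> Mesh:
    """Read a mesh written by :func:`write_mesh`."""
    text = Path(path).read_text()
    mm = re.search(r'<!--fddflow:meta (.*?)-->', text, re.S)
    meta = _meta_from_json(mm.group(1)) if mm else {}
    mo = re.search(r'<!--fddflow:mode (\d)-->', text)
    mode = AXISYMMETRIC if (mo and mo.group(1) == "1") else PLANAR_2D

    mp = re.search(r'<Points>.*?format="ascii">(.*?)</DataArray>', text, re.S)
    if mp is None:
        raise FormatError("missing Points block")
    pts = np.fromstring(mp.group(1), sep=" ").reshape(-1, 3)[:, :2]
    conn = _get_array(text, "connectivity").astype(np.int64)
    offsets = _get_array(text, "offsets").astype(np.int64)
    types = _get_array(text, "types").astype(int)
    region_all = _get_array(text, "region").astype(np.int64)
    label_all = _get_array(text, "label").astype(np.int64)
    normal_all = _get_array(text, "surface_normal").reshape(-1, 3)[:, :2]

    cells, region = [], []
    boundary: dict[str, list] = {}
    surfaces: dict[str, list] = {}
    surface_normals: dict[str, list] = {}
    start = 0
    for i, (off, typ) in enumerate(zip(offsets, types)):
        ids = conn[start:off]
        start = off
        if typ == 5:
            cells.append(ids)
            region.append(region_all[i])
        elif typ == 3:
            lab = _CODE_LABELS.get(int(label_all[i]))
            if lab is None:
                raise FormatError(f"unknown facet label code {label_all[i]}")
            if lab in _SURFACE_LABELS:
                surfaces.setdefault(lab, []).append(ids)
                surface_normals.setdefault(lab, []).append(normal_all[i])
            else:
                boundary.setdefault(lab, []).append(ids)
        else:
            raise FormatError(f"unsupported VTK cell type {typ}")
    mesh = Mesh(
        nodes=pts,
        cells=np.asarray(cells, dtype=np.int64),
        cell_region=np.asarray(region, dtype=np.int64),
        boundary={k: np.asarray(v, dtype=np.int64)
                  for k, v in boundary.items()},
        surfaces={k: np.asarray(v, dtype=np.int64)
                  for k, v in surfaces.items()},
        surface_normals={k: np.asarray(v) for k, v in surface_normals.items()},
        mode=mode, meta=meta)
    return mesh


def read_flow(path, mesh: Mesh | None = None) -> FlowField:
    """Reload a flow snapshot written with ``write_mesh(..., flow=...)``.

    The quadratic edge velocities are restored from the embedded comment;
    the edge ordering is reconstructed deterministically from the cell
    connectivity.
    """
    if mesh is None:
        mesh = read_mesh(path)
    text = Path(path).read_text()
    vm = re.search(r'Name="velocity"[^>]*>(.*?)</DataArray>', text, re.S)
    pm = re.search(r'Name="pressure"[^>]*>(.*?)</DataArray>', text, re.S)
    em = re.search(r'<!--fddflow:edge_velocity (.*?)-->', text, re.S)
    if vm is None or pm is None or em is None:
        raise FormatError(f"{path}: no stored flow snapshot")
    uv = np.fromstring(vm.group(1), sep=" ").reshape(-1, 3)[:, :2]
    ue = np.fromstring(em.group(1), sep=" ").reshape(-1, 2)
    p = np.fromstring(pm.group(1), sep=" ")
    tm = re.search(r'<!--fddflow:time (.*?)-->', text)
    mum = re.search(r'<!--fddflow:mu_cell (.*?)-->', text, re.S)
    mu = np.fromstring(mum.group(1), sep=" ") if mum else None
    return FlowField(mesh=mesh, u=np.vstack([uv, ue]), p=p,
                     t=float(tm.group(1)) if tm else 0.0, mu_cell=mu)


def write_waveform_csv(path, waveform: Waveform) -> None:
    pd.DataFrame({"time": waveform.times,
                  "velocity": waveform.velocities}).to_csv(path, index=False)


def read_waveform_csv(path, period: float | None = None) -> Waveform:
    """Read a two-column (time, velocity) CSV; times must be sorted."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if "time" not in cols or "velocity" not in cols:
        raise FormatError(f"{path}: expected columns time, velocity")
    df.columns = cols
    t = df["time"].to_numpy(dtype=float)
    v = df["velocity"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise FormatError(f"{path}: sample times must be strictly "
                          "increasing")
    if period is None:
        period = float(t[-1] - t[0]) if len(t) > 1 else 1.0
    return Waveform(times=t, velocities=v, period=period)


#: Declarative schema of the pipeline report (field -> type or nested dict).
REPORT_SCHEMA = {
    "scenario": str,
    "outcome": str,
    "max_dwss": {"t1": float, "t2": float, "t3": float, "t4": float},
    "rsi": dict,
    "inflow": dict,
    "steady": dict,
    "thresholds": {"theta_stenosis": float, "theta_occlusion": float},
    "histogram": dict,
}


def validate_report(report: dict, schema: dict = REPORT_SCHEMA,
                    where: str = "report") -> None:
    """Raise FormatError if the report does not match the schema."""
    if not isinstance(report, dict):
        raise FormatError(f"{where}: expected object")
    for key, want in schema.items():
        if key not in report:
            raise FormatError(f"{where}: missing key {key!r}")
        val = report[key]
        if isinstance(want, dict):
            if want and all(isinstance(v, (type, dict))
                            for v in want.values()):
                validate_report(val, want, f"{where}.{key}")
            elif not isinstance(val, dict):
                raise FormatError(f"{where}.{key}: expected object")
        elif want is float:
            if not isinstance(val, (int, float)):
                raise FormatError(f"{where}.{key}: expected number")
        elif not isinstance(val, want):
            raise FormatError(f"{where}.{key}: expected {want.__name__}")


def write_report(path, report: dict) -> None:
    validate_report(report)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))


def read_report(path) -> dict:
    report = json.loads(Path(path).read_text())
    validate_report(report)
    return report
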