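"""Mesh and artifact I/O: ASCII VTU (XML unstructured grid) and Gmsh MSH 4.1.

The VTU writer stores tets with the subdomain label as the cell-data array
"subdomain" plus the refinement level as field data; the MSH writer groups
elements into one entity block per subdomain with the label as the entity
tag. Both round-trip nodes, connectivity and labels exactly. Externally
produced labeled tet meshes (e.g. segmented anatomical models) can be read
through the same functions.
"""

from __future__ import annotations

import json
import os
import xml.etree.ElementTree as ET

import numpy as np

from .geometry import REFINEMENT_LEVELS, ElectrodeLayout, HeartTorsoMesh

__all__ = ["read_mesh", "write_mesh", "write_vtu_fields",
           "write_electrodes", "read_electrodes"]


class MeshIOError(IOError):
    pass


def write_mesh(mesh: HeartTorsoMesh, path: str) -> None:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".vtu":
        _write_vtu(mesh, path)
    elif ext == ".msh":
        _write_msh(mesh, path)
    else:
        raise MeshIOError(f"unsupported mesh format {ext!r} (use .vtu or .msh)")


def read_mesh(path: str) -> HeartTorsoMesh:
    ext = os.path.splitext(path)[1].lower()
    if ext == ".vtu":
        return _read_vtu(path)
    if ext == ".msh":
        return _read_msh(path)
    raise MeshIOError(f"unsupported mesh format {ext!r} (use .vtu or .msh)")


# -- VTU --------------------------------------------------------------------

def _fmt(arr, per_line=6):
    flat = np.asarray(arr).reshape(-1)
    if flat.dtype.kind == "f":
        strs = [f"{x:.17g}" for x in flat]
    else:
        strs = [str(int(x)) for x in flat]
    lines = [" ".join(strs[i:i + per_line]) for i in range(0, len(strs), per_line)]
    return "\n".join(lines)


def _write_vtu(mesh: HeartTorsoMesh, path: str, cell_data=None, point_data=None):
    nn, ne = mesh.n_nodes, mesh.n_tets
    parts = []
    w = parts.append
    w('<?xml version="1.0"?>')
    w('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    w("<UnstructuredGrid>")
    lvl = REFINEMENT_LEVELS.index(mesh.refinement_level)
    w('<FieldData><DataArray type="Int32" Name="refinement_level" '
      f'NumberOfTuples="1" format="ascii">{lvl}</DataArray></FieldData>')
    w(f'<Piece NumberOfPoints="{nn}" NumberOfCells="{ne}">')
    w('<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    w(_fmt(mesh.nodes))
    w("</DataArray></Points>")
    w("<Cells>")
    w('<DataArray type="Int64" Name="connectivity" format="ascii">')
    w(_fmt(mesh.tets))
    w("</DataArray>")
    w('<DataArray type="Int64" Name="offsets" format="ascii">')
    w(_fmt(np.arange(1, ne + 1) * 4))
    w("</DataArray>")
    w('<DataArray type="UInt8" Name="types" format="ascii">')
    w(_fmt(np.full(ne, 10)))
    w("</DataArray>")
    w("</Cells>")
    w("<CellData>")
    w('<DataArray type="Int32" Name="subdomain" format="ascii">')
    w(_fmt(mesh.labels))
    w("</DataArray>")
    for name, arr in (cell_data or {}).items():
        w(f'<DataArray type="Float64" Name="{name}" format="ascii">')
        w(_fmt(np.asarray(arr, float)))
        w("</DataArray>")
    w("</CellData>")
    if point_data:
        w("<PointData>")
        for name, arr in point_data.items():
            w(f'<DataArray type="Float64" Name="{name}" format="ascii">')
            w(_fmt(np.asarray(arr, float)))
            w("</DataArray>")
        w("</PointData>")
    w("</Piece></UnstructuredGrid></VTKFile>")
    with open(path, "w") as f:
        f.write("\n".join(parts))


def _read_vtu(path: str) -> HeartTorsoMesh:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise MeshIOError(f"malformed VTU file {path}: {exc}") from exc
    root = tree.getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshIOError(f"{path}: no UnstructuredGrid piece")

    def arr(xpath, name=None, dtype=float):
        for da in piece.findall(xpath):
            if name is None or da.get("Name") == name:
                return np.array(da.text.split(), dtype=float).astype(dtype)
        raise MeshIOError(f"{path}: missing array {name or xpath}")

    nodes = arr("Points/DataArray").reshape(-1, 3)
    conn = arr("Cells/DataArray", "connectivity", np.int64)
    offsets = arr("Cells/DataArray", "offsets", np.int64)
    types = arr("Cells/DataArray", "types", np.int64)
    if not np.all(types == 10):
        raise MeshIOError(f"{path}: only linear tetrahedra (VTK type 10) supported")
    if not np.all(np.diff(np.concatenate([[0], offsets])) == 4):
        raise MeshIOError(f"{path}: non-tetrahedral connectivity offsets")
    tets = conn.reshape(-1, 4)
    labels = arr("CellData/DataArray", "subdomain", np.int32)
    lvl = 0
    fd = root.find(".//FieldData/DataArray[@Name='refinement_level']")
    if fd is not None and fd.text:
        lvl = int(fd.text.strip())
    return HeartTorsoMesh(nodes, tets, labels, REFINEMENT_LEVELS[lvl])


def write_vtu_fields(mesh: HeartTorsoMesh, path: str, point_data: dict) -> None:
    """Write the mesh with nodal field arrays (Vm, Ve, V, v) for visualization."""
    _write_vtu(mesh, path, point_data=point_data)


# -- Gmsh MSH 4.1 -----------------------------------------------------------

def _write_msh(mesh: HeartTorsoMesh, path: str):
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]
    lvl = REFINEMENT_LEVELS.index(mesh.refinement_level)
    lines += ["$Comments", f"refinement_level {lvl}", "$EndComments"]
    nn = mesh.n_nodes
    lines += ["$Nodes", f"1 {nn} 1 {nn}", f"3 1 0 {nn}"]
    lines += [str(i + 1) for i in range(nn)]
    lines += [f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in mesh.nodes]
    lines.append("$EndNodes")
    labels = np.unique(mesh.labels)
    ne = mesh.n_tets
    lines += ["$Elements", f"{len(labels)} {ne} 1 {ne}"]
    eid = 1
    for lb in labels:
        sel = mesh.tets[mesh.labels == lb]
        lines.append(f"3 {int(lb)} 4 {len(sel)}")
        for t in sel:
            lines.append(f"{eid} {t[0]+1} {t[1]+1} {t[2]+1} {t[3]+1}")
            eid += 1
    lines.append("$EndElements")
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def _read_msh(path: str) -> HeartTorsoMesh:
    with open(path) as f:
        txt = f.read().split("\n")
    i = 0
    nodes = None
    tets, labels = [], []
    lvl = 0
    n = len(txt)
    while i < n:
        line = txt[i].strip()
        if line == "$Comments":
            i += 1
            while txt[i].strip() != "$EndComments":
                parts = txt[i].split()
                if parts and parts[0] == "refinement_level":
                    lvl = int(parts[1])
                i += 1
        elif line == "$Nodes":
            header = txt[i + 1].split()
            nblocks, total = int(header[0]), int(header[1])
            i += 2
            coords = np.empty((total, 3))
            tag2idx = {}
            filled = 0
            for _ in range(nblocks):
                bn = int(txt[i].split()[3])
                tags = [int(txt[i + 1 + j]) for j in range(bn)]
                for j in range(bn):
                    xyz = txt[i + 1 + bn + j].split()
                    coords[filled] = [float(x) for x in xyz[:3]]
                    tag2idx[tags[j]] = filled
                    filled += 1
                i += 1 + 2 * bn
            nodes = coords
        elif line == "$Elements":
            header = txt[i + 1].split()
            nblocks = int(header[0])
            i += 2
            for _ in range(nblocks):
                bh = txt[i].split()
                etag, etype, bn = int(bh[1]), int(bh[2]), int(bh[3])
                if etype != 4:
                    raise MeshIOError(f"{path}: only 4-node tets supported, got type {etype}")
                for j in range(bn):
                    parts = txt[i + 1 + j].split()
                    tets.append([tag2idx[int(x)] for x in parts[1:5]])
                    labels.append(etag)
                i += 1 + bn
        i += 1
    if nodes is None or not tets:
        raise MeshIOError(f"{path}: missing $Nodes or $Elements section")
    return HeartTorsoMesh(nodes, np.asarray(tets, np.int64),
                          np.asarray(labels, np.int32), REFINEMENT_LEVELS[lvl])


# -- electrode layout -------------------------------------------------------

def write_electrodes(layout: ElectrodeLayout, path: str) -> None:
    with open(path, "w") as f:
        json.dump(layout.to_dict(), f, indent=1)


def read_electrodes(path: str) -> ElectrodeLayout:
    with open(path) as f:
        d = json.load(f)
    names = list(d["probes"])
    positions = {k: np.asarray(v, float) for k, v in d["probes"].items()}
    node_ids = {k: int(v) for k, v in d["nodes"].items()}
    return ElectrodeLayout(names, positions, node_ids, d.get("ground_probe", "RL"))
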