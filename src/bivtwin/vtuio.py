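"""Plain-text serialization of meshes, trees and signals.

Meshes go to ASCII VTU (the unstructured-grid XML flavour readable by
ParaView and friends) with any number of named point-data arrays;
Purkinje trees to a JSON adjacency file; multi-channel signals to
delimited text with a JSON sidecar carrying the sampling rate, channel
names and fiducials.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from lxml import etree

from bivtwin.mesh import Mesh
from bivtwin.synthetic import MultiLeadSignal

__all__ = ["write_vtu", "read_vtu", "write_tree_json", "read_tree_json",
           "write_signal_txt", "read_signal_txt"]

VTK_TETRA = 10


def write_vtu(path, mesh: Mesh, point_data: dict | None = None) -> None:
    """Write a tetrahedral mesh (and per-node arrays) as ASCII VTU.

    Surface tags are stored as 0/1 indicator arrays named ``tag_<name>``.
    """
    n_pts, n_cells = mesh.n_nodes, mesh.n_tets
    root = etree.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                         byte_order="LittleEndian")
    grid = etree.SubElement(root, "UnstructuredGrid")
    piece = etree.SubElement(grid, "Piece", NumberOfPoints=str(n_pts),
                             NumberOfCells=str(n_cells))

    pdata = etree.SubElement(piece, "PointData")
    arrays = dict(point_data or {})
    for name, ids in mesh.surface_tags.items():
        ind = np.zeros(n_pts, dtype=np.int64)
        ind[ids] = 1
        arrays[f"tag_{name}"] = ind
    for name, arr in arrays.items():
        arr = np.asarray(arr)
        ncomp = 1 if arr.ndim == 1 else arr.shape[1]
        da = etree.SubElement(pdata, "DataArray", type="Float64", Name=name,
                              NumberOfComponents=str(ncomp), format="ascii")
        da.text = " ".join(f"{v:.10g}" for v in np.asarray(arr, float).ravel())

    pts = etree.SubElement(piece, "Points")
    da = etree.SubElement(pts, "DataArray", type="Float64",
                          NumberOfComponents="3", format="ascii")
    da.text = " ".join(f"{v:.10g}" for v in mesh.nodes.ravel())

    cells = etree.SubElement(piece, "Cells")
    conn = etree.SubElement(cells, "DataArray", type="Int64",
                            Name="connectivity", format="ascii")
    conn.text = " ".join(str(v) for v in mesh.tets.ravel())
    offs = etree.SubElement(cells, "DataArray", type="Int64", Name="offsets",
                            format="ascii")
    offs.text = " ".join(str(4 * (i + 1)) for i in range(n_cells))
    typ = etree.SubElement(cells, "DataArray", type="UInt8", Name="types",
                           format="ascii")
    typ.text = " ".join(str(VTK_TETRA) for _ in range(n_cells))

    Path(path).write_bytes(etree.tostring(root, xml_declaration=True,
                                          encoding="UTF-8", pretty_print=True))


def read_vtu(path) -> tuple[Mesh, dict]:
    """Read an ASCII VTU written by :func:`write_vtu`.

    Returns ``(mesh, point_data)``; ``tag_*`` arrays are restored into
    the mesh's surface tags.
    """
    root = etree.parse(str(path)).getroot()
    piece = root.find(".//{*}Piece") if root.find(".//{*}Piece") is not None \
        else root.find(".//Piece")
    if piece is None:
        piece = root.xpath("//*[local-name()='Piece']")[0]

    def grab(parent_name, array_name=None):
        for el in piece.iter():
            tag = etree.QName(el).localname
            if tag != "DataArray":
                continue
            parent = etree.QName(el.getparent()).localname
            if parent != parent_name:
                continue
            if array_name is None or el.get("Name") == array_name:
                return el
        return None

    pts_el = grab("Points")
    nodes = np.array(pts_el.text.split(), dtype=float).reshape(-1, 3)
    conn = np.array(grab("Cells", "connectivity").text.split(),
                    dtype=np.int64).reshape(-1, 4)
    point_data, tags = {}, {}
    for el in piece.iter():
        if etree.QName(el).localname != "DataArray":
            continue
        if etree.QName(el.getparent()).localname != "PointData":
            continue
        name = el.get("Name")
        ncomp = int(el.get("NumberOfComponents", "1"))
        arr = np.array(el.text.split(), dtype=float)
        if ncomp > 1:
            arr = arr.reshape(-1, ncomp)
        if name.startswith("tag_"):
            tags[name[4:]] = np.flatnonzero(arr.astype(int) == 1)
        else:
            point_data[name] = arr
    return Mesh(nodes, conn, tags), point_data


def write_tree_json(path, tree) -> None:
    payload = {
        "nodes": tree.nodes.tolist(),
        "segments": tree.segments.tolist(),
        "root": int(tree.root),
        "terminals": tree.terminals.tolist(),
        "depth_label": tree.depth_label.tolist(),
        "branch_id": None if tree.branch_id is None else tree.branch_id.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_tree_json(path):
    from bivtwin.conduction import PurkinjeTree

    d = json.loads(Path(path).read_text())
    return PurkinjeTree(np.array(d["nodes"]), np.array(d["segments"], dtype=np.int64),
                        root=d["root"],
                        terminals=np.array(d["terminals"], dtype=np.int64),
                        depth_label=np.array(d["depth_label"], dtype=np.int64),
                        branch_id=None if d["branch_id"] is None
                        else np.array(d["branch_id"], dtype=np.int64))


def write_signal_txt(path, sig: MultiLeadSignal) -> None:
    """One column per channel; JSON sidecar ``<path>.json`` with metadata."""
    path = Path(path)
    header = "\t".join(sig.channel_names)
    np.savetxt(path, sig.samples.T, delimiter="\t", header=header, comments="")
    meta = {"sampling_rate": sig.sampling_rate,
            "channel_names": list(sig.channel_names),
            "fiducials": None if sig.fiducials is None else sig.fiducials.tolist()}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_signal_txt(path) -> MultiLeadSignal:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.loadtxt(path, delimiter="\t", skiprows=1)
    return MultiLeadSignal(np.atleast_2d(data.T), meta["sampling_rate"],
                           meta["channel_names"],
                           fiducials=None if meta["fiducials"] is None
                           else np.array(meta["fiducials"]))
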