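"""RSML (Root System Markup Language) export and import.

Snapshots are written as one RSML scene per file with one ``<plant>``; axile
roots are top-level ``<root>`` elements and laterals are nested under their
parent.  Because the growth model tracks topology, lengths, radii and ages
but not 3D geometry, straight-line coordinates are fabricated on export:
axes descend vertically (z < 0), each offset along x, and laterals extend
horizontally from their branch point.  The root type is stored as a
standard ``type`` property, the attachment is recorded as a 0-based
``parent-node`` property, and per-node ``diameter`` and ``creation_time``
functions carry the quantitative data, so a round trip preserves the
segment table semantically (topology, lengths, radii, ages).
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
from lxml import etree

from .architecture import ROOT_TYPES, TYPE_CODE, RootSystem

__all__ = ["write_rsml", "read_rsml"]

_FMT = "%.10g"


class RSMLParseError(ValueError):
    """Raised on malformed RSML input, with element context."""


def _roots_of(system: RootSystem) -> dict[int, list[int]]:
    """root_id -> ordered list of segment indices (creation order)."""
    out: dict[int, list[int]] = defaultdict(list)
    for i, rid in enumerate(system.root_id):
        out[int(rid)].append(i)
    return out


def write_rsml(system: RootSystem, path) -> None:
    """Write one snapshot to an RSML file."""
    rsml = etree.Element("rsml")
    meta = etree.SubElement(rsml, "metadata")
    etree.SubElement(meta, "version").text = "1"
    etree.SubElement(meta, "unit").text = "m"
    etree.SubElement(meta, "software").text = "rhizoflow"
    etree.SubElement(meta, "last-modified").text = ""
    prop = etree.SubElement(meta, "property-definitions")
    for name, typ in (("type", "string"), ("parent-node", "integer")):
        d = etree.SubElement(prop, "property-definition")
        etree.SubElement(d, "label").text = name
        etree.SubElement(d, "type").text = typ
    scene = etree.SubElement(rsml, "scene")
    plant = etree.SubElement(scene, "plant", id="1", label="wheat")
    plant.set("time", _FMT % system.simulation_time)
    if system.seed is not None:
        plant.set("seed", str(system.seed))

    segs_by_root = _roots_of(system)
    # map segment index -> (root element, node index within that root)
    node_of_seg: dict[int, tuple[etree._Element, int]] = {}
    root_elems: dict[int, etree._Element] = {}

    # axile roots first (their first segment has parent -1), then laterals
    order = sorted(
        segs_by_root,
        key=lambda rid: (int(system.parent_index[segs_by_root[rid][0]]) >= 0, rid),
    )
    x_axile = 0.0
    for rid in order:
        seg_idx = segs_by_root[rid]
        first = seg_idx[0]
        p = int(system.parent_index[first])
        rtype = ROOT_TYPES[int(system.type_code[first])]
        if p < 0:
            parent_elem = plant
            x0, y0, z0 = x_axile, 0.0, 0.0
            x_axile += 0.02
            direction = (0.0, 0.0, -1.0)
            parent_node = -1
        else:
            parent_elem, parent_node = node_of_seg[p]
            # branch point: fabricate horizontal growth in +y
            pts = parent_elem.find("geometry/polyline")
            pt = pts[parent_node]
            x0 = float(pt.get("x")); y0 = float(pt.get("y")); z0 = float(pt.get("z"))
            direction = (0.0, 1.0, 0.0)
        root = etree.SubElement(parent_elem, "root", ID=str(rid), label=rtype)
        root_elems[rid] = root
        props = etree.SubElement(root, "properties")
        etree.SubElement(props, "type").text = rtype
        etree.SubElement(props, "parent-node").text = str(parent_node)
        geom = etree.SubElement(root, "geometry")
        poly = etree.SubElement(geom, "polyline")
        fns = etree.SubElement(root, "functions")
        f_diam = etree.SubElement(fns, "function", name="diameter", domain="polyline")
        f_ct = etree.SubElement(fns, "function", name="creation_time", domain="polyline")

        def add_point(x, y, z, diam, ct):
            etree.SubElement(poly, "point", x=_FMT % x, y=_FMT % y, z=_FMT % z)
            etree.SubElement(f_diam, "sample", value=_FMT % diam)
            etree.SubElement(f_ct, "sample", value=_FMT % ct)

        first_ct = float(system.creation_time[first])
        add_point(x0, y0, z0, 2 * float(system.radius[first]), first_ct)
        dist = 0.0
        for k, si in enumerate(seg_idx):
            dist += float(system.length[si])
            add_point(
                x0 + direction[0] * dist,
                y0 + direction[1] * dist,
                z0 + direction[2] * dist,
                2 * float(system.radius[si]),
                float(system.creation_time[si]),
            )
            node_of_seg[si] = (root, k + 1)

    tree = etree.ElementTree(rsml)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True)


def read_rsml(path) -> RootSystem:
    """Read an RSML file written by :func:`write_rsml` back into a RootSystem."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise RSMLParseError(f"{path}: {exc}") from exc
    rsml = tree.getroot()
    plant = rsml.find("scene/plant")
    if plant is None:
        raise RSMLParseError(f"{path}: no <scene>/<plant> element")
    sim_time = float(plant.get("time", "0"))
    seed = plant.get("seed")
    seed = int(seed) if seed is not None else None

    parent_l: list[int] = []
    root_l: list[int] = []
    type_l: list[int] = []
    len_l: list[float] = []
    rad_l: list[float] = []
    ct_l: list[float] = []
    rows: list[tuple] = []  # (creation_time, order, payload) for re-sorting

    def walk(root_elem, parent_root_segments):
        rid = int(root_elem.get("ID"))
        rtype_el = root_elem.find("properties/type")
        if rtype_el is None or rtype_el.text not in TYPE_CODE:
            raise RSMLParseError(f"root ID={rid}: missing/unknown type property")
        rtype = TYPE_CODE[rtype_el.text]
        pn_el = root_elem.find("properties/parent-node")
        parent_node = int(pn_el.text) if pn_el is not None else -1
        pts = root_elem.findall("geometry/polyline/point")
        diam = [float(s.get("value"))
                for s in root_elem.findall("functions/function[@name='diameter']/sample")]
        ct = [float(s.get("value"))
              for s in root_elem.findall("functions/function[@name='creation_time']/sample")]
        if not (len(pts) == len(diam) == len(ct)) or len(pts) < 2:
            raise RSMLParseError(f"root ID={rid}: inconsistent polyline/functions")
        coords = np.array([[float(p.get("x")), float(p.get("y")), float(p.get("z"))]
                           for p in pts])
        seg_lengths = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        own_segments = []
        for k, L in enumerate(seg_lengths):
            if parent_node < 0 and k == 0:
                par = -1
            elif k == 0:
                par = parent_root_segments[parent_node - 1]
            else:
                par = own_segments[-1]
            payload = (par, rid, rtype, float(L), 0.5 * diam[k + 1], ct[k + 1])
            own_segments.append(("pending", len(rows)))
            rows.append([payload, None])
            own_segments[-1] = len(rows) - 1
        for child in root_elem.findall("root"):
            walk(child, own_segments)

    for top in plant.findall("root"):
        walk(top, [])

    # rows reference parents by row index; re-sort by creation time keeping a
    # stable order so the result is topologically ordered again
    order = sorted(range(len(rows)), key=lambda i: (rows[i][0][5], i))
    new_pos = {old: new for new, old in enumerate(order)}
    for old in order:
        par, rid, rtype, L, r, ct_v = rows[old][0]
        parent_l.append(new_pos[par] if par >= 0 else -1)
        root_l.append(rid)
        type_l.append(rtype)
        len_l.append(L)
        rad_l.append(r)
        ct_l.append(ct_v)

    return RootSystem(
        np.array(parent_l, dtype=np.int64),
        np.array(root_l, dtype=np.int64),
        np.array(type_l, dtype=np.int64),
        np.array(len_l, dtype=float),
        np.array(rad_l, dtype=float),
        np.array(ct_l, dtype=float),
        simulation_time=sim_time,
        seed=seed,
    )
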