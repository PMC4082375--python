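"""Graph interchange (JSON), structural validation and DOT export.

The on-disk format is a small versioned JSON document::

    {"format": "historygraph/v1",
     "vertices":    [{"id": "v1", "label": "ACGT" | null}, ...],
     "adjacencies": [[["v1", "head"], ["v2", "tail"]], ...],
     "branches":    [["parent", "child"], ...],
     "provenance":  {...}}          # optional free-form block

Serialisation is canonical (sorted ids, two-space indent) so documents
diff cleanly and write∘read / read∘write are identities up to key order.
A machine-readable description of the format ships as
``schema/graph-v1.json``.
"""

from __future__ import annotations

import json
from typing import IO, Optional, Union

from .core import HEAD, ORIENTATIONS, TAIL, HistoryGraph, Violation
from .lifting import FREE_ROOT_PREFIX, Lifting

FORMAT_TAG = "historygraph/v1"


class GraphFormatError(ValueError):
    """A malformed document; the message names the offending field."""


class GraphValidationError(ValueError):
    """A well-formed document describing an invalid history graph."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__("; ".join(str(v) for v in violations))


def _check(cond: bool, where: str, message: str) -> None:
    if not cond:
        raise GraphFormatError(f"{where}: {message}")


def graph_from_doc(doc: dict, validate: bool = True) -> HistoryGraph:
    """Build a history graph from a parsed document."""
    _check(isinstance(doc, dict), "$", "document must be a JSON object")
    tag = doc.get("format", FORMAT_TAG)
    _check(tag == FORMAT_TAG, "format", f"unsupported format {tag!r}")
    g = HistoryGraph()
    vertices = doc.get("vertices", [])
    _check(isinstance(vertices, list), "vertices", "must be a list")
    for i, v in enumerate(vertices):
        where = f"vertices[{i}]"
        _check(isinstance(v, dict) and "id" in v, where,
               'must be an object with an "id"')
        vid = v["id"]
        _check(isinstance(vid, str) and vid, where + ".id",
               "must be a non-empty string")
        _check(not vid.startswith(FREE_ROOT_PREFIX), where + ".id",
               f"the prefix {FREE_ROOT_PREFIX!r} is reserved")
        label = v.get("label")
        _check(label is None or isinstance(label, str), where + ".label",
               "must be a string or null")
        _check(vid not in g.labels, where + ".id", f"duplicate id {vid!r}")
        g.add_vertex(vid, label)

    def side(raw, where: str):
        _check(isinstance(raw, (list, tuple)) and len(raw) == 2, where,
               "a side is a [vertex, orientation] pair")
        vid, orientation = raw
        _check(vid in g.labels, where, f"unknown vertex {vid!r}")
        _check(orientation in ORIENTATIONS, where,
               f"orientation must be one of {ORIENTATIONS}, "
               f"got {orientation!r}")
        return (vid, orientation)

    adjacencies = doc.get("adjacencies", [])
    _check(isinstance(adjacencies, list), "adjacencies", "must be a list")
    for i, pair in enumerate(adjacencies):
        where = f"adjacencies[{i}]"
        _check(isinstance(pair, (list, tuple)) and len(pair) == 2, where,
               "an adjacency is a pair of sides")
        a = side(pair[0], where + "[0]")
        b = side(pair[1], where + "[1]")
        _check(a != b, where, "a side cannot pair with itself")
        g.add_adjacency(a, b, strict=False)

    branches = doc.get("branches", [])
    _check(isinstance(branches, list), "branches", "must be a list")
    for i, pair in enumerate(branches):
        where = f"branches[{i}]"
        _check(isinstance(pair, (list, tuple)) and len(pair) == 2, where,
               "a branch is a [parent, child] pair")
        p, c = pair
        for v in (p, c):
            _check(v in g.labels, where, f"unknown vertex {v!r}")
        g.add_branch(p, c, strict=False)

    if validate:
        violations = g.validate()
        if violations:
            raise GraphValidationError(violations)
    return g


def graph_to_doc(graph: HistoryGraph,
                 provenance: Optional[dict] = None) -> dict:
    """Canonical (sorted) document for a graph."""
    doc = {
        "format": FORMAT_TAG,
        "vertices": [{"id": v, "label": graph.label(v)}
                     for v in graph.vertices()],
        "adjacencies": [[list(a), list(b)]
                        for a, b in graph.adjacencies()],
        "branches": [list(b) for b in graph.branches()],
    }
    if provenance is not None:
        doc["provenance"] = provenance
    return doc


def read_graph(stream: Union[str, IO], validate: bool = True) -> HistoryGraph:
    """Read a graph from a path, file object or JSON string."""
    if isinstance(stream, str):
        if stream.lstrip().startswith("{"):
            doc = json.loads(stream)
        else:
            with open(stream) as fh:
                doc = json.load(fh)
    else:
        doc = json.load(stream)
    return graph_from_doc(doc, validate=validate)


def write_graph(graph: HistoryGraph, stream: Union[str, IO],
                provenance: Optional[dict] = None) -> None:
    doc = graph_to_doc(graph, provenance)
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            json.dump(doc, fh, indent=2)
            fh.write("\n")
    else:
        json.dump(doc, stream, indent=2)
        stream.write("\n")


def dumps_graph(graph: HistoryGraph,
                provenance: Optional[dict] = None) -> str:
    return json.dumps(graph_to_doc(graph, provenance), indent=2) + "\n"


# ----------------------------------------------------------------------
# DOT export
# ----------------------------------------------------------------------
def export_dot(graph: HistoryGraph, annot: Optional[str] = None) -> str:
    """Deterministic Graphviz DOT text for a history graph.

    Vertices are boxes labeled "id [DNA]" with explicit head/tail ports;
    adjacencies are solid edges between ports, branches dotted arrows.
    With ``annot="lifted"`` the lifted graph is drawn too: free roots as
    dashed nodes, lifted adjacencies as coloured edges (blue = trivial,
    red = non-trivial), and per-vertex lifted labels in the node text.
    """
    lines = ["graph historygraph {", "  node [shape=record];"]
    lift = Lifting(graph) if annot == "lifted" else None

    def node_id(v: str) -> str:
        return '"%s"' % v

    for v in graph.vertices():
        lab = graph.label(v) or "-"
        extra = ""
        if lift is not None:
            lls = lift.labels_at(v)
            if lls:
                marks = ",".join(("%s" if ll.trivial else "%s*") % ll.label
                                 for ll in lls)
                extra = f"\\n^{{{marks}}}"
        lines.append(f'  {node_id(v)} '
                     f'[label="<tail>t|{v}\\n{lab}{extra}|<head>h"];')
    for (av, ao), (bv, bo) in graph.adjacencies():
        lines.append(f'  {node_id(av)}:{ao} -- {node_id(bv)}:{bo} '
                     '[style=solid];')
    for p, c in graph.branches():
        lines.append(f'  {node_id(p)} -- {node_id(c)} '
                     '[style=dotted, dir=forward, arrowhead=normal];')
    if lift is not None:
        free_roots = sorted({e[0] for edge in lift.lifted_edges
                             for e in edge.ends if ":" in e[0]})
        for fr in free_roots:
            lines.append(f'  {node_id(fr)} [shape=box, style=dashed, '
                         f'label="{fr}"];')
        for edge in lift.lifted_edges:
            (av, ao), (bv, bo) = edge.ends
            colour = "blue" if edge.trivial else "red"
            pa = f"{node_id(av)}:{ao}" if ":" not in av else node_id(av)
            pb = f"{node_id(bv)}:{bo}" if ":" not in bv else node_id(bv)
            lines.append(f'  {pa} -- {pb} [color={colour}, '
                         'constraint=false];')
    lines.append("}")
    return "\n".join(lines) + "\n"
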