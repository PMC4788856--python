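"""Read a KNIME-style workflow directory and collapse loop constructs into
port-level parameter sweeps.

The source layout (documented here because the real platform's format is
version-dependent and under-specified) is a directory with one connectivity
document plus one settings document per node::

    workflow/
      workflow.xml            # nodes + connections
      <node id>/settings.xml  # per-node settings

``workflow.xml``::

    <source_workflow>
      <node id="files" kind="input_files"/>
      <node id="zls" kind="loop_start"/>
      <node id="t1" kind="tool"/>
      ...
      <connection source="files" source_port="files" target="zls" target_port="in"/>
      ...
    </source_workflow>

Settings documents: tool nodes embed a value-CTD (``<settings
kind="tool"><tool .../></settings>``); ``input_files`` nodes list their
files; ``loop_end`` nodes name their matching ``loop_start`` via a
``start`` attribute.  Tool ports are the tool's file-typed parameter paths.

Loop semantics: the section enclosed by a loop_start/loop_end pair runs
once per input item — a parameter sweep.  The target representation has no
loop nodes; instead the pair collapses into port annotations: the in-port
that consumed the loop_start's output becomes a sweep *generator*, the
out-port that fed the loop_end becomes a sweep *collector*, and every task
strictly between the pair is marked as a sweep member.  Nested pairs and
flow-variable connections are rejected with an explicit report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from lxml import etree

from .ctd import ToolDescriptor, ValueBindings, extract_bindings, parse_ctd
from .errors import ConversionRejected, SourceParseError
from .report import ConversionReport
from .workflow import DataChannel, Port, Task, WorkflowGraph, validate_graph

__all__ = [
    "SourceNode",
    "Connection",
    "SourceWorkflow",
    "parse_source",
    "collapse_sweeps",
    "map_io_nodes",
    "NODE_KINDS",
]

NODE_KINDS = ("tool", "input_files", "output", "loop_start", "loop_end")


@dataclass
class SourceNode:
    id: str
    kind: str
    descriptor: Optional[ToolDescriptor] = None  # kind == "tool"
    bindings: Optional[ValueBindings] = None
    files: tuple[str, ...] = ()  # kind == "input_files"
    loop_start_id: Optional[str] = None  # kind == "loop_end"


@dataclass(frozen=True)
class Connection:
    source: str
    source_port: str
    target: str
    target_port: str
    kind: str = "data"  # "data" | "flow_variable"


@dataclass
class SourceWorkflow:
    nodes: list = field(default_factory=list)
    connections: list = field(default_factory=list)

    def node(self, node_id: str) -> SourceNode:
        for n in self.nodes:
            if n.id == node_id:
                return n
        raise SourceParseError(f"unknown node id {node_id!r}")


# ---------------------------------------------------------------------------
# parsing the directory layout


def parse_source(directory) -> SourceWorkflow:
    """Parse the documented workflow directory layout.

    Every referenced node must have a settings document; tool nodes must
    embed a CTD that parses; unsupported node kinds are reported by name.
    """
    directory = Path(directory)
    connectivity = directory / "workflow.xml"
    if not connectivity.is_file():
        raise SourceParseError(f"missing connectivity document {connectivity}")
    try:
        root = etree.fromstring(connectivity.read_bytes())
    except etree.XMLSyntaxError as exc:
        raise SourceParseError(f"malformed connectivity document: {exc}") from exc
    if root.tag != "source_workflow":
        raise SourceParseError(
            f"connectivity root must be <source_workflow>, got <{root.tag}>"
        )
    source = SourceWorkflow()
    seen: set[str] = set()
    for elem in root:
        if elem.tag is etree.Comment:
            continue
        if elem.tag == "node":
            node_id = elem.get("id")
            kind = elem.get("kind")
            if not node_id:
                raise SourceParseError("<node> without id")
            if node_id in seen:
                raise SourceParseError(f"duplicate node id {node_id!r}")
            seen.add(node_id)
            if kind not in NODE_KINDS:
                raise SourceParseError(
                    f"node {node_id!r}: unsupported node kind {kind!r}"
                )
            source.nodes.append(_parse_settings(directory, node_id, kind))
        elif elem.tag == "connection":
            for attr in ("source", "source_port", "target", "target_port"):
                if elem.get(attr) is None:
                    raise SourceParseError(
                        f"<connection> missing attribute {attr!r}"
                    )
            source.connections.append(
                Connection(
                    source=elem.get("source"),
                    source_port=elem.get("source_port"),
                    target=elem.get("target"),
                    target_port=elem.get("target_port"),
                    kind=elem.get("kind", "data"),
                )
            )
        else:
            raise SourceParseError(
                f"unexpected element <{elem.tag}> in connectivity document"
            )
    for conn in source.connections:
        for endpoint in (conn.source, conn.target):
            if endpoint not in seen:
                raise SourceParseError(
                    f"connection references unknown node {endpoint!r}"
                )
    return source


def _parse_settings(directory: Path, node_id: str, kind: str) -> SourceNode:
    settings_path = directory / node_id / "settings.xml"
    if not settings_path.is_file():
        raise SourceParseError(
            f"node {node_id!r}: missing settings document {settings_path}"
        )
    try:
        root = etree.fromstring(settings_path.read_bytes())
    except etree.XMLSyntaxError as exc:
        raise SourceParseError(
            f"node {node_id!r}: malformed settings: {exc}"
        ) from exc
    if root.tag != "settings":
        raise SourceParseError(
            f"node {node_id!r}: settings root must be <settings>"
        )
    if root.get("kind") != kind:
        raise SourceParseError(
            f"node {node_id!r}: settings kind {root.get('kind')!r} "
            f"does not match connectivity kind {kind!r}"
        )
    node = SourceNode(id=node_id, kind=kind)
    if kind == "tool":
        tool_elem = root.find("tool")
        if tool_elem is None:
            raise SourceParseError(
                f"node {node_id!r}: tool node without embedded CTD"
            )
        node.descriptor = parse_ctd(etree.tostring(tool_elem))
        node.bindings = extract_bindings(node.descriptor)
    elif kind == "input_files":
        node.files = tuple(
            (f.text or "") for f in root.findall("file")
        )
    elif kind == "loop_end":
        node.loop_start_id = root.get("start")
        if not node.loop_start_id:
            raise SourceParseError(
                f"node {node_id!r}: loop_end without a start attribute"
            )
    return node


# ---------------------------------------------------------------------------
# sweep collapse


def _match_loop_pairs(source: SourceWorkflow, report: ConversionReport):
    starts = {n.id for n in source.nodes if n.kind == "loop_start"}
    pairs: list[tuple[str, str]] = []
    claimed: set[str] = set()
    for node in source.nodes:
        if node.kind != "loop_end":
            continue
        if node.loop_start_id not in starts:
            report.reject("unbalanced-loop")
            raise ConversionRejected(
                f"loop_end {node.id!r} references no loop_start "
                f"({node.loop_start_id!r})",
                report=report.finalize(),
            )
        if node.loop_start_id in claimed:
            report.reject("unbalanced-loop")
            raise ConversionRejected(
                f"loop_start {node.loop_start_id!r} matched by several ends",
                report=report.finalize(),
            )
        claimed.add(node.loop_start_id)
        pairs.append((node.loop_start_id, node.id))
    if claimed != starts:
        report.reject("unbalanced-loop")
        orphan = sorted(starts - claimed)[0]
        raise ConversionRejected(
            f"loop_start {orphan!r} has no matching loop_end",
            report=report.finalize(),
        )
    return sorted(pairs)


def _reachable(conns, start: str, forward: bool) -> set[str]:
    adjacency: dict[str, set[str]] = {}
    for c in conns:
        a, b = (c.source, c.target) if forward else (c.target, c.source)
        adjacency.setdefault(a, set()).add(b)
    seen: set[str] = set()
    stack = [start]
    while stack:
        node = stack.pop()
        for nxt in adjacency.get(node, ()):
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return seen


def _enclosed(source: SourceWorkflow, start: str, end: str) -> set[str]:
    downstream = _reachable(source.connections, start, forward=True)
    upstream = _reachable(source.connections, end, forward=False)
    return (downstream & upstream) - {start, end}


def _resolve_loop_connections(source: SourceWorkflow, pairs):
    """Rewire data connections around loop nodes; returns the surviving
    connections plus the generator/collector port annotations."""
    conns = list(source.connections)
    generator_ports: set[tuple[str, str]] = set()
    collector_ports: set[tuple[str, str]] = set()
    for start_id, end_id in pairs:
        incoming = [c for c in conns if c.target == start_id]
        outgoing = [c for c in conns if c.source == start_id]
        rewired = []
        for inc in incoming:
            for out in outgoing:
                rewired.append(
                    Connection(inc.source, inc.source_port,
                               out.target, out.target_port)
                )
                generator_ports.add((out.target, out.target_port))
        conns = [c for c in conns
                 if c.target != start_id and c.source != start_id] + rewired
        incoming = [c for c in conns if c.target == end_id]
        outgoing = [c for c in conns if c.source == end_id]
        rewired = []
        for inc in incoming:
            collector_ports.add((inc.source, inc.source_port))
            for out in outgoing:
                rewired.append(
                    Connection(inc.source, inc.source_port,
                               out.target, out.target_port)
                )
        conns = [c for c in conns
                 if c.target != end_id and c.source != end_id] + rewired
    return conns, generator_ports, collector_ports


def map_io_nodes(source: SourceWorkflow):
    """Workflow boundary from io nodes: ``input_files`` nodes become
    workflow inputs on the tool ports they (transitively, through loop
    nodes) feed; terminal ``output`` nodes become workflow outputs on the
    ports feeding them.  Returns ``(inputs, outputs, dropped)`` where
    *dropped* lists disconnected io nodes."""
    report = ConversionReport()
    pairs = _match_loop_pairs(source, report)
    conns, _gen, _coll = _resolve_loop_connections(source, pairs)
    kind = {n.id: n.kind for n in source.nodes}
    inputs: list[tuple[str, str]] = []
    outputs: list[tuple[str, str]] = []
    dropped: list[tuple[str, str]] = []
    for node in source.nodes:
        if node.kind == "input_files":
            fed = [c for c in conns
                   if c.source == node.id and kind[c.target] == "tool"]
            if not fed:
                dropped.append(
                    (node.id, "input_files node with no consumer, dropped")
                )
            for c in fed:
                inputs.append((c.target, c.target_port))
        elif node.kind == "output":
            for c in conns:
                if c.target == node.id and kind[c.source] == "tool":
                    outputs.append((c.source, c.source_port))
    return inputs, outputs, dropped


def collapse_sweeps(
    source: SourceWorkflow,
) -> tuple[WorkflowGraph, ConversionReport]:
    """Convert a source workflow into an engine-neutral graph, removing
    loop node pairs in favour of sweep-annotated ports.

    Raises :class:`ConversionRejected` (report attached) on unbalanced or
    nested loop pairs and on flow-variable connections.
    """
    report = ConversionReport()
    for conn in source.connections:
        if conn.kind == "flow_variable":
            report.reject("flow-variable")
            raise ConversionRejected(
                f"flow-variable connection "
                f"{conn.source}.{conn.source_port} -> "
                f"{conn.target}.{conn.target_port} is not convertible",
                report=report.finalize(),
            )
    pairs = _match_loop_pairs(source, report)
    enclosed_by_pair = {
        (s, e): _enclosed(source, s, e) for s, e in pairs
    }
    loop_ids = {nid for pair in pairs for nid in pair}
    for (s, e), enclosed in enclosed_by_pair.items():
        if enclosed & loop_ids:
            report.reject("nested-loops")
            raise ConversionRejected(
                f"loop pair {s!r}/{e!r} encloses another loop node",
                report=report.finalize(),
            )
    sweep_members = set().union(*enclosed_by_pair.values()) if pairs else set()
    conns, generator_ports, collector_ports = _resolve_loop_connections(
        source, pairs
    )
    inputs, outputs, io_dropped = map_io_nodes(source)
    report.dropped.extend(io_dropped)

    kind = {n.id: n.kind for n in source.nodes}
    connected_ports: dict[str, set[str]] = {}
    for c in conns:
        if kind.get(c.source) == "tool":
            connected_ports.setdefault(c.source, set()).add(c.source_port)
        if kind.get(c.target) == "tool":
            connected_ports.setdefault(c.target, set()).add(c.target_port)
    for task_id, port in inputs:
        connected_ports.setdefault(task_id, set()).add(port)
    for task_id, port in outputs:
        connected_ports.setdefault(task_id, set()).add(port)

    graph = WorkflowGraph(
        workflow_inputs=inputs, workflow_outputs=outputs
    )
    for node in source.nodes:
        if node.kind != "tool":
            if node.kind in ("loop_start", "loop_end"):
                report.mapped.append(
                    (node.id, "(removed)", "loop node -> sweep ports")
                )
            continue
        ports = []
        for path, param in node.descriptor.flat_parameters():
            if not param.is_file:
                continue
            direction = "in" if param.base_type == "input-file" else "out"
            connected = path in connected_ports.get(node.id, set())
            if not connected and not param.required:
                report.dropped.append(
                    (f"{node.id}.{path}",
                     "unconnected optional port, omitted")
                )
                continue
            role = "none"
            if (node.id, path) in generator_ports and direction == "in":
                role = "generator"
            elif (node.id, path) in collector_ports and direction == "out":
                role = "collector"
            ports.append(
                Port(
                    name=path,
                    direction=direction,
                    format=param.file_formats[0] if param.file_formats else None,
                    sweep_role=role,
                    required=param.required,
                )
            )
        graph.tasks.append(
            Task(
                id=node.id,
                label=node.descriptor.name,
                descriptor=node.descriptor,
                bindings=node.bindings,
                ports=ports,
                sweep_member=node.id in sweep_members,
            )
        )
        report.mapped.append((node.id, node.id, "tool node -> task"))
    tool_ids = {n.id for n in source.nodes if n.kind == "tool"}
    for c in conns:
        if c.source in tool_ids and c.target in tool_ids:
            graph.channels.append(
                DataChannel(
                    source=(c.source, c.source_port),
                    target=(c.target, c.target_port),
                )
            )
    validate_graph(graph)
    return graph, report.finalize()
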