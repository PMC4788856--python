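"""Engine-neutral two-layer workflow graphs and their Petri-net semantics.

A workflow is a directed acyclic graph of tasks connected by data channels
(an output port feeding an input port).  Each task may carry a *concrete*
layer — a tool descriptor, value bindings and a resource hint — on top of
the *abstract* layer (topology, labels, ports); :func:`abstract_view`
strips the concrete layer.

For formal checking the graph translates into a Petri net: every task
becomes a transition, every data channel a place, every workflow input a
source place holding one token, and every workflow output a sink place.
A transition fires by consuming one token from each input place and
producing one on each output place; the workflow is *sound* when some
firing sequence fires every transition exactly once and leaves tokens only
in sink places.  For an acyclic graph whose required inputs are all
connected this always holds; dangling required inputs yield an unsound net,
which operationalises "a task runs once all its inputs can be resolved".

Place ids are assigned ``P0..Pn`` in topological channel order (workflow
inputs first, then channels ordered by the position of their source task,
then workflow outputs), so a 4-task chain with one input and one output
gets the start place ``P0`` and the end place ``P4``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional
from xml.sax.saxutils import escape, quoteattr

import networkx as nx
from lxml import etree

from .ctd import (
    ToolDescriptor,
    ValueBindings,
    apply_bindings,
    extract_bindings,
    parse_ctd,
    write_ctd,
)
from .errors import GraphError, PetriNetError

__all__ = [
    "Port",
    "Task",
    "DataChannel",
    "WorkflowGraph",
    "PetriNet",
    "SoundnessResult",
    "validate_graph",
    "abstract_view",
    "to_petri_net",
    "fire",
    "check_soundness",
    "write_workflow_xml",
    "parse_workflow_xml",
    "petri_edge_list",
]

SWEEP_ROLES = ("none", "generator", "collector")


@dataclass
class Port:
    name: str
    direction: str  # "in" | "out"
    format: Optional[str] = None
    sweep_role: str = "none"
    required: bool = True  # meaningful for in-ports only

    def __post_init__(self) -> None:
        if self.direction not in ("in", "out"):
            raise GraphError(f"port {self.name!r}: bad direction {self.direction!r}")
        if self.sweep_role not in SWEEP_ROLES:
            raise GraphError(
                f"port {self.name!r}: bad sweep role {self.sweep_role!r}"
            )


@dataclass
class Task:
    id: str
    label: str = ""
    descriptor: Optional[ToolDescriptor] = None
    bindings: Optional[ValueBindings] = None
    ports: list = field(default_factory=list)
    sweep_member: bool = False
    resource_hint: Optional[str] = None

    def __post_init__(self) -> None:
        if self.bindings is not None and self.descriptor is None:
            raise GraphError(
                f"task {self.id!r}: bindings without a descriptor"
            )
        names = [p.name for p in self.ports]
        if len(names) != len(set(names)):
            raise GraphError(f"task {self.id!r}: duplicate port names")

    def port(self, name: str) -> Optional[Port]:
        for p in self.ports:
            if p.name == name:
                return p
        return None


@dataclass(frozen=True)
class DataChannel:
    source: tuple[str, str]  # (task id, out-port name)
    target: tuple[str, str]  # (task id, in-port name)


@dataclass
class WorkflowGraph:
    tasks: list = field(default_factory=list)
    channels: list = field(default_factory=list)
    workflow_inputs: list = field(default_factory=list)  # (task id, port)
    workflow_outputs: list = field(default_factory=list)

    def task(self, task_id: str) -> Task:
        for t in self.tasks:
            if t.id == task_id:
                return t
        raise GraphError(f"unknown task id {task_id!r}")


# ---------------------------------------------------------------------------
# validation


def _check_endpoint(graph: WorkflowGraph, endpoint, direction: str, what: str):
    task_id, port_name = endpoint
    task = None
    for t in graph.tasks:
        if t.id == task_id:
            task = t
            break
    if task is None:
        raise GraphError(f"{what}: dangling endpoint, no task {task_id!r}")
    port = task.port(port_name)
    if port is None:
        raise GraphError(
            f"{what}: no port {port_name!r} on task {task_id!r}"
        )
    if port.direction != direction:
        raise GraphError(
            f"{what}: port {task_id}.{port_name} has direction "
            f"{port.direction!r}, expected {direction!r}"
        )
    return port


def validate_graph(graph: WorkflowGraph) -> list[str]:
    """Validate the graph and return a deterministic topological order of
    task ids (ties broken lexicographically).

    Raises :class:`GraphError` on duplicate ids, dangling channel
    endpoints, direction mismatches, or a cycle (reporting the ids on one
    cycle).
    """
    ids = [t.id for t in graph.tasks]
    if len(ids) != len(set(ids)):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise GraphError(f"duplicate task id {dup!r}")
    for ch in graph.channels:
        what = f"channel {ch.source[0]}.{ch.source[1]} -> {ch.target[0]}.{ch.target[1]}"
        _check_endpoint(graph, ch.source, "out", what)
        _check_endpoint(graph, ch.target, "in", what)
    for endpoint in graph.workflow_inputs:
        _check_endpoint(graph, endpoint, "in", f"workflow input {endpoint}")
    for endpoint in graph.workflow_outputs:
        _check_endpoint(graph, endpoint, "out", f"workflow output {endpoint}")
    dg = nx.DiGraph()
    dg.add_nodes_from(ids)
    dg.add_edges_from((ch.source[0], ch.target[0]) for ch in graph.channels)
    try:
        return list(nx.lexicographical_topological_sort(dg))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(dg)
        members = " -> ".join(edge[0] for edge in cycle)
        raise GraphError(f"workflow graph contains a cycle: {members}") from None


def abstract_view(graph: WorkflowGraph) -> WorkflowGraph:
    """The application-domain view: a copy with descriptors, bindings and
    resource hints stripped; topology, labels and ports are untouched."""
    tasks = [
        Task(
            id=t.id,
            label=t.label,
            descriptor=None,
            bindings=None,
            ports=[replace(p) for p in t.ports],
            sweep_member=t.sweep_member,
            resource_hint=None,
        )
        for t in graph.tasks
    ]
    return WorkflowGraph(
        tasks=tasks,
        channels=list(graph.channels),
        workflow_inputs=list(graph.workflow_inputs),
        workflow_outputs=list(graph.workflow_outputs),
    )


# ---------------------------------------------------------------------------
# Petri-net translation


@dataclass(frozen=True)
class PetriNet:
    """Bipartite place/transition net with a marking.  Arcs connect a place
    to a transition or vice versa, never two nodes of the same kind."""

    places: tuple[str, ...]
    transitions: tuple[str, ...]
    arcs: tuple[tuple[str, str], ...]
    marking: tuple[tuple[str, int], ...]  # sorted (place, tokens) pairs

    def __post_init__(self) -> None:
        pset, tset = set(self.places), set(self.transitions)
        if pset & tset:
            raise PetriNetError("place and transition ids overlap")
        for src, dst in self.arcs:
            if (src in pset) == (dst in pset):
                raise PetriNetError(
                    f"arc {src}->{dst} connects two nodes of the same kind"
                )
            if src not in pset | tset or dst not in pset | tset:
                raise PetriNetError(f"arc {src}->{dst} references unknown node")
        for place, tokens in self.marking:
            if tokens < 0:
                raise PetriNetError(f"negative token count on {place}")

    def tokens(self, place: str) -> int:
        return dict(self.marking).get(place, 0)

    def input_places(self, transition: str) -> list[str]:
        return [src for src, dst in self.arcs if dst == transition]

    def output_places(self, transition: str) -> list[str]:
        return [dst for src, dst in self.arcs if src == transition]

    def sink_places(self) -> list[str]:
        with_out = {src for src, _ in self.arcs if src in set(self.places)}
        return [p for p in self.places if p not in with_out]

    def enabled(self, transition: str) -> bool:
        m = dict(self.marking)
        return all(m.get(p, 0) >= 1 for p in self.input_places(transition))


def _marking_tuple(marking: dict) -> tuple[tuple[str, int], ...]:
    return tuple(sorted((p, n) for p, n in marking.items() if n != 0))


def to_petri_net(graph: WorkflowGraph) -> PetriNet:
    """Translate a valid workflow graph into its Petri net.

    One transition per task; one place per data channel, per workflow input
    (holding the single initial token) and per workflow output; plus one
    unmarked place per *unconnected required* input port, which is what
    makes under-specified workflows unsound.  Unconnected optional inputs
    generate nothing.
    """
    order = validate_graph(graph)
    topo_pos = {tid: i for i, tid in enumerate(order)}
    places: list[str] = []
    arcs: list[tuple[str, str]] = []
    marking: dict[str, int] = {}

    def new_place() -> str:
        pid = f"P{len(places)}"
        places.append(pid)
        return pid

    for task_id, _port in graph.workflow_inputs:
        pid = new_place()
        arcs.append((pid, task_id))
        marking[pid] = 1
    sorted_channels = sorted(
        graph.channels,
        key=lambda ch: (topo_pos[ch.source[0]], ch.source, ch.target),
    )
    for ch in sorted_channels:
        pid = new_place()
        arcs.append((ch.source[0], pid))
        arcs.append((pid, ch.target[0]))
    for task_id, _port in graph.workflow_outputs:
        pid = new_place()
        arcs.append((task_id, pid))
    # dangling required inputs: a place no transition will ever mark
    connected_in = {ch.target for ch in graph.channels} | set(
        graph.workflow_inputs
    )
    dangling = []
    for task in graph.tasks:
        for port in task.ports:
            if (
                port.direction == "in"
                and port.required
                and (task.id, port.name) not in connected_in
            ):
                dangling.append((task.id, port.name))
    for task_id, _port in sorted(dangling):
        pid = new_place()
        arcs.append((pid, task_id))
    return PetriNet(
        places=tuple(places),
        transitions=tuple(t.id for t in graph.tasks),
        arcs=tuple(arcs),
        marking=_marking_tuple(marking),
    )


def fire(net: PetriNet, transition: str) -> PetriNet:
    """Fire one transition: consume a token from every input place, produce
    one on every output place.  Firing a disabled transition is an error."""
    if transition not in net.transitions:
        raise PetriNetError(f"unknown transition {transition!r}")
    marking = dict(net.marking)
    for place in net.input_places(transition):
        if marking.get(place, 0) < 1:
            raise PetriNetError(
                f"transition {transition!r} is not enabled: "
                f"place {place!r} holds no token"
            )
        marking[place] = marking.get(place, 0) - 1
    for place in net.output_places(transition):
        marking[place] = marking.get(place, 0) + 1
    return PetriNet(
        places=net.places,
        transitions=net.transitions,
        arcs=net.arcs,
        marking=_marking_tuple(marking),
    )


@dataclass(frozen=True)
class SoundnessResult:
    sound: bool
    witness: Optional[tuple[str, ...]] = None  # firing sequence when sound
    stuck_marking: Optional[tuple[tuple[str, int], ...]] = None


def check_soundness(net: PetriNet) -> SoundnessResult:
    """Search the marking graph for a firing sequence that fires every
    transition exactly once and terminates with tokens only in sink places.

    Returns the witness sequence when sound; otherwise a stuck marking — a
    reachable marking from which no eligible transition can fire although
    not every transition has fired.
    """
    sinks = set(net.sink_places())
    in_places = {t: net.input_places(t) for t in net.transitions}
    out_places = {t: net.output_places(t) for t in net.transitions}

    def final_ok(marking: dict) -> bool:
        return all(p in sinks for p, n in marking.items() if n > 0)

    seen: set = set()
    stuck: Optional[tuple[tuple[str, int], ...]] = None
    # DFS over (marking, fired set); nets from acyclic graphs keep this small
    stack = [(dict(net.marking), frozenset(), ())]
    while stack:
        marking, fired, seq = stack.pop()
        key = (_marking_tuple(marking), fired)
        if key in seen:
            continue
        seen.add(key)
        if len(fired) == len(net.transitions):
            if final_ok(marking):
                return SoundnessResult(sound=True, witness=seq)
            if stuck is None:
                stuck = _marking_tuple(marking)
            continue
        progressed = False
        for t in net.transitions:
            if t in fired:
                continue
            if all(marking.get(p, 0) >= 1 for p in in_places[t]):
                progressed = True
                nxt = dict(marking)
                for p in in_places[t]:
                    nxt[p] -= 1
                for p in out_places[t]:
                    nxt[p] = nxt.get(p, 0) + 1
                stack.append((nxt, fired | {t}, seq + (t,)))
        if not progressed and stuck is None:
            stuck = _marking_tuple(marking)
    return SoundnessResult(sound=False, stuck_marking=stuck)


# ---------------------------------------------------------------------------
# serialization


def write_workflow_xml(graph: WorkflowGraph) -> str:
    """Canonical engine-neutral XML form of a workflow graph (2-space
    indent, fixed attribute order, byte-stable)."""
    out = ['<?xml version="1.0" encoding="UTF-8"?>', "<workflow>"]
    for task in graph.tasks:
        attrs = f" id={quoteattr(task.id)} label={quoteattr(task.label)}"
        if task.sweep_member:
            attrs += ' sweep_member="true"'
        if task.resource_hint is not None:
            attrs += f" resource_hint={quoteattr(task.resource_hint)}"
        if task.bindings is not None:
            attrs += ' bound="true"'
        body = bool(task.ports or task.descriptor)
        out.append(f"  <task{attrs}>" if body else f"  <task{attrs}/>")
        for port in task.ports:
            pattrs = (
                f" name={quoteattr(port.name)}"
                f" direction={quoteattr(port.direction)}"
            )
            if port.format is not None:
                pattrs += f" format={quoteattr(port.format)}"
            if port.sweep_role != "none":
                pattrs += f" sweep_role={quoteattr(port.sweep_role)}"
            if not port.required:
                pattrs += ' required="false"'
            out.append(f"    <port{pattrs}/>")
        if task.descriptor is not None:
            doc = task.descriptor
            if task.bindings is not None:
                doc = apply_bindings(doc, task.bindings)
            ctd_text = write_ctd(doc).split("\n", 1)[1]  # drop XML decl
            for line in ctd_text.rstrip("\n").split("\n"):
                out.append(f"    {line}")
        if body:
            out.append("  </task>")
    for ch in graph.channels:
        out.append(
            "  <channel"
            f" source_task={quoteattr(ch.source[0])}"
            f" source_port={quoteattr(ch.source[1])}"
            f" target_task={quoteattr(ch.target[0])}"
            f" target_port={quoteattr(ch.target[1])}/>"
        )
    for task_id, port in graph.workflow_inputs:
        out.append(f"  <input task={quoteattr(task_id)} port={quoteattr(port)}/>")
    for task_id, port in graph.workflow_outputs:
        out.append(f"  <output task={quoteattr(task_id)} port={quoteattr(port)}/>")
    out.append("</workflow>")
    return "\n".join(out) + "\n"


def parse_workflow_xml(text) -> WorkflowGraph:
    if isinstance(text, str):
        text = text.encode("utf-8")
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise GraphError(f"malformed workflow XML: {exc}") from exc
    if root.tag != "workflow":
        raise GraphError(f"root element must be <workflow>, got <{root.tag}>")
    graph = WorkflowGraph()
    for elem in root:
        if elem.tag == "task":
            ports = []
            descriptor = None
            for child in elem:
                if child.tag == "port":
                    ports.append(
                        Port(
                            name=child.get("name"),
                            direction=child.get("direction"),
                            format=child.get("format"),
                            sweep_role=child.get("sweep_role", "none"),
                            required=child.get("required", "true") == "true",
                        )
                    )
                elif child.tag == "tool":
                    descriptor = parse_ctd(etree.tostring(child))
            bindings = None
            if elem.get("bound") == "true":
                if descriptor is None:
                    raise GraphError(
                        f"task {elem.get('id')!r}: bound but no embedded tool"
                    )
                bindings = extract_bindings(descriptor)
            graph.tasks.append(
                Task(
                    id=elem.get("id"),
                    label=elem.get("label", ""),
                    descriptor=descriptor,
                    bindings=bindings,
                    ports=ports,
                    sweep_member=elem.get("sweep_member") == "true",
                    resource_hint=elem.get("resource_hint"),
                )
            )
        elif elem.tag == "channel":
            graph.channels.append(
                DataChannel(
                    source=(elem.get("source_task"), elem.get("source_port")),
                    target=(elem.get("target_task"), elem.get("target_port")),
                )
            )
        elif elem.tag == "input":
            graph.workflow_inputs.append((elem.get("task"), elem.get("port")))
        elif elem.tag == "output":
            graph.workflow_outputs.append((elem.get("task"), elem.get("port")))
    validate_graph(graph)
    return graph


def petri_edge_list(net: PetriNet) -> str:
    """Plain-text edge list of a net for debugging: one ``src -> dst`` line
    per arc, then the marking."""
    lines = [f"{src} -> {dst}" for src, dst in net.arcs]
    for place, tokens in net.marking:
        lines.append(f"marking {place} = {tokens}")
    return "\n".join(lines) + "\n"
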