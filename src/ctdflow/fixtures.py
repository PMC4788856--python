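"""Seeded synthetic generators: descriptors, ToolConfig documents, source
workflows — plus small worked examples and executable test stubs.

Every generator is a pure function of its arguments (one ``random.Random``
seeded per call, no global state), so any property-test failure replays
from its seed.  Workflow generators also return definitionally correct
ground truth (constructed alongside the artifact, not inferred from it),
which the converter tests use as their oracle.

Sampling scheme for descriptors: value types uniform over all twelve type
tokens; numeric parameters carry a range restriction with probability 0.4
(one open end with probability 0.3), strings a choice list with
probability 0.3; defaults are present with probability 0.75 (always drawn
to satisfy the restriction); ``required`` 0.3, ``advanced`` 0.25.  String
values never contain commas so that list values survive the comma-joined
Galaxy encoding.
"""

from __future__ import annotations

import random
from pathlib import Path
from typing import Optional

from .ctd import (
    Parameter,
    ParameterGroup,
    Restriction,
    ToolDescriptor,
    ValueBindings,
    apply_bindings,
    write_ctd,
)
from .knime import Connection, SourceNode, SourceWorkflow
from .workflow import DataChannel, Port, Task, WorkflowGraph

__all__ = [
    "gen_tool_descriptor",
    "gen_bindings",
    "gen_galaxy_tool",
    "gen_source_workflow",
    "gen_workflow_graph",
    "write_source_dir",
    "pdbcutter_descriptor",
    "protonation_workflow",
    "lfq_source_workflow",
    "make_echo_stub",
    "make_noop_stub",
    "make_failing_stub",
]

_WORDS = (
    "alpha", "beta", "gamma", "delta", "omega", "sigma", "kappa", "theta",
    "lambda_", "zeta", "iota", "rho",
)
_EXTS = ("pdb", "mzML", "fasta", "csv", "idXML", "featureXML", "txt")
_TYPES = (
    "int", "float", "string", "bool", "input-file", "output-file",
    "int-list", "float-list", "string-list", "bool-list",
    "input-file-list", "output-file-list",
)
_STRING_ALPHABET = "abcdefghijklmnopqrstuvwxyz0123456789_- "


def _rand_string(rng: random.Random) -> str:
    n = rng.randint(3, 10)
    return "".join(rng.choice(_STRING_ALPHABET) for _ in range(n)).strip() or "x"


def _sample_restriction(rng: random.Random, base: str) -> Optional[Restriction]:
    if base in ("int", "float") and rng.random() < 0.4:
        lo = rng.randint(-10, 50)
        hi = lo + rng.randint(0, 50)
        if base == "float":
            lo, hi = float(lo), float(hi)
        open_end = rng.random() < 0.3
        if open_end and rng.random() < 0.5:
            return Restriction("numeric_range", min_value=lo)
        if open_end:
            return Restriction("numeric_range", max_value=hi)
        return Restriction("numeric_range", min_value=lo, max_value=hi)
    if base == "string" and rng.random() < 0.3:
        k = rng.randint(2, 5)
        choices = rng.sample(_WORDS, k)
        return Restriction("choice_list", choices=tuple(choices))
    return None


def _sample_scalar(rng: random.Random, base: str, restriction, idx: int):
    if restriction is not None and restriction.kind == "choice_list":
        return rng.choice(restriction.choices)
    if base == "int":
        lo = int(restriction.min_value) if restriction and restriction.min_value is not None else None
        hi = int(restriction.max_value) if restriction and restriction.max_value is not None else None
        if lo is None:
            lo = -5 if hi is None else hi - 20
        if hi is None:
            hi = lo + 20
        return rng.randint(lo, hi)
    if base == "float":
        lo = restriction.min_value if restriction and restriction.min_value is not None else None
        hi = restriction.max_value if restriction and restriction.max_value is not None else None
        if lo is None:
            lo = -5.0 if hi is None else hi - 20.0
        if hi is None:
            hi = lo + 20.0
        return min(max(round(rng.uniform(lo, hi), 4), lo), hi)
    if base == "bool":
        return rng.random() < 0.5
    if base in ("input-file", "output-file"):
        return f"file{idx}_{rng.randint(0, 99)}.{rng.choice(_EXTS)}"
    return _rand_string(rng)


def _sample_value(rng: random.Random, param: Parameter, idx: int):
    if param.is_list:
        return [
            _sample_scalar(rng, param.base_type, param.restriction, idx)
            for _ in range(rng.randint(1, 3))
        ]
    return _sample_scalar(rng, param.base_type, param.restriction, idx)


def gen_tool_descriptor(seed: int, n_params: Optional[int] = None) -> ToolDescriptor:
    """Deterministic random descriptor covering all value types and
    restriction kinds (probabilities in the module docstring)."""
    rng = random.Random(seed)
    if n_params is None:
        n_params = rng.randint(0, 8)
    params: list[Parameter] = []
    for i in range(n_params):
        vtype = rng.choice(_TYPES)
        base = vtype[:-5] if vtype.endswith("-list") else vtype
        restriction = _sample_restriction(rng, base)
        formats = ()
        if base in ("input-file", "output-file") and rng.random() < 0.6:
            formats = tuple(
                sorted(rng.sample(_EXTS, rng.randint(1, 3)))
            )
        param = Parameter(
            name=f"{rng.choice(_WORDS)}{i}",
            value_type=vtype,
            required=rng.random() < 0.3,
            advanced=rng.random() < 0.25,
            description=_rand_string(rng) if rng.random() < 0.5 else "",
            restriction=restriction,
            file_formats=formats,
        )
        if rng.random() < 0.75:
            param.default = _sample_value(rng, param, i)
            param.__post_init__()
        params.append(param)
    # distribute parameters over the root and up to two groups
    children: list = []
    if n_params >= 3 and rng.random() < 0.5:
        n_groups = rng.randint(1, 2)
        groups = [
            ParameterGroup(name=f"grp{g}") for g in range(n_groups)
        ]
        for param in params:
            bucket = rng.randint(0, n_groups)
            if bucket == 0:
                children.append(param)
            else:
                groups[bucket - 1].children.append(param)
        children.extend(g for g in groups if g.children)
    else:
        children = list(params)
    return ToolDescriptor(
        name=f"tool{seed % 1000}",
        version=f"{rng.randint(0, 3)}.{rng.randint(0, 9)}.{rng.randint(0, 9)}",
        description=_rand_string(rng) if rng.random() < 0.6 else "",
        category=rng.choice(("Utilities", "Conversion", None)),
        parameters=ParameterGroup(name="", children=children),
    )


def gen_bindings(seed: int, descriptor: ToolDescriptor) -> ValueBindings:
    """Random valid bindings: every required parameter bound, optional ones
    with probability 0.5; values satisfy their restrictions."""
    rng = random.Random(seed)
    values = {}
    for i, (path, param) in enumerate(descriptor.flat_parameters()):
        must = param.required and param.default is None
        if must or rng.random() < 0.5:
            values[path] = _sample_value(rng, param, i)
    return ValueBindings(values)


# ---------------------------------------------------------------------------
# Galaxy ToolConfig generator

_GALAXY_TYPES = ("text", "integer", "float", "boolean", "select", "data")


def gen_galaxy_tool(seed: int, convertible: bool) -> tuple[str, tuple[str, ...]]:
    """A ToolConfig document plus ground truth: the tuple of unsupported
    construct tags it contains (empty iff *convertible*).

    The document is assembled textually and independently of the emitter in
    :mod:`ctdflow.galaxy`, so corpus tests exercise a genuinely foreign
    input.
    """
    rng = random.Random(seed)
    n = rng.randint(1, 6)
    names = [f"{rng.choice(_WORDS)}{i}" for i in range(n)]
    lines = []
    command_parts = [f"tool{seed % 1000}"]
    for name in names:
        gtype = rng.choice(_GALAXY_TYPES)
        command_parts.append(f"-{name} ${name}")
        if gtype == "select":
            opts = rng.sample(_WORDS, 3)
            body = "".join(
                f'<option value="{o}">{o}</option>' for o in opts
            )
            lines.append(f'    <param name="{name}" type="select">{body}</param>')
        elif gtype == "integer":
            lines.append(
                f'    <param name="{name}" type="integer" '
                f'value="{rng.randint(0, 9)}"/>'
            )
        elif gtype == "float":
            lines.append(
                f'    <param name="{name}" type="float" '
                f'value="{round(rng.uniform(0, 9), 2)}"/>'
            )
        elif gtype == "boolean":
            lines.append(
                f'    <param name="{name}" type="boolean" '
                f'truevalue="-{name}" falsevalue="" checked="false"/>'
            )
        elif gtype == "data":
            lines.append(
                f'    <param name="{name}" type="data" '
                f'format="{rng.choice(_EXTS)}"/>'
            )
        else:
            lines.append(
                f'    <param name="{name}" type="text" value="{name}_v"/>'
            )
    truth: list[str] = []
    if not convertible:
        kinds = rng.sample(
            ("conditional", "repeat", "template-control-flow",
             "configfile-logic"),
            rng.randint(1, 3),
        )
        truth = sorted(kinds)
        if "conditional" in kinds:
            lines.append(
                '    <conditional name="cond0">'
                '<param name="sel" type="select">'
                '<option value="a">a</option></param>'
                '<when value="a"/></conditional>'
            )
        if "repeat" in kinds:
            lines.append(
                '    <repeat name="rep0" title="series">'
                '<param name="r" type="text"/></repeat>'
            )
        if "template-control-flow" in kinds:
            command_parts.append("#if $flag -x #end if")
    n_out = rng.randint(0, 2)
    outputs = []
    for i in range(n_out):
        outputs.append(
            f'    <data name="out{i}" format="{rng.choice(_EXTS)}"/>'
        )
        command_parts.append(f"-out{i} $out{i}")
    doc = [
        f'<tool id="gtool{seed % 10000}" name="gtool{seed % 10000}" '
        'version="0.1">',
        f"  <command>{' '.join(command_parts)}</command>",
        "  <inputs>",
        *lines,
        "  </inputs>",
        "  <outputs>",
        *outputs,
        "  </outputs>",
    ]
    if not convertible and "configfile-logic" in truth:
        doc.append(
            "  <configfiles><configfile name=\"cf\">"
            "#for $i in $items:\n$i\n#end for</configfile></configfiles>"
        )
    doc.append("</tool>")
    return "\n".join(doc) + "\n", tuple(truth)


# ---------------------------------------------------------------------------
# source workflows (KNIME-style)


def _chain_tool(index: int, rng: random.Random) -> SourceNode:
    tid = f"t{index}"
    extras = []
    for j in range(rng.randint(0, 2)):
        base = rng.choice(("int", "float", "string", "bool"))
        restriction = _sample_restriction(rng, base)
        param = Parameter(
            name=f"opt{j}",
            value_type=base,
            restriction=restriction,
        )
        param.default = _sample_value(rng, param, j)
        param.__post_init__()
        extras.append(param)
    descriptor = ToolDescriptor(
        name=f"Tool{index}",
        version="1.0.0",
        parameters=ParameterGroup(
            name="",
            children=[
                Parameter(
                    name="in",
                    value_type="input-file",
                    default=f"{tid}_in.dat",
                    required=True,
                ),
                Parameter(
                    name="out",
                    value_type="output-file",
                    default=f"{tid}_out.dat",
                    required=True,
                ),
                *extras,
            ],
        ),
    )
    from .ctd import extract_bindings

    return SourceNode(
        id=tid,
        kind="tool",
        descriptor=descriptor,
        bindings=extract_bindings(descriptor),
    )


def gen_source_workflow(
    seed: int, n_tools: int, loop_pairs: int
) -> tuple[SourceWorkflow, dict]:
    """A linear tool chain with *loop_pairs* non-nested loop sections, an
    input-files node feeding the head and an output node draining the tail.

    Returns the workflow and its ground truth: enclosed tool ids, expected
    sweep ports, workflow boundary and loop-node count.
    """
    if n_tools < 1:
        raise ValueError("n_tools must be >= 1")
    if loop_pairs < 0 or loop_pairs > n_tools:
        raise ValueError(
            f"cannot place {loop_pairs} non-nested loop pairs over "
            f"{n_tools} tools"
        )
    rng = random.Random(seed)
    starts = sorted(rng.sample(range(1, n_tools + 1), k=loop_pairs))
    intervals = []
    for k, a in enumerate(starts):
        limit = starts[k + 1] - 1 if k + 1 < len(starts) else n_tools
        intervals.append((a, rng.randint(a, limit)))
    start_at = {a: k for k, (a, _b) in enumerate(intervals)}
    end_at = {b: k for k, (_a, b) in enumerate(intervals)}

    nodes = [SourceNode(id="files", kind="input_files",
                        files=tuple(f"run{i}.mzML" for i in range(rng.randint(2, 4))))]
    tools = [_chain_tool(i, rng) for i in range(1, n_tools + 1)]
    nodes.extend(tools)
    for k in range(loop_pairs):
        nodes.append(SourceNode(id=f"zls{k}", kind="loop_start"))
        nodes.append(
            SourceNode(id=f"zle{k}", kind="loop_end", loop_start_id=f"zls{k}")
        )
    nodes.append(SourceNode(id="sink", kind="output"))

    conns = []

    def link(src: str, sp: str, pos: int) -> None:
        """Connect src.sp to tool at 1-based chain position *pos*, routing
        through a loop_start if an interval begins there."""
        if pos in start_at:
            k = start_at[pos]
            conns.append(Connection(src, sp, f"zls{k}", "in"))
            conns.append(Connection(f"zls{k}", "out", f"t{pos}", "in"))
        else:
            conns.append(Connection(src, sp, f"t{pos}", "in"))

    link("files", "files", 1)
    for i in range(1, n_tools):
        if i in end_at:
            k = end_at[i]
            conns.append(Connection(f"t{i}", "out", f"zle{k}", "in"))
            link(f"zle{k}", "out", i + 1)
        else:
            link(f"t{i}", "out", i + 1)
    if n_tools in end_at:
        k = end_at[n_tools]
        conns.append(Connection(f"t{n_tools}", "out", f"zle{k}", "in"))
        conns.append(Connection(f"zle{k}", "out", "sink", "in"))
    else:
        conns.append(Connection(f"t{n_tools}", "out", "sink", "in"))

    enclosed = {
        k: {f"t{i}" for i in range(a, b + 1)}
        for k, (a, b) in enumerate(intervals)
    }
    truth = {
        "n_tools": n_tools,
        "loop_nodes": 2 * loop_pairs,
        "enclosed": enclosed,
        "sweep_members": set().union(*enclosed.values()) if enclosed else set(),
        "generator_ports": {(f"t{a}", "in") for a, _b in intervals},
        "collector_ports": {(f"t{b}", "out") for _a, b in intervals},
        "workflow_inputs": [("t1", "in")],
        "workflow_outputs": [(f"t{n_tools}", "out")],
    }
    return SourceWorkflow(nodes=nodes, connections=conns), truth


def write_source_dir(source: SourceWorkflow, directory) -> Path:
    """Materialise a source workflow as the documented directory layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<source_workflow>"]
    for node in source.nodes:
        lines.append(f'  <node id="{node.id}" kind="{node.kind}"/>')
    for c in source.connections:
        kind = '' if c.kind == "data" else f' kind="{c.kind}"'
        lines.append(
            f'  <connection source="{c.source}" source_port="{c.source_port}"'
            f' target="{c.target}" target_port="{c.target_port}"{kind}/>'
        )
    lines.append("</source_workflow>")
    (directory / "workflow.xml").write_text("\n".join(lines) + "\n")
    for node in source.nodes:
        node_dir = directory / node.id
        node_dir.mkdir(exist_ok=True)
        body = ['<?xml version="1.0" encoding="UTF-8"?>']
        if node.kind == "tool":
            body.append('<settings kind="tool">')
            ctd = write_ctd(apply_bindings(node.descriptor, node.bindings))
            for line in ctd.split("\n", 1)[1].rstrip("\n").split("\n"):
                body.append(f"  {line}")
            body.append("</settings>")
        elif node.kind == "input_files":
            body.append('<settings kind="input_files">')
            for f in node.files:
                body.append(f"  <file>{f}</file>")
            body.append("</settings>")
        elif node.kind == "loop_end":
            body.append(
                f'<settings kind="loop_end" start="{node.loop_start_id}"/>'
            )
        else:
            body.append(f'<settings kind="{node.kind}"/>')
        (node_dir / "settings.xml").write_text("\n".join(body) + "\n")
    return directory


# ---------------------------------------------------------------------------
# random workflow graphs (for the Petri-net property suites)


def gen_workflow_graph(
    seed: int,
    n_tasks: Optional[int] = None,
    p_edge: float = 0.3,
    p_dangling: float = 0.0,
) -> WorkflowGraph:
    """A random DAG over ``n_tasks`` tasks: edges only point forward in a
    fixed task order, roots become workflow inputs and leaves workflow
    outputs.  With probability *p_dangling* a task additionally gets an
    unconnected required in-port (which renders its net unsound)."""
    rng = random.Random(seed)
    if n_tasks is None:
        n_tasks = rng.randint(1, 6)
    ids = [f"T{i}" for i in range(n_tasks)]
    tasks = {tid: Task(id=tid, label=tid, ports=[]) for tid in ids}
    channels = []
    for i in range(n_tasks):
        for j in range(i + 1, n_tasks):
            if rng.random() < p_edge:
                src, dst = ids[i], ids[j]
                out_name = f"o{j}"
                in_name = f"i{i}"
                tasks[src].ports.append(Port(name=out_name, direction="out"))
                tasks[dst].ports.append(Port(name=in_name, direction="in"))
                channels.append(
                    DataChannel(source=(src, out_name), target=(dst, in_name))
                )
    has_in = {ch.target[0] for ch in channels}
    has_out = {ch.source[0] for ch in channels}
    inputs, outputs = [], []
    for tid in ids:
        if tid not in has_in:
            tasks[tid].ports.append(Port(name="start", direction="in"))
            inputs.append((tid, "start"))
        if tid not in has_out:
            tasks[tid].ports.append(Port(name="result", direction="out"))
            outputs.append((tid, "result"))
        if rng.random() < p_dangling:
            tasks[tid].ports.append(
                Port(name="dangling", direction="in", required=True)
            )
    return WorkflowGraph(
        tasks=[tasks[tid] for tid in ids],
        channels=channels,
        workflow_inputs=inputs,
        workflow_outputs=outputs,
    )


# ---------------------------------------------------------------------------
# worked examples


def pdbcutter_descriptor() -> ToolDescriptor:
    """The classic three-parameter structure tool: one PDB input, two
    outputs (the ligand and the remaining protein)."""
    return ToolDescriptor(
        name="PDBCutter",
        version="1.0.0",
        description="Separates ligand and protein of a PDB file",
        parameters=ParameterGroup(
            name="",
            children=[
                Parameter(
                    name="in", value_type="input-file", required=True,
                    file_formats=("pdb",),
                    description="complex structure",
                ),
                Parameter(
                    name="ligand", value_type="output-file", required=True,
                    file_formats=("pdb",),
                    description="extracted ligand",
                ),
                Parameter(
                    name="protein", value_type="output-file", required=True,
                    file_formats=("pdb",),
                    description="remaining protein",
                ),
            ],
        ),
    )


def _simple_tool(name: str, in_port: bool = True, out_port: bool = True):
    children = []
    if in_port:
        children.append(
            Parameter(name="in", value_type="input-file",
                      default=f"{name.lower()}_in.pdb", required=True)
        )
    if out_port:
        children.append(
            Parameter(name="out", value_type="output-file",
                      default=f"{name.lower()}_out.pdb", required=True)
        )
    return ToolDescriptor(
        name=name, version="1.0.0",
        parameters=ParameterGroup(name="", children=children),
    )


def protonation_workflow(concrete: bool = False) -> WorkflowGraph:
    """The four-task molecule-protonation chain
    Input -> Split -> Protonate -> Output (three edges, one workflow input,
    one workflow output).  With ``concrete=True`` every task carries a tool
    descriptor, bindings and a resource hint."""
    from .ctd import extract_bindings

    names = ["Input", "Split", "Protonate", "Output"]
    tools = {
        "Input": _simple_tool("FileFetcher"),
        "Split": _simple_tool("PDBSplitter"),
        "Protonate": _simple_tool("Protonate"),
        "Output": _simple_tool("FileStore"),
    }
    tasks = []
    for name in names:
        descriptor = tools[name] if concrete else None
        tasks.append(
            Task(
                id=name,
                label=name,
                descriptor=descriptor,
                bindings=extract_bindings(descriptor) if concrete else None,
                ports=[
                    Port(name="in", direction="in"),
                    Port(name="out", direction="out"),
                ],
                resource_hint="local-cluster" if concrete else None,
            )
        )
    channels = [
        DataChannel(source=(a, "out"), target=(b, "in"))
        for a, b in zip(names, names[1:])
    ]
    return WorkflowGraph(
        tasks=tasks,
        channels=channels,
        workflow_inputs=[("Input", "in")],
        workflow_outputs=[("Output", "out")],
    )


_LFQ_INNER = (
    "FileConverter",
    "PeakPickerHiRes",
    "FeatureFinderCentroided",
    "OMSSAAdapter",
    "FalseDiscoveryRate",
    "IDMapper",
)
_LFQ_OUTER = ("FeatureLinkerUnlabeledQT", "ConsensusNormalizer", "TextExporter")


def lfq_source_workflow() -> tuple[SourceWorkflow, dict]:
    """A label-free-quantification-shaped source workflow: an input-files
    node feeds a loop pair enclosing the per-run identification and
    quantification chain; linking, normalisation and CSV export run once
    after the loop collects all runs."""
    from .ctd import extract_bindings

    nodes = [
        SourceNode(
            id="input_files", kind="input_files",
            files=("run1.mzML", "run2.mzML", "run3.mzML"),
        ),
        SourceNode(id="zip_loop_start", kind="loop_start"),
    ]
    chain = list(_LFQ_INNER) + list(_LFQ_OUTER)
    for name in chain:
        descriptor = _simple_tool(name)
        nodes.append(
            SourceNode(
                id=name, kind="tool",
                descriptor=descriptor,
                bindings=extract_bindings(descriptor),
            )
        )
    nodes.append(
        SourceNode(id="zip_loop_end", kind="loop_end",
                   loop_start_id="zip_loop_start")
    )
    nodes.append(SourceNode(id="csv_out", kind="output"))
    conns = [
        Connection("input_files", "files", "zip_loop_start", "in"),
        Connection("zip_loop_start", "out", _LFQ_INNER[0], "in"),
    ]
    for a, b in zip(_LFQ_INNER, _LFQ_INNER[1:]):
        conns.append(Connection(a, "out", b, "in"))
    conns.append(Connection(_LFQ_INNER[-1], "out", "zip_loop_end", "in"))
    conns.append(Connection("zip_loop_end", "out", _LFQ_OUTER[0], "in"))
    for a, b in zip(_LFQ_OUTER, _LFQ_OUTER[1:]):
        conns.append(Connection(a, "out", b, "in"))
    conns.append(Connection(_LFQ_OUTER[-1], "out", "csv_out", "in"))
    truth = {
        "n_tools": len(chain),
        "loop_nodes": 2,
        "sweep_members": set(_LFQ_INNER),
        "generator_ports": {(_LFQ_INNER[0], "in")},
        "collector_ports": {(_LFQ_INNER[-1], "out")},
        "workflow_inputs": [(_LFQ_INNER[0], "in")],
        "workflow_outputs": [(_LFQ_OUTER[-1], "out")],
    }
    return SourceWorkflow(nodes=nodes, connections=conns), truth


# ---------------------------------------------------------------------------
# executable stubs for process tests

_ECHO_STUB = """#!/usr/bin/env python3
import sys
for arg in sys.argv:
    print(arg)
"""
_NOOP_STUB = "#!/usr/bin/env python3\n"
_FAIL_STUB = """#!/usr/bin/env python3
import sys
sys.stderr.write("stub failure\\n")
sys.exit(3)
"""


def _write_stub(directory, name: str, body: str) -> Path:
    path = Path(directory) / name
    path.write_text(body)
    path.chmod(0o755)
    return path


def make_echo_stub(directory) -> Path:
    """Executable that prints its argv one entry per line and exits 0."""
    return _write_stub(directory, "echo_stub", _ECHO_STUB)


def make_noop_stub(directory) -> Path:
    return _write_stub(directory, "noop_stub", _NOOP_STUB)


def make_failing_stub(directory) -> Path:
    return _write_stub(directory, "fail_stub", _FAIL_STUB)
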