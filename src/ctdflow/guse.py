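"""Emit and re-read a gUSE/WS-PGRADE-style two-layer workflow bundle.

The portal model separates workflow creation into an *abstract graph*
(jobs, ports, channels — application domain only) and a node-per-node
*concrete* configuration (command line, parameter values, target resource).
The bundle mirrors that split as a ZIP archive with a documented layout
(versioned dialect, not a bit-exact clone of any portal release)::

    bundle/
      abstract.xml        # the abstract graph (engine-neutral workflow XML)
      jobs/<job id>.xml   # one concrete configuration per job

Each job configuration carries the exact argv the wrapper would execute,
the job's ports (sweep generator/collector ports carry a ``sweep``
property attribute — the property-key names are this dialect's own), the
embedded value-CTD, and an opaque resource hint.  Archive entries are
sorted and timestamps fixed to the ZIP epoch, so writing the same graph is
byte-stable from the first write.
"""

from __future__ import annotations

import io
import zipfile
from pathlib import Path
from typing import Union
from xml.sax.saxutils import escape, quoteattr

from lxml import etree

from .ctd import apply_bindings, extract_bindings, parse_ctd, write_ctd
from .errors import BundleError
from .workflow import (
    Port,
    WorkflowGraph,
    abstract_view,
    validate_graph,
    write_workflow_xml,
    parse_workflow_xml,
)
from .wrapper import build_command

__all__ = ["write_bundle", "read_bundle", "BUNDLE_VERSION"]

BUNDLE_VERSION = "1"
_EPOCH = (1980, 1, 1, 0, 0, 0)


def _job_xml(task) -> str:
    invocation = build_command(task.descriptor, task.bindings)
    out = ['<?xml version="1.0" encoding="UTF-8"?>']
    attrs = f" id={quoteattr(task.id)} label={quoteattr(task.label)}"
    if task.resource_hint is not None:
        attrs += f" resource_hint={quoteattr(task.resource_hint)}"
    out.append(f"<job{attrs}>")
    out.append("  <command>")
    for arg in invocation.argv:
        out.append(f"    <arg>{escape(arg)}</arg>")
    out.append("  </command>")
    if task.ports:
        out.append("  <ports>")
        for port in task.ports:
            pattrs = (
                f" name={quoteattr(port.name)}"
                f" direction={quoteattr(port.direction)}"
            )
            if port.format is not None:
                pattrs += f" format={quoteattr(port.format)}"
            if port.sweep_role != "none":
                pattrs += f" sweep={quoteattr(port.sweep_role)}"
            if not port.required:
                pattrs += ' required="false"'
            out.append(f"    <port{pattrs}/>")
        out.append("  </ports>")
    else:
        out.append("  <ports/>")
    ctd_text = write_ctd(apply_bindings(task.descriptor, task.bindings))
    for line in ctd_text.split("\n", 1)[1].rstrip("\n").split("\n"):
        out.append(f"  {line}")
    out.append("</job>")
    return "\n".join(out) + "\n"


def write_bundle(graph: WorkflowGraph) -> bytes:
    """Serialize a concrete workflow graph to the two-layer bundle.

    Every task must carry a descriptor and bindings; sweep roles must sit
    on ports of the matching direction (generator on an in-port, collector
    on an out-port).
    """
    validate_graph(graph)
    for task in graph.tasks:
        if task.descriptor is None or task.bindings is None:
            raise BundleError(
                f"task {task.id!r} has no concrete configuration "
                "(descriptor and bindings are required)"
            )
        for port in task.ports:
            if port.sweep_role == "generator" and port.direction != "in":
                raise BundleError(
                    f"task {task.id!r}: generator role on out-port {port.name!r}"
                )
            if port.sweep_role == "collector" and port.direction != "out":
                raise BundleError(
                    f"task {task.id!r}: collector role on in-port {port.name!r}"
                )
    members: dict[str, str] = {
        "abstract.xml": write_workflow_xml(abstract_view(graph)),
        "bundle.xml": (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<bundle version="{BUNDLE_VERSION}" jobs="{len(graph.tasks)}"/>\n'
        ),
    }
    for task in graph.tasks:
        members[f"jobs/{task.id}.xml"] = _job_xml(task)
    buffer = io.BytesIO()
    with zipfile.ZipFile(buffer, "w", zipfile.ZIP_DEFLATED) as archive:
        for name in sorted(members):
            info = zipfile.ZipInfo(name, date_time=_EPOCH)
            info.external_attr = 0o644 << 16
            archive.writestr(info, members[name])
    return buffer.getvalue()


def read_bundle(archive: Union[bytes, str, Path]) -> WorkflowGraph:
    """Reconstruct the workflow graph from a bundle.

    The abstract graph supplies the topology; each job configuration
    restores descriptor, bindings and resource hint, and is cross-checked
    against the recorded command line.
    """
    if isinstance(archive, (str, Path)):
        archive = Path(archive).read_bytes()
    try:
        zf = zipfile.ZipFile(io.BytesIO(archive))
    except zipfile.BadZipFile as exc:
        raise BundleError(f"not a bundle archive: {exc}") from exc
    names = set(zf.namelist())
    if "abstract.xml" not in names:
        raise BundleError("bundle has no abstract.xml")
    graph = parse_workflow_xml(zf.read("abstract.xml"))
    known = {t.id for t in graph.tasks}
    for name in sorted(names):
        if not name.startswith("jobs/") or not name.endswith(".xml"):
            continue
        root = etree.fromstring(zf.read(name))
        job_id = root.get("id")
        if job_id not in known:
            raise BundleError(
                f"job configuration {name!r} references unknown job {job_id!r}"
            )
        task = graph.task(job_id)
        task.label = root.get("label", task.label)
        task.resource_hint = root.get("resource_hint")
        tool_elem = root.find("tool")
        if tool_elem is None:
            raise BundleError(f"job {job_id!r}: missing embedded value-CTD")
        task.descriptor = parse_ctd(etree.tostring(tool_elem))
        task.bindings = extract_bindings(task.descriptor)
        ports_elem = root.find("ports")
        if ports_elem is not None:
            ports = []
            for pe in ports_elem:
                ports.append(
                    Port(
                        name=pe.get("name"),
                        direction=pe.get("direction"),
                        format=pe.get("format"),
                        sweep_role=pe.get("sweep", "none"),
                        required=pe.get("required", "true") == "true",
                    )
                )
            task.ports = ports
        recorded = tuple(
            (arg.text or "") for arg in root.findall("command/arg")
        )
        rebuilt = build_command(task.descriptor, task.bindings).argv
        if recorded != rebuilt:
            raise BundleError(
                f"job {job_id!r}: recorded command line does not match the "
                "embedded value-CTD"
            )
    for task in graph.tasks:
        if task.descriptor is None:
            raise BundleError(f"bundle has no job configuration for {task.id!r}")
    validate_graph(graph)
    return graph
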