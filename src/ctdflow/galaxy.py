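"""Convert tool descriptors to Galaxy ToolConfig XML and back.

CTD is the more restricted format, so descriptor → ToolConfig always
succeeds; the reverse direction rejects ToolConfig documents using
constructs that have no CTD counterpart.  The closed list of rejected
constructs is: ``conditional`` blocks, ``repeat`` blocks, template control
flow in the command (``#if``/``#for`` and friends), and configfiles
containing such logic.  Unknown tags elsewhere are skipped with a warning
entry in the report, never silently.

Type map (both directions):

==============  ===================
CTD             Galaxy
==============  ===================
int             integer (min/max)
float           float (min/max)
bool            boolean (truevalue carries the flag)
string          text
string+choices  select (options)
input-file      data (format)
output-file     output data (format)
list variants   same, ``multiple="true"``, values comma-joined
==============  ===================

Parameter paths map to Galaxy names with ``.`` replaced by ``__`` so that
group nesting survives the flat Galaxy namespace; runs of advanced
parameters are wrapped in collapsed ``<section>`` elements and flattened
back into the tree on import.  The generated command template contains the
same flags :func:`ctdflow.wrapper.build_command` would emit, with
``$name`` placeholders and no control flow, which keeps emitted documents
inside the convertible subset by construction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional
from xml.sax.saxutils import escape, quoteattr

from lxml import etree

from .ctd import (
    Parameter,
    ParameterGroup,
    Restriction,
    ToolDescriptor,
    format_value,
    parse_value_text,
)
from .errors import CTDParseError
from .report import ConversionReport
from .wrapper import flag_for

__all__ = [
    "GalaxyParam",
    "GalaxyOutput",
    "GalaxyTool",
    "ConversionReport",
    "ctd_to_galaxy",
    "galaxy_to_ctd",
    "write_galaxy_xml",
    "parse_galaxy_xml",
    "UNSUPPORTED_TAGS",
    "TEMPLATE_CONTROL_TOKENS",
]

UNSUPPORTED_TAGS = ("conditional", "repeat")
TEMPLATE_CONTROL_TOKENS = ("#if", "#for", "#while", "#unless", "#else", "#end")

_TYPE_TO_GALAXY = {
    "int": "integer",
    "float": "float",
    "bool": "boolean",
    "string": "text",
    "input-file": "data",
}
_GALAXY_TO_TYPE = {
    "integer": "int",
    "float": "float",
    "boolean": "bool",
    "text": "string",
    "data": "input-file",
    "select": "string",
}


@dataclass
class GalaxyParam:
    name: str
    gtype: str
    value: Optional[str] = None
    optional: bool = True
    label: str = ""
    minimum: Optional[str] = None
    maximum: Optional[str] = None
    options: tuple = ()  # (value, selected) pairs for selects
    multiple: bool = False
    truevalue: Optional[str] = None
    checked: Optional[str] = None
    format: Optional[str] = None
    advanced: bool = False


@dataclass
class GalaxyOutput:
    name: str
    format: Optional[str] = None
    label: str = ""
    advanced: bool = False
    value: Optional[str] = None  # preset filename(s), comma-joined for lists
    multiple: bool = False
    optional: bool = False


@dataclass
class GalaxyTool:
    id: str
    name: str
    version: str
    description: str = ""
    inputs: list = field(default_factory=list)
    outputs: list = field(default_factory=list)
    command_template: str = ""
    unsupported_constructs: list = field(default_factory=list)


def _galaxy_name(path: str) -> str:
    return path.replace(".", "__")


def _ctd_path(name: str) -> str:
    return name.replace("__", ".")


# ---------------------------------------------------------------------------
# CTD -> Galaxy


def ctd_to_galaxy(descriptor: ToolDescriptor) -> tuple[GalaxyTool, ConversionReport]:
    """Map a descriptor onto a Galaxy tool; this direction always succeeds
    and the report lists every parameter mapping."""
    report = ConversionReport()
    tool = GalaxyTool(
        id=descriptor.name,
        name=descriptor.name,
        version=descriptor.version,
        description=descriptor.description,
    )
    command = [descriptor.executable_name]
    for path, param in descriptor.flat_parameters():
        gname = _galaxy_name(path)
        flag = flag_for(descriptor, path)
        if param.base_type == "output-file":
            value = None
            if param.default is not None:
                value = (
                    ",".join(param.default) if param.is_list else param.default
                )
            tool.outputs.append(
                GalaxyOutput(
                    name=gname,
                    format=",".join(param.file_formats) or None,
                    label=param.description,
                    advanced=param.advanced,
                    value=value,
                    multiple=param.is_list,
                    optional=not param.required,
                )
            )
            command.append(f"{flag} ${gname}")
            report.mapped.append((path, gname, f"{param.value_type} -> output"))
            continue
        if param.base_type == "bool":
            gtype = "boolean"
        elif param.base_type == "string" and param.restriction is not None:
            gtype = "select"
        else:
            gtype = _TYPE_TO_GALAXY[param.base_type]
        gp = GalaxyParam(
            name=gname,
            gtype=gtype,
            optional=not param.required,
            label=param.description,
            multiple=param.is_list,
            advanced=param.advanced,
        )
        if gtype == "boolean":
            gp.truevalue = flag
            if param.is_list:
                if param.default is not None:
                    gp.value = ",".join(
                        format_value("bool", v) for v in param.default
                    )
            elif param.default is not None:
                gp.checked = format_value("bool", param.default)
            command.append(f"${gname}")
        else:
            if param.restriction is not None:
                if param.restriction.kind == "numeric_range":
                    if param.restriction.min_value is not None:
                        gp.minimum = format_value(
                            param.base_type, param.restriction.min_value
                        )
                    if param.restriction.max_value is not None:
                        gp.maximum = format_value(
                            param.base_type, param.restriction.max_value
                        )
                else:
                    selected = ()
                    if param.default is not None:
                        selected = (
                            tuple(param.default)
                            if param.is_list
                            else (param.default,)
                        )
                    gp.options = tuple(
                        (c, c in selected) for c in param.restriction.choices
                    )
                    if param.is_list and param.default is not None:
                        gp.value = ",".join(param.default)
            if gtype != "select" and param.default is not None:
                if param.is_list:
                    gp.value = ",".join(
                        format_value(param.base_type, v) for v in param.default
                    )
                else:
                    gp.value = format_value(param.base_type, param.default)
            if gtype == "data":
                gp.format = ",".join(param.file_formats) or None
            command.append(f"{flag} ${gname}")
        tool.inputs.append(gp)
        report.mapped.append((path, gname, f"{param.value_type} -> {gtype}"))
    tool.command_template = " ".join(command)
    return tool, report.finalize()


def write_galaxy_xml(tool: GalaxyTool) -> str:
    """Canonical ToolConfig serialization (byte-stable)."""
    out = ['<?xml version="1.0" encoding="UTF-8"?>']
    out.append(
        f"<tool id={quoteattr(tool.id)} name={quoteattr(tool.name)} "
        f"version={quoteattr(tool.version)}>"
    )
    if tool.description:
        out.append(f"  <description>{escape(tool.description)}</description>")
    out.append(f"  <command><![CDATA[{tool.command_template}]]></command>")

    def param_line(gp: GalaxyParam, indent: str) -> list[str]:
        pairs = [("name", gp.name), ("type", gp.gtype)]
        if gp.value is not None:
            pairs.append(("value", gp.value))
        if gp.truevalue is not None:
            pairs.append(("truevalue", gp.truevalue))
            pairs.append(("falsevalue", ""))
        if gp.checked is not None:
            pairs.append(("checked", gp.checked))
        if gp.minimum is not None:
            pairs.append(("min", gp.minimum))
        if gp.maximum is not None:
            pairs.append(("max", gp.maximum))
        if gp.format is not None:
            pairs.append(("format", gp.format))
        if gp.multiple:
            pairs.append(("multiple", "true"))
        pairs.append(("optional", "true" if gp.optional else "false"))
        if gp.label:
            pairs.append(("label", gp.label))
        attrs = "".join(f" {k}={quoteattr(v)}" for k, v in pairs)
        if gp.options:
            lines = [f"{indent}<param{attrs}>"]
            for value, selected in gp.options:
                sel = ' selected="true"' if selected else ""
                lines.append(
                    f"{indent}  <option value={quoteattr(value)}{sel}>"
                    f"{escape(value)}</option>"
                )
            lines.append(f"{indent}</param>")
            return lines
        return [f"{indent}<param{attrs}/>"]

    if tool.inputs:
        out.append("  <inputs>")
        section_no = 0
        i = 0
        while i < len(tool.inputs):
            gp = tool.inputs[i]
            if gp.advanced:
                section_no += 1
                suffix = "" if section_no == 1 else f"_{section_no}"
                out.append(
                    f'    <section name="advanced{suffix}" '
                    'title="Advanced options" expanded="false">'
                )
                while i < len(tool.inputs) and tool.inputs[i].advanced:
                    out.extend(param_line(tool.inputs[i], "      "))
                    i += 1
                out.append("    </section>")
            else:
                out.extend(param_line(gp, "    "))
                i += 1
        out.append("  </inputs>")
    else:
        out.append("  <inputs/>")
    if tool.outputs:
        out.append("  <outputs>")
        for go in tool.outputs:
            pairs = [("name", go.name)]
            if go.format is not None:
                pairs.append(("format", go.format))
            if go.value is not None:
                pairs.append(("value", go.value))
            if go.multiple:
                pairs.append(("multiple", "true"))
            if go.optional:
                pairs.append(("optional", "true"))
            if go.label:
                pairs.append(("label", go.label))
            if go.advanced:
                pairs.append(("advanced", "true"))
            attrs = "".join(f" {k}={quoteattr(v)}" for k, v in pairs)
            out.append(f"    <data{attrs}/>")
        out.append("  </outputs>")
    else:
        out.append("  <outputs/>")
    out.append("</tool>")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Galaxy -> CTD


def _scan_command(text: str, report: ConversionReport) -> None:
    for token in TEMPLATE_CONTROL_TOKENS:
        if token in text:
            report.reject("template-control-flow")
            return


def parse_galaxy_xml(document) -> tuple[GalaxyTool, ConversionReport]:
    """Parse a ToolConfig document into a :class:`GalaxyTool`, collecting
    every unsupported construct into both the tool and the report."""
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise CTDParseError(f"malformed ToolConfig XML: {exc}") from exc
    if root.tag != "tool":
        raise CTDParseError(f"root element must be <tool>, got <{root.tag}>")
    report = ConversionReport()
    tool = GalaxyTool(
        id=root.get("id") or "",
        name=root.get("name") or root.get("id") or "",
        version=root.get("version") or "1.0",
    )

    def parse_param(elem, advanced: bool) -> None:
        gp = GalaxyParam(
            name=elem.get("name") or "",
            gtype=elem.get("type") or "text",
            value=elem.get("value"),
            optional=elem.get("optional", "false") == "true",
            label=elem.get("label", ""),
            minimum=elem.get("min"),
            maximum=elem.get("max"),
            multiple=elem.get("multiple") == "true",
            truevalue=elem.get("truevalue"),
            checked=elem.get("checked"),
            format=elem.get("format"),
            advanced=advanced,
        )
        options = []
        for opt in elem:
            if opt.tag == "option":
                options.append(
                    (opt.get("value") or "", opt.get("selected") == "true")
                )
        gp.options = tuple(options)
        tool.inputs.append(gp)

    def walk_inputs(parent, advanced: bool) -> None:
        for elem in parent:
            if elem.tag is etree.Comment:
                continue
            if elem.tag in UNSUPPORTED_TAGS:
                report.reject(elem.tag)
            elif elem.tag == "param":
                parse_param(elem, advanced)
            elif elem.tag == "section":
                collapsed = (
                    elem.get("expanded", "true") == "false"
                    or (elem.get("name") or "").startswith("advanced")
                )
                walk_inputs(elem, advanced or collapsed)
            else:
                report.dropped.append(
                    (f"inputs/{elem.tag}", "unknown element, skipped")
                )

    for child in root:
        if child.tag is etree.Comment:
            continue
        if child.tag == "description":
            tool.description = child.text or ""
        elif child.tag == "command":
            tool.command_template = (child.text or "").strip()
            _scan_command(tool.command_template, report)
        elif child.tag == "inputs":
            walk_inputs(child, False)
        elif child.tag == "outputs":
            for elem in child:
                if elem.tag is etree.Comment:
                    continue
                if elem.tag == "data":
                    tool.outputs.append(
                        GalaxyOutput(
                            name=elem.get("name") or "",
                            format=elem.get("format"),
                            label=elem.get("label", ""),
                            advanced=elem.get("advanced") == "true",
                            value=elem.get("value"),
                            multiple=elem.get("multiple") == "true",
                            optional=elem.get("optional") == "true",
                        )
                    )
                else:
                    report.dropped.append(
                        (f"outputs/{elem.tag}", "unknown element, skipped")
                    )
        elif child.tag == "configfiles":
            for cf in child:
                text = cf.text or ""
                if any(tok in text for tok in TEMPLATE_CONTROL_TOKENS):
                    report.reject("configfile-logic")
                else:
                    report.dropped.append(
                        ("configfiles", "configfile without logic, skipped")
                    )
        elif child.tag in UNSUPPORTED_TAGS:
            report.reject(child.tag)
        elif child.tag in ("help", "tests", "citations", "requirements",
                           "stdio", "version_command"):
            pass  # documentation/packaging elements carry no parameters
        else:
            report.dropped.append((child.tag, "unknown element, skipped"))
    tool.unsupported_constructs = list(report.rejections)
    return tool, report.finalize()


_PLACEHOLDER_RE = re.compile(r"\$\{?([A-Za-z_][A-Za-z0-9_]*)\}?")


def _command_order(command: str) -> list[str]:
    seen: list[str] = []
    for match in _PLACEHOLDER_RE.finditer(command):
        name = match.group(1)
        if name not in seen:
            seen.append(name)
    return seen


def _split_list(text: str, base_type: str, path: str) -> list:
    if text == "":
        return []
    return [parse_value_text(base_type, v, path) for v in text.split(",")]


def _param_from_galaxy(gp: GalaxyParam, report: ConversionReport) -> Parameter:
    path = _ctd_path(gp.name)
    name = path.rsplit(".", 1)[-1]
    base = _GALAXY_TO_TYPE.get(gp.gtype)
    if base is None:
        report.dropped.append(
            (gp.name, f"unknown param type {gp.gtype!r}, treated as text")
        )
        base = "string"
    vtype = base + ("-list" if gp.multiple else "")
    restriction = None
    default = None
    if gp.gtype == "select":
        restriction = Restriction(
            "choice_list", choices=tuple(v for v, _ in gp.options)
        )
        if gp.multiple:
            if gp.value is not None:
                default = _split_list(gp.value, "string", path)
        else:
            selected = [v for v, sel in gp.options if sel]
            if selected:
                default = selected[0]
    elif gp.gtype == "boolean":
        if gp.multiple:
            if gp.value is not None:
                default = _split_list(gp.value, "bool", path)
        elif gp.checked is not None:
            default = parse_value_text("bool", gp.checked, path)
    else:
        if gp.minimum is not None or gp.maximum is not None:
            restriction = Restriction(
                "numeric_range",
                min_value=parse_value_text(base, gp.minimum, path)
                if gp.minimum is not None
                else None,
                max_value=parse_value_text(base, gp.maximum, path)
                if gp.maximum is not None
                else None,
            )
        if gp.value is not None:
            if gp.multiple:
                default = _split_list(gp.value, base, path)
            else:
                default = parse_value_text(base, gp.value, path)
    formats = ()
    if base == "input-file" and gp.format:
        formats = tuple(f for f in gp.format.split(",") if f)
    return Parameter(
        name=name,
        value_type=vtype,
        default=default,
        required=not gp.optional,
        advanced=gp.advanced,
        description=gp.label,
        restriction=restriction,
        file_formats=formats,
    )


def _build_tree(ordered: list[tuple[str, Parameter]]) -> ParameterGroup:
    root = ParameterGroup(name="")
    groups: dict[str, ParameterGroup] = {"": root}

    def group_for(prefix: str) -> ParameterGroup:
        if prefix in groups:
            return groups[prefix]
        parent_prefix, _, gname = prefix.rpartition(".")
        parent = group_for(parent_prefix)
        group = ParameterGroup(name=gname)
        parent.children.append(group)
        groups[prefix] = group
        return group

    for path, param in ordered:
        prefix = path.rpartition(".")[0]
        group_for(prefix).children.append(param)
    # re-validate child-name uniqueness now that the tree is assembled
    def revalidate(group: ParameterGroup) -> None:
        group.__post_init__()
        for child in group.children:
            if isinstance(child, ParameterGroup):
                revalidate(child)

    revalidate(root)
    return root


def galaxy_to_ctd(document) -> tuple[Optional[ToolDescriptor], ConversionReport]:
    """Convert a ToolConfig document to a descriptor.

    Returns ``(descriptor, report)`` for convertible tools and ``(None,
    report)`` when the document uses constructs outside the CTD subset;
    the report then names every offending construct.
    """
    tool, report = parse_galaxy_xml(document)
    if report.rejections:
        return None, report
    params: dict[str, Parameter] = {}
    order_hint: list[str] = []
    for gp in tool.inputs:
        params[gp.name] = _param_from_galaxy(gp, report)
        order_hint.append(gp.name)
    for go in tool.outputs:
        path = _ctd_path(go.name)
        default = None
        if go.value is not None:
            default = (
                _split_list(go.value, "output-file", path)
                if go.multiple
                else go.value
            )
        params[go.name] = Parameter(
            name=path.rsplit(".", 1)[-1],
            value_type="output-file" + ("-list" if go.multiple else ""),
            default=default,
            required=not go.optional,
            advanced=go.advanced,
            description=go.label,
            file_formats=tuple(f for f in (go.format or "").split(",") if f),
        )
        order_hint.append(go.name)
    # document order: command-template placeholder order first (it reflects
    # the source tool's parameter order), then any params the command omits
    cmd_order = [n for n in _command_order(tool.command_template) if n in params]
    ordered_names = cmd_order + [n for n in order_hint if n not in cmd_order]
    ordered = [(_ctd_path(n), params[n]) for n in ordered_names]
    executable = tool.command_template.split()[0] if tool.command_template else ""
    try:
        descriptor = ToolDescriptor(
            name=tool.id or tool.name or "tool",
            version=tool.version,
            description=tool.description,
            executable_name=executable or (tool.id or tool.name or "tool"),
            parameters=_build_tree(ordered),
        )
    except Exception as exc:  # duplicate paths etc.
        raise CTDParseError(f"ToolConfig does not map to a valid CTD: {exc}")
    for name in ordered_names:
        path = _ctd_path(name)
        report.mapped.append((name, path, f"-> {params[name].value_type}"))
    return descriptor, report.finalize()
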