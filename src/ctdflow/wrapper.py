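"""Execute CTD-described tools: build argv vectors, capture existing
command-line tools as descriptors, and run them.

The flag for a parameter is a single leading dash plus the parameter's name
when that name is unique across the whole descriptor, and the full dotted
path otherwise (``-in`` vs ``-algorithm.param.in``).  Parameters are emitted
in descriptor (document) order, so identical descriptor+bindings always
produce identical argv; no shell is ever involved.
"""

from __future__ import annotations

import subprocess
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .ctd import (
    Parameter,
    ParameterGroup,
    Restriction,
    ToolDescriptor,
    ValueBindings,
    format_value,
    validate_values,
    write_ctd,
)
from .errors import DescriptorError, ToolExecutionError

__all__ = [
    "CommandInvocation",
    "ToolResult",
    "ParamDecl",
    "flag_for",
    "build_command",
    "capture_tool",
    "run_tool",
    "handle_write_ctd",
]


@dataclass(frozen=True)
class CommandInvocation:
    """A fully resolved command line.  ``argv[0]`` is the executable;
    declared inputs/outputs record which argv entries are filenames."""

    argv: tuple[str, ...]
    declared_inputs: tuple[tuple[str, str], ...] = ()  # (param path, filename)
    declared_outputs: tuple[tuple[str, str], ...] = ()


@dataclass
class ToolResult:
    exit_code: int
    stdout: str
    stderr: str


def flag_for(descriptor: ToolDescriptor, path: str) -> str:
    """Derive the command-line flag for a parameter path: ``-name`` when the
    leaf name is unique within the descriptor, ``-full.dotted.path`` when
    several parameters share the leaf name."""
    leaf = path.rsplit(".", 1)[-1]
    leaf_counts = Counter(p.rsplit(".", 1)[-1] for p in descriptor.paths())
    return f"-{leaf}" if leaf_counts[leaf] == 1 else f"-{path}"


def build_command(
    descriptor: ToolDescriptor, bindings: ValueBindings
) -> CommandInvocation:
    """Turn validated bindings into an argv vector.

    Booleans become bare flags when true and vanish when false; lists expand
    to one flag followed by all items; everything else is ``-flag value``.
    """
    validated = validate_values(descriptor, bindings)
    argv: list[str] = [descriptor.executable_name]
    inputs: list[tuple[str, str]] = []
    outputs: list[tuple[str, str]] = []
    for path, param in descriptor.flat_parameters():
        if path not in validated.values:
            continue
        value = validated.values[path]
        flag = flag_for(descriptor, path)
        if param.base_type == "bool" and not param.is_list:
            if value:
                argv.append(flag)
            continue
        items = value if param.is_list else [value]
        if not items:
            continue
        argv.append(flag)
        for item in items:
            text = format_value(param.base_type, item)
            argv.append(text)
            if param.base_type == "input-file":
                inputs.append((path, text))
            elif param.base_type == "output-file":
                outputs.append((path, text))
    return CommandInvocation(
        argv=tuple(argv),
        declared_inputs=tuple(inputs),
        declared_outputs=tuple(outputs),
    )


@dataclass
class ParamDecl:
    """One parameter declaration for :func:`capture_tool`: the minimum a
    wrapper author states about an existing tool's option."""

    name: str
    value_type: str
    default: object = None
    required: bool = False
    advanced: bool = False
    description: str = ""
    restriction: Optional[Restriction] = None
    file_formats: tuple[str, ...] = ()


def capture_tool(
    name: str,
    version: str,
    declarations: Sequence[ParamDecl],
    description: str = "",
    executable_name: str = "",
    category: Optional[str] = None,
) -> ToolDescriptor:
    """Bind an existing command-line tool: build a descriptor from an ordered
    list of parameter declarations so the tool becomes CTD-enabled."""
    seen: set[str] = set()
    children = []
    for decl in declarations:
        if decl.name in seen:
            raise DescriptorError(f"duplicate parameter name {decl.name!r}")
        seen.add(decl.name)
        children.append(
            Parameter(
                name=decl.name,
                value_type=decl.value_type,
                default=decl.default,
                required=decl.required,
                advanced=decl.advanced,
                description=decl.description,
                restriction=decl.restriction,
                file_formats=decl.file_formats,
            )
        )
    return ToolDescriptor(
        name=name,
        version=version,
        description=description,
        executable_name=executable_name or name,
        category=category,
        parameters=ParameterGroup(name="", children=children),
    )


def run_tool(
    invocation: CommandInvocation, cwd: Optional[str] = None
) -> ToolResult:
    """Run the invocation as a child process (argv vector, never a shell)
    and capture both streams.

    Raises :class:`ToolExecutionError` when the executable cannot be found
    or exits non-zero; the error carries an excerpt of stderr.
    """
    try:
        proc = subprocess.run(
            list(invocation.argv),
            capture_output=True,
            text=True,
            cwd=cwd,
        )
    except FileNotFoundError as exc:
        raise ToolExecutionError(
            f"executable {invocation.argv[0]!r} not found"
        ) from exc
    if proc.returncode != 0:
        excerpt = proc.stderr[-2000:]
        raise ToolExecutionError(
            f"{invocation.argv[0]!r} exited with status {proc.returncode}: "
            f"{excerpt}",
            exit_code=proc.returncode,
            stderr=proc.stderr,
        )
    return ToolResult(proc.returncode, proc.stdout, proc.stderr)


def handle_write_ctd(descriptor: ToolDescriptor, argv: Sequence[str]) -> bool:
    """Support the ``--write-ctd <file>`` convention: if present in *argv*,
    dump the tool's descriptor to the named file and report True so the
    wrapper can exit without running the tool."""
    args = list(argv)
    if "--write-ctd" not in args:
        return False
    idx = args.index("--write-ctd")
    if idx + 1 >= len(args):
        raise ToolExecutionError("--write-ctd requires a file argument")
    with open(args[idx + 1], "w", encoding="utf-8") as fh:
        fh.write(write_ctd(descriptor))
    return True
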