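"""Common Tool Descriptor (CTD) documents: model, parse, validate, serialize.

A CTD is an XML description of a command-line tool: its identity, its
executable, and a typed tree of parameters (plain values and input/output
files) with optional restrictions.  The dialect implemented here is
self-contained and documented below; it is deliberately small so that every
document has exactly one canonical serialization.

Dialect
-------
::

    <?xml version="1.0" encoding="UTF-8"?>
    <tool name="PDBCutter" version="1.0.0">
      <description>Cuts chains out of PDB files</description>
      <executable>PDBCutter</executable>
      <category>Structure</category>            <!-- optional -->
      <parameters>
        <group name="io" description="...">
          <item name="in" type="input-file" value="x.pdb" required="true"
                advanced="false" supported_formats="pdb"/>
        </group>
        <item name="threads" type="int" value="1" required="false"
              advanced="true" restrictions="1:64"/>
      </parameters>
    </tool>

* ``type`` is one of ``int``, ``float``, ``string``, ``bool``,
  ``input-file``, ``output-file`` or any of those with a ``-list`` suffix.
* Scalar defaults/values live in the ``value`` attribute; list values are
  repeated ``<value>`` child elements (never comma-split, so commas are
  legal inside string items).
* ``restrictions`` holds ``min:max`` (inclusive, either end may be open:
  ``3:`` / ``:7``) for numeric types, and a comma-separated choice list for
  strings.
* Canonical form: 2-space indent, fixed attribute order
  (``name, type, value, required, advanced, restrictions,
  supported_formats, description``), UTF-8, trailing newline.  Writing the
  same descriptor twice yields byte-identical documents.
* Unknown attributes and unknown child elements of ``<tool>`` are preserved
  verbatim as opaque annotations and echoed on write; ``strict=True``
  rejects them instead.

A *value-CTD* is simply a CTD whose ``value`` attributes have been filled
in with concrete bindings; :func:`apply_bindings` and
:func:`extract_bindings` convert between the two views.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union
from xml.sax.saxutils import escape, quoteattr

from lxml import etree

from .errors import BindingError, CTDParseError, DescriptorError

__all__ = [
    "Restriction",
    "Parameter",
    "ParameterGroup",
    "ToolDescriptor",
    "ValueBindings",
    "parse_ctd",
    "write_ctd",
    "validate_values",
    "merge_overrides",
    "extract_bindings",
    "apply_bindings",
    "BASE_TYPES",
    "VALUE_TYPES",
]

BASE_TYPES = ("int", "float", "string", "bool", "input-file", "output-file")
VALUE_TYPES = BASE_TYPES + tuple(t + "-list" for t in BASE_TYPES)

_IDENT_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_\-]*$")


def _check_identifier(name: str, what: str) -> None:
    if not _IDENT_RE.match(name):
        raise DescriptorError(f"{what} {name!r} is not a valid identifier")


@dataclass(frozen=True)
class Restriction:
    """Constraint on a parameter's values.

    ``numeric_range`` bounds are inclusive and either end may be open.
    ``choice_list`` enumerates the admissible strings.
    """

    kind: str  # "numeric_range" | "choice_list"
    min_value: Optional[float] = None
    max_value: Optional[float] = None
    choices: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind == "numeric_range":
            if self.min_value is None and self.max_value is None:
                raise DescriptorError("numeric_range needs at least one bound")
            if (
                self.min_value is not None
                and self.max_value is not None
                and self.min_value > self.max_value
            ):
                raise DescriptorError(
                    f"numeric_range min {self.min_value} > max {self.max_value}"
                )
            if self.choices:
                raise DescriptorError("numeric_range carries no choices")
        elif self.kind == "choice_list":
            if not self.choices:
                raise DescriptorError("choice_list must not be empty")
            if len(set(self.choices)) != len(self.choices):
                raise DescriptorError("choice_list has duplicate entries")
            if self.min_value is not None or self.max_value is not None:
                raise DescriptorError("choice_list carries no bounds")
        else:
            raise DescriptorError(f"unknown restriction kind {self.kind!r}")

    def admits(self, value) -> bool:
        """Whether a single (scalar) value satisfies this restriction."""
        if self.kind == "numeric_range":
            if self.min_value is not None and value < self.min_value:
                return False
            if self.max_value is not None and value > self.max_value:
                return False
            return True
        return str(value) in self.choices

    def to_text(self, base_type: str) -> str:
        if self.kind == "choice_list":
            return ",".join(self.choices)
        fmt = (lambda v: str(int(v))) if base_type == "int" else repr
        lo = "" if self.min_value is None else fmt(self.min_value)
        hi = "" if self.max_value is None else fmt(self.max_value)
        return f"{lo}:{hi}"

    @staticmethod
    def from_text(text: str, base_type: str, path: str) -> "Restriction":
        if base_type in ("int", "float"):
            if ":" not in text:
                raise CTDParseError(
                    f"parameter {path!r}: numeric restriction {text!r} "
                    "must use 'min:max' syntax"
                )
            lo_s, _, hi_s = text.partition(":")
            conv = int if base_type == "int" else float
            try:
                lo = conv(lo_s) if lo_s else None
                hi = conv(hi_s) if hi_s else None
            except ValueError as exc:
                raise CTDParseError(
                    f"parameter {path!r}: bad numeric bound in {text!r}"
                ) from exc
            try:
                return Restriction("numeric_range", min_value=lo, max_value=hi)
            except DescriptorError as exc:
                raise CTDParseError(f"parameter {path!r}: {exc}") from exc
        if base_type == "string":
            choices = tuple(c for c in text.split(",") if c)
            try:
                return Restriction("choice_list", choices=choices)
            except DescriptorError as exc:
                raise CTDParseError(f"parameter {path!r}: {exc}") from exc
        raise CTDParseError(
            f"parameter {path!r}: type {base_type!r} admits no restrictions"
        )


@dataclass
class Parameter:
    name: str
    value_type: str
    default: object = None
    required: bool = False
    advanced: bool = False
    description: str = ""
    restriction: Optional[Restriction] = None
    file_formats: tuple[str, ...] = ()
    extra_attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_identifier(self.name, "parameter name")
        if self.value_type not in VALUE_TYPES:
            raise DescriptorError(
                f"parameter {self.name!r}: unknown value type {self.value_type!r}"
            )
        if self.file_formats and not self.is_file:
            raise DescriptorError(
                f"parameter {self.name!r}: file_formats on non-file type "
                f"{self.value_type!r}"
            )
        if self.restriction is not None and self.base_type not in (
            "int",
            "float",
            "string",
        ):
            raise DescriptorError(
                f"parameter {self.name!r}: type {self.value_type!r} "
                "admits no restrictions"
            )
        self.file_formats = tuple(self.file_formats)
        if self.default is not None:
            self.default = check_value(self, self.default, self.name)

    @property
    def is_list(self) -> bool:
        return self.value_type.endswith("-list")

    @property
    def base_type(self) -> str:
        return self.value_type[:-5] if self.is_list else self.value_type

    @property
    def is_file(self) -> bool:
        return self.base_type in ("input-file", "output-file")


@dataclass
class ParameterGroup:
    name: str
    description: str = ""
    children: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.name:  # the root group is anonymous
            _check_identifier(self.name, "group name")
        seen = set()
        for child in self.children:
            if child.name in seen:
                raise DescriptorError(
                    f"group {self.name or '<root>'!r}: duplicate child "
                    f"name {child.name!r}"
                )
            seen.add(child.name)

    def iter_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        """Yield (dotted path, parameter) in document order."""
        for child in self.children:
            path = f"{prefix}{child.name}"
            if isinstance(child, ParameterGroup):
                yield from child.iter_parameters(path + ".")
            else:
                yield path, child


@dataclass
class ToolDescriptor:
    """Structured description of one command-line tool."""

    name: str
    version: str
    description: str = ""
    executable_name: str = ""
    category: Optional[str] = None
    parameters: ParameterGroup = field(
        default_factory=lambda: ParameterGroup(name="")
    )
    extra_attrs: dict = field(default_factory=dict)
    opaque: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise DescriptorError("tool name must be non-empty")
        if not self.version:
            raise DescriptorError("tool version must be non-empty")
        if not self.executable_name:
            self.executable_name = self.name
        self.opaque = tuple(self.opaque)
        paths = [p for p, _ in self.parameters.iter_parameters()]
        if len(paths) != len(set(paths)):
            dup = next(p for p in paths if paths.count(p) > 1)
            raise DescriptorError(f"duplicate parameter path {dup!r}")

    def flat_parameters(self) -> list[tuple[str, Parameter]]:
        return list(self.parameters.iter_parameters())

    def find(self, path: str) -> Parameter:
        for p, param in self.parameters.iter_parameters():
            if p == path:
                return param
        raise BindingError(f"unknown parameter path {path!r}")

    def paths(self) -> list[str]:
        return [p for p, _ in self.parameters.iter_parameters()]


@dataclass
class ValueBindings:
    """Map from parameter path to a typed value (scalar or list)."""

    values: dict = field(default_factory=dict)

    def __getitem__(self, path: str):
        return self.values[path]

    def __contains__(self, path: str) -> bool:
        return path in self.values

    def __len__(self) -> int:
        return len(self.values)

    def items(self):
        return self.values.items()

    def copy(self) -> "ValueBindings":
        return ValueBindings(dict(self.values))


# ---------------------------------------------------------------------------
# value formatting / parsing / checking


def check_value(param: Parameter, value, path: str):
    """Type- and restriction-check one value; returns the (possibly
    normalised) value or raises :class:`BindingError` naming *path*."""
    if param.is_list:
        if not isinstance(value, (list, tuple)):
            raise BindingError(
                f"parameter {path!r}: expected a list for type "
                f"{param.value_type!r}, got {type(value).__name__}"
            )
        return [_check_scalar(param, v, path) for v in value]
    return _check_scalar(param, value, path)


def _check_scalar(param: Parameter, value, path: str):
    base = param.base_type
    if base == "int":
        if isinstance(value, bool) or not isinstance(value, int):
            raise BindingError(
                f"parameter {path!r}: expected int, got {value!r}"
            )
    elif base == "float":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise BindingError(
                f"parameter {path!r}: expected float, got {value!r}"
            )
        value = float(value)
    elif base == "bool":
        if not isinstance(value, bool):
            raise BindingError(
                f"parameter {path!r}: expected bool, got {value!r}"
            )
    else:  # string and file types are strings
        if not isinstance(value, str):
            raise BindingError(
                f"parameter {path!r}: expected string, got {value!r}"
            )
    if param.restriction is not None and not param.restriction.admits(value):
        raise BindingError(
            f"parameter {path!r}: value {value!r} violates restriction "
            f"{param.restriction.to_text(param.base_type)!r}"
        )
    return value


def format_value(base_type: str, value) -> str:
    """Render one scalar as its canonical attribute text."""
    if base_type == "bool":
        return "true" if value else "false"
    if base_type == "float":
        return repr(float(value))
    return str(value)


def parse_value_text(base_type: str, text: str, path: str):
    if base_type == "int":
        try:
            return int(text)
        except ValueError as exc:
            raise CTDParseError(
                f"parameter {path!r}: bad int value {text!r}"
            ) from exc
    if base_type == "float":
        try:
            return float(text)
        except ValueError as exc:
            raise CTDParseError(
                f"parameter {path!r}: bad float value {text!r}"
            ) from exc
    if base_type == "bool":
        if text == "true":
            return True
        if text == "false":
            return False
        raise CTDParseError(
            f"parameter {path!r}: bad bool value {text!r} "
            "(expected 'true' or 'false')"
        )
    return text


# ---------------------------------------------------------------------------
# serialization (canonical form)

_ITEM_ATTR_ORDER = (
    "name",
    "type",
    "value",
    "required",
    "advanced",
    "restrictions",
    "supported_formats",
    "description",
)


def _attrs_text(pairs: list[tuple[str, str]]) -> str:
    return "".join(f" {k}={quoteattr(v)}" for k, v in pairs)


def _write_item(param: Parameter, indent: str, out: list[str]) -> None:
    pairs = [("name", param.name), ("type", param.value_type)]
    scalar_default = param.default is not None and not param.is_list
    if scalar_default:
        pairs.append(("value", format_value(param.base_type, param.default)))
    pairs.append(("required", "true" if param.required else "false"))
    pairs.append(("advanced", "true" if param.advanced else "false"))
    if param.restriction is not None:
        pairs.append(("restrictions", param.restriction.to_text(param.base_type)))
    if param.file_formats:
        pairs.append(("supported_formats", ",".join(param.file_formats)))
    if param.description:
        pairs.append(("description", param.description))
    for key in sorted(param.extra_attrs):
        pairs.append((key, param.extra_attrs[key]))
    if param.is_list and param.default is not None:
        out.append(f"{indent}<item{_attrs_text(pairs)}>")
        for item in param.default:
            out.append(
                f"{indent}  <value>"
                f"{escape(format_value(param.base_type, item))}</value>"
            )
        out.append(f"{indent}</item>")
    else:
        out.append(f"{indent}<item{_attrs_text(pairs)}/>")


def _write_group(group: ParameterGroup, indent: str, out: list[str]) -> None:
    for child in group.children:
        if isinstance(child, ParameterGroup):
            pairs = [("name", child.name)]
            if child.description:
                pairs.append(("description", child.description))
            if child.children:
                out.append(f"{indent}<group{_attrs_text(pairs)}>")
                _write_group(child, indent + "  ", out)
                out.append(f"{indent}</group>")
            else:
                out.append(f"{indent}<group{_attrs_text(pairs)}/>")
        else:
            _write_item(child, indent, out)


def write_ctd(descriptor: ToolDescriptor) -> str:
    """Serialize a descriptor to its canonical XML text.

    The output is byte-stable: fixed element and attribute order, 2-space
    indentation, trailing newline.
    """
    out = ['<?xml version="1.0" encoding="UTF-8"?>']
    pairs = [("name", descriptor.name), ("version", descriptor.version)]
    for key in sorted(descriptor.extra_attrs):
        pairs.append((key, descriptor.extra_attrs[key]))
    out.append(f"<tool{_attrs_text(pairs)}>")
    if descriptor.description:
        out.append(f"  <description>{escape(descriptor.description)}</description>")
    out.append(f"  <executable>{escape(descriptor.executable_name)}</executable>")
    if descriptor.category is not None:
        out.append(f"  <category>{escape(descriptor.category)}</category>")
    if descriptor.parameters.children:
        out.append("  <parameters>")
        _write_group(descriptor.parameters, "    ", out)
        out.append("  </parameters>")
    else:
        out.append("  <parameters/>")
    for blob in descriptor.opaque:
        for line in blob.rstrip("\n").split("\n"):
            out.append(f"  {line}")
    out.append("</tool>")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# parsing

_KNOWN_TOOL_CHILDREN = ("description", "executable", "category", "parameters")
_BOOL_ATTR = {"true": True, "false": False}


def _parse_bool_attr(elem, attr: str, path: str) -> bool:
    raw = elem.get(attr, "false")
    if raw not in _BOOL_ATTR:
        raise CTDParseError(
            f"parameter {path!r}: attribute {attr!r} must be "
            f"'true' or 'false', got {raw!r}"
        )
    return _BOOL_ATTR[raw]


def _parse_item(elem, prefix: str, strict: bool) -> Parameter:
    name = elem.get("name")
    if not name:
        raise CTDParseError(f"<item> without name under {prefix or '<root>'!r}")
    path = f"{prefix}{name}"
    vtype = elem.get("type")
    if vtype not in VALUE_TYPES:
        raise CTDParseError(
            f"parameter {path!r}: unknown value type {vtype!r}"
        )
    base = vtype[:-5] if vtype.endswith("-list") else vtype
    restriction = None
    if elem.get("restrictions") is not None:
        restriction = Restriction.from_text(elem.get("restrictions"), base, path)
    default = None
    if vtype.endswith("-list"):
        items = [
            parse_value_text(base, child.text or "", path)
            for child in elem
            if child.tag == "value"
        ]
        if items or any(child.tag == "value" for child in elem):
            default = items
        if elem.get("value") is not None:
            raise CTDParseError(
                f"parameter {path!r}: list values use <value> children, "
                "not the value attribute"
            )
    elif elem.get("value") is not None:
        default = parse_value_text(base, elem.get("value"), path)
    formats = ()
    if elem.get("supported_formats") is not None:
        formats = tuple(
            f for f in elem.get("supported_formats").split(",") if f
        )
    known = {
        "name",
        "type",
        "value",
        "required",
        "advanced",
        "restrictions",
        "supported_formats",
        "description",
    }
    extra = {k: v for k, v in elem.attrib.items() if k not in known}
    if extra and strict:
        raise CTDParseError(
            f"parameter {path!r}: unknown attributes {sorted(extra)} "
            "(strict mode)"
        )
    try:
        return Parameter(
            name=name,
            value_type=vtype,
            default=default,
            required=_parse_bool_attr(elem, "required", path),
            advanced=_parse_bool_attr(elem, "advanced", path),
            description=elem.get("description", ""),
            restriction=restriction,
            file_formats=formats,
            extra_attrs=extra,
        )
    except (DescriptorError, BindingError) as exc:
        raise CTDParseError(f"parameter {path!r}: {exc}") from exc


def _parse_group_children(elem, prefix: str, strict: bool) -> list:
    children = []
    for child in elem:
        if child.tag is etree.Comment:
            continue
        if child.tag == "group":
            gname = child.get("name")
            if not gname:
                raise CTDParseError(
                    f"<group> without name under {prefix or '<root>'!r}"
                )
            sub = _parse_group_children(child, f"{prefix}{gname}.", strict)
            try:
                children.append(
                    ParameterGroup(
                        name=gname,
                        description=child.get("description", ""),
                        children=sub,
                    )
                )
            except DescriptorError as exc:
                raise CTDParseError(str(exc)) from exc
        elif child.tag == "item":
            children.append(_parse_item(child, prefix, strict))
        else:
            raise CTDParseError(
                f"unexpected element <{child.tag}> under "
                f"{prefix or '<parameters>'!r}"
            )
    return children


def parse_ctd(document: Union[str, bytes], strict: bool = False) -> ToolDescriptor:
    """Parse a CTD document into a :class:`ToolDescriptor`.

    Unknown attributes and unknown child elements of ``<tool>`` are kept as
    opaque annotations (echoed back by :func:`write_ctd`); with
    ``strict=True`` they raise :class:`CTDParseError` instead.
    """
    if isinstance(document, str):
        document = document.encode("utf-8")
    try:
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise CTDParseError(f"malformed XML: {exc}") from exc
    if root.tag != "tool":
        raise CTDParseError(f"root element must be <tool>, got <{root.tag}>")
    name = root.get("name")
    version = root.get("version")
    if not name or not version:
        raise CTDParseError("<tool> requires name and version attributes")
    extra_attrs = {
        k: v for k, v in root.attrib.items() if k not in ("name", "version")
    }
    if extra_attrs and strict:
        raise CTDParseError(
            f"unknown <tool> attributes {sorted(extra_attrs)} (strict mode)"
        )
    description = ""
    executable = ""
    category = None
    params = ParameterGroup(name="")
    opaque: list[str] = []
    seen_parameters = False
    for child in root:
        if child.tag is etree.Comment:
            continue
        if child.tag == "description":
            description = child.text or ""
        elif child.tag == "executable":
            executable = child.text or ""
        elif child.tag == "category":
            category = child.text or ""
        elif child.tag == "parameters":
            if seen_parameters:
                raise CTDParseError("multiple <parameters> elements")
            seen_parameters = True
            children = _parse_group_children(child, "", strict)
            try:
                params = ParameterGroup(name="", children=children)
            except DescriptorError as exc:
                raise CTDParseError(str(exc)) from exc
        else:
            if strict:
                raise CTDParseError(
                    f"unknown element <{child.tag}> under <tool> (strict mode)"
                )
            opaque.append(
                etree.tostring(child, encoding="unicode").strip()
            )
    if not seen_parameters:
        raise CTDParseError("missing <parameters> element")
    try:
        return ToolDescriptor(
            name=name,
            version=version,
            description=description,
            executable_name=executable,
            category=category,
            parameters=params,
            extra_attrs=extra_attrs,
            opaque=tuple(opaque),
        )
    except DescriptorError as exc:
        raise CTDParseError(str(exc)) from exc


# ---------------------------------------------------------------------------
# value binding operations


def validate_values(
    descriptor: ToolDescriptor, bindings: ValueBindings
) -> ValueBindings:
    """Check bindings against the descriptor and fill in defaults.

    Returns a new :class:`ValueBindings` in which every bound value has been
    type- and restriction-checked and every unbound parameter with a default
    has been materialised.  A required parameter that ends up without a
    value raises :class:`BindingError` naming its full dotted path.
    """
    known = dict(descriptor.flat_parameters())
    for path in bindings.values:
        if path not in known:
            raise BindingError(f"unknown parameter path {path!r}")
    result: dict = {}
    for path, param in known.items():
        if path in bindings:
            result[path] = check_value(param, bindings[path], path)
        elif param.default is not None:
            result[path] = param.default
        elif param.required:
            raise BindingError(
                f"required parameter {path!r} has no value and no default"
            )
    return ValueBindings(result)


def merge_overrides(
    descriptor: ToolDescriptor, base: ValueBindings, overrides: ValueBindings
) -> ValueBindings:
    """Per-path last-writer-wins merge: override values replace base values,
    unmentioned paths keep their base values; the merged result re-validates.
    """
    known = set(descriptor.paths())
    for path in overrides.values:
        if path not in known:
            raise BindingError(f"override on unknown parameter path {path!r}")
    merged = dict(base.values)
    merged.update(overrides.values)
    return validate_values(descriptor, ValueBindings(merged))


def extract_bindings(descriptor: ToolDescriptor) -> ValueBindings:
    """Read the values stored in a (value-)CTD as bindings: every parameter
    whose ``value`` is filled in contributes one entry."""
    return ValueBindings(
        {
            path: param.default
            for path, param in descriptor.flat_parameters()
            if param.default is not None
        }
    )


def apply_bindings(
    descriptor: ToolDescriptor, bindings: ValueBindings
) -> ToolDescriptor:
    """Produce a value-CTD: a copy of the descriptor with bound values
    written into the parameter defaults."""
    validated = validate_values(descriptor, bindings)

    def rebuild(group: ParameterGroup, prefix: str) -> ParameterGroup:
        children = []
        for child in group.children:
            path = f"{prefix}{child.name}"
            if isinstance(child, ParameterGroup):
                children.append(rebuild(child, path + "."))
            else:
                children.append(
                    Parameter(
                        name=child.name,
                        value_type=child.value_type,
                        default=validated.values.get(path, child.default),
                        required=child.required,
                        advanced=child.advanced,
                        description=child.description,
                        restriction=child.restriction,
                        file_formats=child.file_formats,
                        extra_attrs=dict(child.extra_attrs),
                    )
                )
        return ParameterGroup(
            name=group.name, description=group.description, children=children
        )

    return ToolDescriptor(
        name=descriptor.name,
        version=descriptor.version,
        description=descriptor.description,
        executable_name=descriptor.executable_name,
        category=descriptor.category,
        parameters=rebuild(descriptor.parameters, ""),
        extra_attrs=dict(descriptor.extra_attrs),
        opaque=descriptor.opaque,
    )
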