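"""Descriptor model, canonical serialization and value validation."""

import pytest
from hypothesis import given, settings, strategies as st

from ctdflow import (
    BindingError,
    CTDParseError,
    DescriptorError,
    Parameter,
    ParameterGroup,
    Restriction,
    ToolDescriptor,
    ValueBindings,
    merge_overrides,
    parse_ctd,
    validate_values,
    write_ctd,
)
from ctdflow import fixtures as fx

MINIMAL = """
<tool name="t" version="1.0.0">
  <executable>t</executable>
  <parameters/>
</tool>
"""


def _int_param(name="x", lo=1, hi=10, **kw):
    return Parameter(
        name=name,
        value_type="int",
        restriction=Restriction("numeric_range", min_value=lo, max_value=hi),
        **kw,
    )


class TestParse:
    def test_minimal_document_has_no_parameters(self):
        descriptor = parse_ctd(MINIMAL)
        assert descriptor.name == "t"
        assert descriptor.version == "1.0.0"
        assert descriptor.flat_parameters() == []

    def test_three_parameter_structure_tool(self, pdbcutter):
        """One PDB input and two outputs: the flattened list has length 3."""
        reparsed = parse_ctd(write_ctd(pdbcutter))
        flat = reparsed.flat_parameters()
        assert len(flat) == 3
        types = [p.value_type for _path, p in flat]
        assert types.count("input-file") == 1
        assert types.count("output-file") == 2

    @pytest.mark.parametrize(
        "document, fragment",
        [
            ("<tool name='t'", "malformed"),
            ("<notatool/>", "root element"),
            ("<tool name='t' version='1'><parameters/></tool>"
             .replace("<parameters/>",
                      "<parameters><item name='a' type='int'/>"
                      "<item name='a' type='int'/></parameters>"),
             "duplicate"),
            ("<tool name='t' version='1'><parameters>"
             "<item name='a' type='quux'/></parameters></tool>",
             "unknown value type"),
            ("<tool name='t' version='1'><parameters>"
             "<item name='a' type='int' restrictions='9:3'/>"
             "</parameters></tool>",
             "'a'"),
        ],
    )
    def test_errors_name_the_offence(self, document, fragment):
        with pytest.raises(CTDParseError, match=fragment):
            parse_ctd(document)

    def test_unknown_content_preserved_not_corrupted(self):
        doc = MINIMAL.replace("</tool>", "<custom x='1'/></tool>")
        descriptor = parse_ctd(doc)
        assert any("custom" in blob for blob in descriptor.opaque)
        assert "custom" in write_ctd(descriptor)
        with pytest.raises(CTDParseError, match="strict"):
            parse_ctd(doc, strict=True)

    def test_restriction_must_satisfy_its_own_invariants(self):
        with pytest.raises(DescriptorError):
            Restriction("numeric_range")
        with pytest.raises(DescriptorError):
            Restriction("choice_list", choices=("a", "a"))


class TestWrite:
    def test_writing_twice_is_byte_identical(self):
        descriptor = fx.gen_tool_descriptor(7)
        assert write_ctd(descriptor) == write_ctd(descriptor)

    def test_range_restriction_serialized_in_documented_syntax(self):
        descriptor = ToolDescriptor(
            name="t", version="1",
            parameters=ParameterGroup(name="", children=[_int_param()]),
        )
        assert 'restrictions="1:10"' in write_ctd(descriptor)

    def test_list_values_use_value_children_never_commas(self):
        descriptor = ToolDescriptor(
            name="t", version="1",
            parameters=ParameterGroup(
                name="",
                children=[
                    Parameter(name="s", value_type="string-list",
                              default=["a,b", "c"]),
                ],
            ),
        )
        text = write_ctd(descriptor)
        assert "<value>a,b</value>" in text
        assert parse_ctd(text).find("s").default == ["a,b", "c"]

    @pytest.mark.parametrize("seed", range(200))
    def test_corpus_round_trip(self, seed):
        """parse(write(d)) is structurally equal to d, and re-writing is
        byte-identical, for 200 seeded descriptors."""
        descriptor = fx.gen_tool_descriptor(seed)
        text = write_ctd(descriptor)
        reparsed = parse_ctd(text)
        assert reparsed == descriptor
        assert write_ctd(reparsed) == text


class TestValidateValues:
    def test_defaults_materialized(self):
        descriptor = ToolDescriptor(
            name="t", version="1",
            parameters=ParameterGroup(
                name="",
                children=[_int_param(default=3, required=True)],
            ),
        )
        validated = validate_values(descriptor, ValueBindings({}))
        assert validated.values == {"x": 3}

    def test_range_check_matches_exhaustive_predicate(self):
        """For an inclusive [1, 10] range, acceptance over 0..12 equals the
        brute-force evaluation of the predicate."""
        descriptor = ToolDescriptor(
            name="t", version="1",
            parameters=ParameterGroup(name="", children=[_int_param()]),
        )
        for candidate in range(0, 13):
            expected = 1 <= candidate <= 10
            if expected:
                validated = validate_values(
                    descriptor, ValueBindings({"x": candidate})
                )
                assert validated.values["x"] == candidate
            else:
                with pytest.raises(BindingError, match="'x'"):
                    validate_values(descriptor, ValueBindings({"x": candidate}))

    def test_missing_required_names_full_dotted_path(self):
        descriptor = ToolDescriptor(
            name="t", version="1",
            parameters=ParameterGroup(
                name="",
                children=[
                    ParameterGroup(
                        name="io",
                        children=[
                            Parameter(name="in", value_type="input-file",
                                      required=True),
                        ],
                    )
                ],
            ),
        )
        with pytest.raises(BindingError, match="io.in"):
            validate_values(descriptor, ValueBindings({}))

    def test_type_mismatch_rejected(self):
        descriptor = ToolDescriptor(
            name="t", version="1",
            parameters=ParameterGroup(name="", children=[_int_param()]),
        )
        with pytest.raises(BindingError):
            validate_values(descriptor, ValueBindings({"x": "three"}))

    @pytest.mark.parametrize("seed", range(50))
    def test_validation_soundness_per_parameter(self, seed):
        """validate_values never accepts a value that the parameter's own
        restriction predicate rejects in isolation."""
        descriptor = fx.gen_tool_descriptor(seed)
        bindings = fx.gen_bindings(seed + 1, descriptor)
        validated = validate_values(descriptor, bindings)
        for path, param in descriptor.flat_parameters():
            if path not in validated.values or param.restriction is None:
                continue
            value = validated.values[path]
            items = value if param.is_list else [value]
            assert all(param.restriction.admits(v) for v in items)


class TestMergeOverrides:
    def _descriptor(self):
        return ToolDescriptor(
            name="t", version="1",
            parameters=ParameterGroup(
                name="",
                children=[_int_param("x"), _int_param("y")],
            ),
        )

    def test_empty_overrides_is_identity(self):
        descriptor = self._descriptor()
        base = ValueBindings({"x": 1, "y": 2})
        merged = merge_overrides(descriptor, base, ValueBindings({}))
        assert merged.values == base.values

    def test_override_wins_per_path(self):
        descriptor = self._descriptor()
        merged = merge_overrides(
            descriptor, ValueBindings({"x": 1}), ValueBindings({"x": 2})
        )
        assert merged.values["x"] == 2

    def test_unknown_override_path_rejected(self):
        with pytest.raises(BindingError, match="zz"):
            merge_overrides(
                self._descriptor(), ValueBindings({}), ValueBindings({"zz": 1})
            )

    @settings(derandomize=True, max_examples=100)
    @given(
        base=st.dictionaries(st.sampled_from(["x", "y"]),
                             st.integers(1, 10)),
        overrides=st.dictionaries(st.sampled_from(["x", "y"]),
                                  st.integers(1, 10)),
    )
    def test_matches_naive_last_writer_wins(self, base, overrides):
        descriptor = self._descriptor()
        merged = merge_overrides(
            descriptor, ValueBindings(dict(base)), ValueBindings(dict(overrides))
        )
        expected = {**base, **overrides}
        for path, value in expected.items():
            assert merged.values[path] == value
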