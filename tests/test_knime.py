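"""Source-workflow parsing and sweep collapse."""

import random

import pytest

from ctdflow import (
    ConversionRejected,
    SourceParseError,
    check_soundness,
    collapse_sweeps,
    map_io_nodes,
    parse_source,
    to_petri_net,
    write_workflow_xml,
)
from ctdflow import fixtures as fx
from ctdflow.knime import Connection, SourceNode, SourceWorkflow

from oracles import transitive_closure


def _corpus_case(seed):
    rng = random.Random(seed)
    n_tools = rng.randint(1, 8)
    loop_pairs = rng.randint(0, min(2, n_tools))
    return fx.gen_source_workflow(seed, n_tools, loop_pairs)


class TestParseSource:
    def test_lfq_layout_round_trips_through_directory(self, tmp_path, lfq_source):
        source, _truth = lfq_source
        directory = fx.write_source_dir(source, tmp_path / "wf")
        parsed = parse_source(directory)
        assert parsed == source
        starts = [n for n in parsed.nodes if n.kind == "loop_start"]
        ends = [n for n in parsed.nodes if n.kind == "loop_end"]
        assert len(starts) == 1 and len(ends) == 1
        assert ends[0].loop_start_id == starts[0].id

    def test_single_tool_node_no_connections(self, tmp_path):
        source, _ = fx.gen_source_workflow(0, 1, 0)
        single = SourceWorkflow(
            nodes=[n for n in source.nodes if n.id == "t1"], connections=[]
        )
        directory = fx.write_source_dir(single, tmp_path / "one")
        parsed = parse_source(directory)
        assert len(parsed.nodes) == 1
        assert parsed.connections == []

    def test_missing_settings_reported(self, tmp_path):
        source, _ = fx.gen_source_workflow(1, 2, 0)
        directory = fx.write_source_dir(source, tmp_path / "wf")
        (directory / "t1" / "settings.xml").unlink()
        with pytest.raises(SourceParseError, match="t1"):
            parse_source(directory)

    def test_unsupported_node_kind_named(self, tmp_path):
        source, _ = fx.gen_source_workflow(1, 1, 0)
        directory = fx.write_source_dir(source, tmp_path / "wf")
        text = (directory / "workflow.xml").read_text()
        (directory / "workflow.xml").write_text(
            text.replace('kind="output"', 'kind="metanode"')
        )
        with pytest.raises(SourceParseError, match="metanode"):
            parse_source(directory)

    @pytest.mark.parametrize("seed", range(60))
    def test_parse_is_lossless_against_generator(self, seed, tmp_path):
        source, _truth = _corpus_case(seed)
        directory = fx.write_source_dir(source, tmp_path / "wf")
        assert parse_source(directory) == source


class TestCollapseSweeps:
    def test_lfq_fixture_loses_loops_gains_sweep_ports(self, lfq_source):
        source, truth = lfq_source
        graph, report = collapse_sweeps(source)
        assert len(graph.tasks) == truth["n_tools"]
        assert {t.id for t in graph.tasks if t.sweep_member} == truth[
            "sweep_members"
        ]
        roles = {
            (t.id, p.name): p.sweep_role
            for t in graph.tasks
            for p in t.ports
            if p.sweep_role != "none"
        }
        assert roles == {
            next(iter(truth["generator_ports"])): "generator",
            next(iter(truth["collector_ports"])): "collector",
        }
        assert report.status == "converted"

    def test_no_loops_is_identity_on_topology(self):
        source, truth = fx.gen_source_workflow(3, 5, 0)
        graph, _report = collapse_sweeps(source)
        assert len(graph.tasks) == 5
        assert not any(t.sweep_member for t in graph.tasks)
        assert all(
            p.sweep_role == "none" for t in graph.tasks for p in t.ports
        )

    def test_unbalanced_pair_rejected(self):
        source, _ = fx.gen_source_workflow(2, 3, 1)
        source.nodes = [n for n in source.nodes if n.kind != "loop_end"]
        source.connections = [
            c for c in source.connections
            if "zle" not in (c.source, c.target)
        ]
        with pytest.raises(ConversionRejected) as info:
            collapse_sweeps(source)
        assert "unbalanced-loop" in info.value.report.rejections

    def test_nested_pairs_rejected(self):
        nodes = [
            SourceNode(id="zlsA", kind="loop_start"),
            SourceNode(id="zlsB", kind="loop_start"),
        ]
        source, _ = fx.gen_source_workflow(4, 1, 0)
        tool = source.node("t1")
        nodes.append(tool)
        nodes.append(SourceNode(id="zleB", kind="loop_end", loop_start_id="zlsB"))
        nodes.append(SourceNode(id="zleA", kind="loop_end", loop_start_id="zlsA"))
        conns = [
            Connection("zlsA", "out", "zlsB", "in"),
            Connection("zlsB", "out", "t1", "in"),
            Connection("t1", "out", "zleB", "in"),
            Connection("zleB", "out", "zleA", "in"),
        ]
        with pytest.raises(ConversionRejected) as info:
            collapse_sweeps(SourceWorkflow(nodes=nodes, connections=conns))
        assert "nested-loops" in info.value.report.rejections

    def test_flow_variable_connection_rejected(self):
        source, _ = fx.gen_source_workflow(5, 2, 0)
        source.connections.append(
            Connection("t1", "out", "t2", "in", kind="flow_variable")
        )
        with pytest.raises(ConversionRejected) as info:
            collapse_sweeps(source)
        assert "flow-variable" in info.value.report.rejections

    @pytest.mark.parametrize("seed", range(80))
    def test_ground_truth_recovered_exactly(self, seed):
        """Vertex count drops by two per pair and sweep membership and port
        roles match the generator's ground truth."""
        source, truth = _corpus_case(seed)
        n_source_nodes = len(source.nodes)
        graph, _report = collapse_sweeps(source)
        n_io = sum(1 for n in source.nodes if n.kind in ("input_files", "output"))
        assert len(graph.tasks) == n_source_nodes - n_io - truth["loop_nodes"]
        assert {t.id for t in graph.tasks if t.sweep_member} == truth[
            "sweep_members"
        ]
        gens = {
            (t.id, p.name)
            for t in graph.tasks for p in t.ports
            if p.sweep_role == "generator"
        }
        colls = {
            (t.id, p.name)
            for t in graph.tasks for p in t.ports
            if p.sweep_role == "collector"
        }
        assert gens == truth["generator_ports"]
        assert colls == truth["collector_ports"]

    @pytest.mark.parametrize("seed", range(40))
    def test_reachability_preserved_between_surviving_tools(self, seed):
        """Path existence between any two tool nodes is identical before
        and after collapse (brute-force transitive closure)."""
        source, _truth = _corpus_case(seed)
        tools = {n.id for n in source.nodes if n.kind == "tool"}
        before_edges = {(c.source, c.target) for c in source.connections}
        nodes = {n.id for n in source.nodes}
        closure_before = transitive_closure(nodes, before_edges)
        graph, _report = collapse_sweeps(source)
        after_edges = {(c.source[0], c.target[0]) for c in graph.channels}
        closure_after = transitive_closure(tools, after_edges)
        for a in tools:
            for b in tools:
                assert ((a, b) in closure_before) == ((a, b) in closure_after)

    @pytest.mark.parametrize("seed", range(40))
    def test_result_validates_and_is_sound(self, seed):
        source, _truth = _corpus_case(seed)
        graph, _report = collapse_sweeps(source)
        assert check_soundness(to_petri_net(graph)).sound

    def test_conversion_is_deterministic(self, tmp_path):
        source, _truth = fx.lfq_source_workflow()
        directory = fx.write_source_dir(source, tmp_path / "wf")
        first = write_workflow_xml(collapse_sweeps(parse_source(directory))[0])
        second = write_workflow_xml(collapse_sweeps(parse_source(directory))[0])
        assert first == second


class TestMapIoNodes:
    def test_one_input_files_node_feeding_the_loop(self, lfq_source):
        source, truth = lfq_source
        inputs, outputs, dropped = map_io_nodes(source)
        assert inputs == truth["workflow_inputs"]
        assert outputs == truth["workflow_outputs"]
        assert dropped == []

    def test_no_io_nodes(self):
        source, _ = fx.gen_source_workflow(0, 2, 0)
        source.nodes = [n for n in source.nodes if n.kind == "tool"]
        source.connections = [
            c for c in source.connections
            if c.source.startswith("t") and c.target.startswith("t")
        ]
        inputs, outputs, dropped = map_io_nodes(source)
        assert inputs == [] and outputs == []

    def test_disconnected_input_files_node_dropped_with_warning(self):
        source, _ = fx.gen_source_workflow(0, 2, 0)
        source.nodes.append(
            SourceNode(id="lonely", kind="input_files", files=("a.mzML",))
        )
        _inputs, _outputs, dropped = map_io_nodes(source)
        assert any(item[0] == "lonely" for item in dropped)

    @pytest.mark.parametrize("seed", range(40))
    def test_counts_match_generator_ground_truth(self, seed):
        source, truth = _corpus_case(seed)
        inputs, outputs, _dropped = map_io_nodes(source)
        assert inputs == truth["workflow_inputs"]
        assert outputs == truth["workflow_outputs"]
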