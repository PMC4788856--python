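"""Workflow graphs, the Petri-net translation and soundness checking."""

import pytest

from ctdflow import (
    DataChannel,
    GraphError,
    PetriNetError,
    Port,
    Task,
    WorkflowGraph,
    abstract_view,
    check_soundness,
    fire,
    parse_workflow_xml,
    to_petri_net,
    validate_graph,
    write_workflow_xml,
)
from ctdflow import fixtures as fx
from ctdflow.workflow import PetriNet

from oracles import brute_force_sound, order_respects_channels


class TestValidateGraph:
    def test_protonation_chain_order(self):
        graph = fx.protonation_workflow()
        assert validate_graph(graph) == [
            "Input", "Split", "Protonate", "Output",
        ]
        assert len(graph.tasks) == 4
        assert len(graph.channels) == 3

    def test_empty_graph(self):
        assert validate_graph(WorkflowGraph()) == []

    def test_cycle_reported_with_ids(self):
        graph = WorkflowGraph(
            tasks=[
                Task(id="a", ports=[Port("in", "in"), Port("out", "out")]),
                Task(id="b", ports=[Port("in", "in"), Port("out", "out")]),
            ],
            channels=[
                DataChannel(("a", "out"), ("b", "in")),
                DataChannel(("b", "out"), ("a", "in")),
            ],
        )
        with pytest.raises(GraphError, match="cycle"):
            validate_graph(graph)

    def test_dangling_endpoint_and_direction_mismatch(self):
        graph = WorkflowGraph(
            tasks=[Task(id="a", ports=[Port("out", "out")])],
            channels=[DataChannel(("a", "out"), ("ghost", "in"))],
        )
        with pytest.raises(GraphError, match="ghost"):
            validate_graph(graph)
        graph = WorkflowGraph(
            tasks=[
                Task(id="a", ports=[Port("out", "out")]),
                Task(id="b", ports=[Port("also_out", "out")]),
            ],
            channels=[DataChannel(("a", "out"), ("b", "also_out"))],
        )
        with pytest.raises(GraphError, match="direction"):
            validate_graph(graph)

    @pytest.mark.parametrize("seed", range(100))
    def test_random_dags_order_respects_every_edge(self, seed):
        graph = fx.gen_workflow_graph(seed, n_tasks=seed % 8 + 1)
        order = validate_graph(graph)
        assert order_respects_channels(order, graph)
        assert sorted(order) == sorted(t.id for t in graph.tasks)


class TestAbstractView:
    def test_concrete_annotations_stripped_topology_kept(self):
        concrete = fx.protonation_workflow(concrete=True)
        abstract = abstract_view(concrete)
        assert [t.id for t in abstract.tasks] == [t.id for t in concrete.tasks]
        assert abstract.channels == concrete.channels
        assert all(t.descriptor is None and t.bindings is None
                   and t.resource_hint is None for t in abstract.tasks)
        # shape matches the hand-built abstract chain
        plain = fx.protonation_workflow(concrete=False)
        assert write_workflow_xml(abstract) == write_workflow_xml(plain)

    def test_idempotent_on_already_abstract_graphs(self):
        graph = fx.protonation_workflow(concrete=False)
        assert write_workflow_xml(abstract_view(graph)) == write_workflow_xml(graph)

    @pytest.mark.parametrize("seed", range(50))
    def test_idempotence_and_size_preservation(self, seed):
        graph = fx.gen_workflow_graph(seed)
        once = abstract_view(graph)
        assert write_workflow_xml(abstract_view(once)) == write_workflow_xml(once)
        assert len(once.tasks) == len(graph.tasks)
        assert len(once.channels) == len(graph.channels)


class TestToPetriNet:
    def test_protonation_chain_net_shape(self):
        net = to_petri_net(fx.protonation_workflow())
        assert len(net.places) == 5
        assert len(net.transitions) == 4
        assert net.tokens("P0") == 1
        assert net.sink_places() == ["P4"]

    def test_empty_workflow(self):
        net = to_petri_net(WorkflowGraph())
        assert net.places == () and net.transitions == ()

    def test_bipartite_invariant_enforced(self):
        with pytest.raises(PetriNetError, match="same kind"):
            PetriNet(places=("P0", "P1"), transitions=("t",),
                     arcs=(("P0", "P1"),), marking=())

    @pytest.mark.parametrize("seed", range(100))
    def test_counting_oracle(self, seed):
        graph = fx.gen_workflow_graph(seed)
        net = to_petri_net(graph)
        assert len(net.places) == (
            len(graph.channels)
            + len(graph.workflow_inputs)
            + len(graph.workflow_outputs)
        )
        assert len(net.transitions) == len(graph.tasks)


class TestFire:
    def test_first_transition_moves_the_start_token(self):
        net = to_petri_net(fx.protonation_workflow())
        after = fire(net, "Input")
        assert after.tokens("P0") == 0
        assert after.tokens("P1") == 1

    def test_disabled_transition_refuses_to_fire(self):
        net = to_petri_net(fx.protonation_workflow())
        with pytest.raises(PetriNetError, match="not enabled"):
            fire(net, "Protonate")

    @pytest.mark.parametrize("seed", range(50))
    def test_token_conservation(self, seed):
        """Token-count change of any firing equals the transition's
        out-degree minus in-degree; counts never go negative."""
        net = to_petri_net(fx.gen_workflow_graph(seed))
        for transition in net.transitions:
            if not net.enabled(transition):
                continue
            after = fire(net, transition)
            delta = sum(n for _p, n in after.marking) - sum(
                n for _p, n in net.marking
            )
            assert delta == (
                len(net.output_places(transition))
                - len(net.input_places(transition))
            )
            assert all(n >= 0 for _p, n in after.marking)


class TestSoundness:
    def test_protonation_chain_is_sound_with_chain_witness(self):
        result = check_soundness(to_petri_net(fx.protonation_workflow()))
        assert result.sound
        assert result.witness == ("Input", "Split", "Protonate", "Output")

    def test_unconnected_required_input_makes_net_unsound(self):
        graph = fx.protonation_workflow()
        graph.task("Protonate").ports.append(
            Port(name="missing", direction="in", required=True)
        )
        result = check_soundness(to_petri_net(graph))
        assert not result.sound
        assert result.stuck_marking is not None

    def test_unconnected_optional_input_is_ignored(self):
        graph = fx.protonation_workflow()
        graph.task("Protonate").ports.append(
            Port(name="maybe", direction="in", required=False)
        )
        assert check_soundness(to_petri_net(graph)).sound

    @pytest.mark.parametrize("seed", range(250))
    def test_verdict_equals_marking_graph_enumeration(self, seed):
        """On small nets (<=12 places) the soundness verdict matches a
        breadth-first enumeration of the full marking graph."""
        graph = fx.gen_workflow_graph(seed, p_dangling=0.25)
        net = to_petri_net(graph)
        if len(net.places) > 12:
            return
        assert check_soundness(net).sound == brute_force_sound(net)

    @pytest.mark.parametrize("seed", range(500))
    def test_fully_connected_dag_nets_are_sound(self, seed):
        """Nets translated from valid graphs whose required ports are all
        connected are always sound."""
        graph = fx.gen_workflow_graph(seed, n_tasks=seed % 7 + 1)
        assert check_soundness(to_petri_net(graph)).sound


class TestSerialization:
    @pytest.mark.parametrize("concrete", [False, True])
    def test_workflow_xml_round_trip(self, concrete):
        graph = fx.protonation_workflow(concrete=concrete)
        text = write_workflow_xml(graph)
        back = parse_workflow_xml(text)
        assert write_workflow_xml(back) == text

    def test_petri_edge_list_mentions_every_arc(self):
        from ctdflow.workflow import petri_edge_list

        net = to_petri_net(fx.protonation_workflow())
        text = petri_edge_list(net)
        for src, dst in net.arcs:
            assert f"{src} -> {dst}" in text
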