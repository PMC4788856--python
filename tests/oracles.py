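"""Independent oracles used by the property suites.

Each function recomputes an expected result by the most naive means
available (exhaustive enumeration, breadth-first search, flat tree walks)
and stays deliberately independent of the implementation paths it checks.
"""

from collections import deque

from lxml import etree

from ctdflow.ctd import ToolDescriptor, ValueBindings, format_value, validate_values
from ctdflow.galaxy import TEMPLATE_CONTROL_TOKENS, UNSUPPORTED_TAGS
from ctdflow.workflow import PetriNet, WorkflowGraph
from ctdflow.wrapper import flag_for


def naive_argv(descriptor: ToolDescriptor, bindings: ValueBindings) -> tuple:
    """Flat re-derivation of the command line: walk the flattened parameter
    list in order and concatenate flags and formatted values."""
    validated = validate_values(descriptor, bindings)
    argv = [descriptor.executable_name]
    for path, param in descriptor.flat_parameters():
        if path not in validated.values:
            continue
        value = validated.values[path]
        if param.base_type == "bool" and not param.is_list:
            if value:
                argv.append(flag_for(descriptor, path))
            continue
        items = value if param.is_list else [value]
        if not items:
            continue
        argv.append(flag_for(descriptor, path))
        argv.extend(format_value(param.base_type, v) for v in items)
    return tuple(argv)


def scan_unsupported(document: str) -> set:
    """Brute-force scan of a ToolConfig element tree for constructs on the
    documented unsupported list."""
    root = etree.fromstring(document.encode("utf-8"))
    tags = set()
    for elem in root.iter():
        if elem.tag in UNSUPPORTED_TAGS:
            tags.add(elem.tag)
        elif elem.tag == "command":
            if any(tok in (elem.text or "") for tok in TEMPLATE_CONTROL_TOKENS):
                tags.add("template-control-flow")
        elif elem.tag == "configfile":
            if any(tok in (elem.text or "") for tok in TEMPLATE_CONTROL_TOKENS):
                tags.add("configfile-logic")
    return tags


def order_respects_channels(order: list, graph: WorkflowGraph) -> bool:
    """Exhaustive pairwise precedence verification of a topological order."""
    position = {tid: i for i, tid in enumerate(order)}
    return all(
        position[ch.source[0]] < position[ch.target[0]] for ch in graph.channels
    )


def brute_force_sound(net: PetriNet) -> bool:
    """Breadth-first exploration of the full marking graph: is there a path
    firing every transition exactly once that ends with tokens only in sink
    places?"""
    sinks = set(net.sink_places())
    in_places = {t: net.input_places(t) for t in net.transitions}
    out_places = {t: net.output_places(t) for t in net.transitions}
    start = (net.marking, frozenset())
    seen = {start}
    queue = deque([start])
    while queue:
        marking, fired = queue.popleft()
        m = dict(marking)
        if len(fired) == len(net.transitions):
            if all(p in sinks for p, n in m.items() if n > 0):
                return True
            continue
        for t in net.transitions:
            if t in fired:
                continue
            if all(m.get(p, 0) >= 1 for p in in_places[t]):
                nxt = dict(m)
                for p in in_places[t]:
                    nxt[p] -= 1
                for p in out_places[t]:
                    nxt[p] = nxt.get(p, 0) + 1
                state = (
                    tuple(sorted((k, v) for k, v in nxt.items() if v)),
                    fired | {t},
                )
                if state not in seen:
                    seen.add(state)
                    queue.append(state)
    return False


def transitive_closure(nodes: set, edges: set) -> set:
    """All (a, b) pairs with a path from a to b, by naive iteration."""
    reach = set(edges)
    changed = True
    while changed:
        changed = False
        for a, b in list(reach):
            for c, d in list(reach):
                if b == c and (a, d) not in reach:
                    reach.add((a, d))
                    changed = True
    return reach
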