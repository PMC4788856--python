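# ctdflow

A workflow-interoperability toolkit for bioinformatics command-line tools.
It is aimed at people who build analysis pipelines in one workflow system
(a desktop editor such as the KNIME Analytics Platform, or Galaxy) and need
to run them on another (a grid/HPC portal in the gUSE/WS-PGRADE style),
without rewriting every node by hand.

The toolkit is organised around three ideas:

1. **Common Tool Descriptors (CTD).** A CTD is a small XML document that
   describes one command-line tool: its identity, executable, and a typed
   parameter tree (ints, floats, strings, booleans, input/output files,
   list variants; ranges and choice lists as restrictions). Because the
   description is platform-neutral, the same tool can be imported into any
   engine, and a value-filled CTD is enough to execute the tool
   (`ctdflow.wrapper` builds the exact argv vector and runs it).
2. **A two-layer workflow graph.** Workflows are directed acyclic graphs
   of tasks joined by data channels. The *abstract* layer carries only the
   application domain (tasks, labels, ports, topology); the *concrete*
   layer adds per-task tool descriptors, parameter values and resource
   hints. Portal-style engines configure these two layers separately, so
   the converter keeps them separable (`abstract_view`).
3. **Petri-net soundness as the formal backbone.** Every graph translates
   into a Petri net: tasks become transitions, data channels become
   places, each workflow input is a source place holding one token, and
   each workflow output a sink place. A transition fires by consuming one
   token per input place and producing one per output place. A workflow is
   *sound* when some firing sequence fires every transition exactly once
   and leaves tokens only in sink places — exactly the statement that every
   task can run once its inputs are resolvable and the pipeline terminates
   cleanly. Dangling required inputs make the net unsound, which is how
   under-specified workflows are caught before submission.

On top of that core the package converts in three directions:

* **CTD → Galaxy ToolConfig** (`ctd_to_galaxy`): always succeeds; emits a
  ToolConfig with a control-flow-free command template.
* **Galaxy ToolConfig → CTD** (`galaxy_to_ctd`): succeeds on the
  convertible subset; documents with `conditional` blocks, `repeat`
  blocks, template `#if`/`#for` logic or logic-bearing configfiles are
  rejected with a report naming every offending construct.
* **KNIME-style workflow → gUSE-style bundle** (`parse_source` →
  `collapse_sweeps` → `write_bundle`): ZipLoopStart/ZipLoopEnd pairs —
  "run this section once per input file" — are removed and replaced by
  port-level sweep annotations (a *generator* in-port where the items
  enter, a *collector* out-port where results are gathered), which is how
  parameter sweeps are expressed in the target model.

Every conversion returns a machine-readable `ConversionReport` (mapped /
dropped / rejected), so nothing is ever silently discarded.

## Worked example

The protonation pipeline — fetch a molecule, split out the structure of
interest, add missing hydrogens, store the result — is a four-task chain:

```python
from ctdflow import fixtures as fx
from ctdflow import validate_graph, to_petri_net, check_soundness

g = fx.protonation_workflow()
print("topological order:", validate_graph(g))
net = to_petri_net(g)
print("places:", net.places)
print("initial marking:", dict(net.marking))
v = check_soundness(net)
print("sound:", v.sound, "witness:", v.witness)
```

prints

```text
topological order: ['Input', 'Split', 'Protonate', 'Output']
places: ('P0', 'P1', 'P2', 'P3', 'P4')
initial marking: {'P0': 1}
sound: True witness: ('Input', 'Split', 'Protonate', 'Output')
```

Four tasks and three channels give a net with five places: `P0` is the
start place holding the single initial token, `P1`–`P3` are the three data
channels, and `P4` marks the end of the process. The soundness witness is
the firing sequence that moves the token through the chain.

Converting a label-free-quantification (LFQ) proteomics pipeline, where a
loop pair encloses the per-run identification/quantification chain:

```python
from ctdflow import collapse_sweeps, write_bundle

src, truth = fx.lfq_source_workflow()
graph, report = collapse_sweeps(src)
print("converted tasks:", len(graph.tasks))
print("sweep members:", sorted(t.id for t in graph.tasks if t.sweep_member))
```

```text
converted tasks: 9
sweep members: ['FalseDiscoveryRate', 'FeatureFinderCentroided',
 'FileConverter', 'IDMapper', 'OMSSAAdapter', 'PeakPickerHiRes']
```

The two loop nodes are gone; the six per-run tools are sweep-marked; the
first in-port of the enclosed chain carries `sweep="generator"` and the
last out-port `sweep="collector"` in the emitted bundle
(`write_bundle(graph)`), while linking, normalisation and CSV export stay
outside the sweep.

## Command line

```console
$ ctdflow validate tool.ctd
$ ctdflow run tool.ctd --dry-run
$ ctdflow ctd2galaxy tool.ctd tool.xml
$ ctdflow galaxy2ctd tool.xml tool.ctd --report report.txt
$ ctdflow knime2guse workflow_dir/ bundle.zip --report report.txt
$ ctdflow petri-check workflow.xml
$ ctdflow fixtures descriptor --seed 4 --out tool.ctd
```

Exit codes: 0 on success, 1 on a validation failure or conversion
rejection (the report is still written), 2 on usage errors.

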