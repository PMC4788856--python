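# Methods

This note records the models, dialects and design choices behind ctdflow,
and what the synthetic test corpora do and do not demonstrate.

## The CTD dialect

No single canonical schema exists across the historical CTD variants, so
the package defines one small, fully documented dialect (module docstring
of `ctdflow.ctd`): a `<tool name version>` root, `<description>`,
`<executable>`, optional `<category>`, and a `<parameters>` tree of
`<group>` and `<item>` nodes. Choices that matter:

* **Restrictions.** Numeric ranges are written `min:max` with inclusive
  bounds and open ends allowed (`3:`, `:7`); choice lists are
  comma-separated. The kind is determined by the parameter type (numeric →
  range, string → choices); boolean and file parameters admit no
  restrictions.
* **List values** are repeated `<value>` child elements, never
  comma-splitting, so commas inside string items are safe.
* **Canonical form.** 2-space indent, a fixed attribute order (`name,
  type, value, required, advanced, restrictions, supported_formats,
  description`), UTF-8, trailing newline. Serialization is therefore
  byte-stable, which is what makes the round-trip property (`parse ∘
  write = id`, `write ∘ parse ∘ write = write`) testable at the byte
  level.
* **Unknown content** (foreign attributes, foreign child elements of the
  root) is preserved verbatim in an opaque annotation slot and echoed on
  write; `strict=True` rejects it instead. Versions are opaque strings and
  never compared.

Value bindings are validated per parameter: type check, restriction check,
defaults filled for unbound parameters, and a required parameter without a
value is an error that names its full dotted path. `merge_overrides` is a
per-path last-writer-wins merge followed by re-validation.

## Command construction

The flag for a parameter is `-` plus its leaf name when that name is
unique in the descriptor, and `-full.dotted.path` otherwise; parameters
are emitted in document order. True booleans become bare flags, false ones
vanish; lists expand to one flag followed by all items. Commands are argv
vectors passed to the child process directly — no shell is ever involved,
which also makes the emitted command byte-reproducible. The
`--write-ctd <file>` convention lets any wrapped tool dump its own
descriptor, the handshake by which a tool becomes CTD-enabled.

## Galaxy conversion

CTD is the restricted format, so CTD → ToolConfig is total. The type map
is the smallest faithful one (int→integer, float→float, bool→boolean with
the flag in `truevalue`, string→text, string+choices→select,
input-file→data, output-file→output data); list variants carry
`multiple="true"` with comma-joined values. Parameter paths map to Galaxy
names with `.` replaced by `__`, so group nesting survives Galaxy's flat
namespace and is rebuilt on import. Runs of consecutive advanced
parameters are wrapped in collapsed `<section>` elements (one per run, so
document order is preserved exactly); on import, sectioning is flattened
back into the tree with the advanced flag set. The generated command
template uses plain `$name` placeholders and contains no control flow, so
every emitted document lies inside the convertible subset by construction.

On import, parameter order is recovered from the command template's
placeholder order (the template mentions every parameter once, in document
order); parameters absent from the command fall back to inputs-then-
outputs order. The importer extends the plain ToolConfig `<data>` output
element with `value`, `multiple` and `optional` attributes so that preset
output filenames, output lists and optional outputs survive the round
trip; a strict Galaxy consumer would ignore or reject these, which is an
accepted dialect deviation in the export direction.

Documented lossy fields of the round trip: the tool `category` and group
descriptions (Galaxy has no place for either). Everything else — names,
types, restrictions, defaults, required/advanced flags, file formats,
descriptions, ordering, nesting — is preserved, and the 200-seed
partial-inverse suite checks exact structural equality of the parameter
tree.

The unsupported-construct list is closed and documented: `conditional`,
`repeat`, template control flow (`#if`, `#for`, `#while`, `#unless`,
`#else`, `#end` in the command), and configfiles containing such logic.
Any other unknown element is skipped with a `dropped` entry in the report,
never silently. Rejection is a reported outcome, not an exception: the
converter returns `(None, report)`.

## Workflow graphs and the Petri-net translation

Graphs are validated structurally (unique ids, existing endpoints with
matching port directions, acyclicity); the returned topological order is
deterministic with lexicographic tie-breaks. Cycle detection and ordering
are delegated to networkx.

The Petri-net mapping is a convention chosen so the worked example
reproduces the classic picture: one transition per task, one place per
data channel, one source place (one initial token) per workflow input, one
sink place per workflow output. Places are numbered `P0..Pn` in
topological channel order — workflow inputs first, then channels sorted by
the topological position of their source task, then workflow outputs — so
the four-task chain yields `P0` as start and `P4` as end.

"An input can be resolved" is operationalised through port requiredness:
an unconnected *required* in-port generates an unmarked place that no
transition ever feeds (the net is then unsound and the stuck marking is
the witness); an unconnected *optional* in-port generates nothing. For an
acyclic graph whose required inputs are all connected the net is always
sound — asserted over 500 random graphs, and the checker's verdict is
cross-checked against an independent breadth-first enumeration of the full
marking graph on nets with ≤ 12 places. The checker itself explores the
marking graph directly (depth-first with memoisation on
(marking, fired-set)); nets from workflow DAGs are small, so no structural
shortcut is used that would couple the implementation to the oracle.

`fire` is pure (returns a new net) and enforces enabledness; token counts
can never go negative.

## Source-workflow dialect and sweep collapse

The real desktop platform's on-disk format is version-dependent and not
publicly specified, so the reader defines a minimal documented layout
(connectivity XML plus one settings document per node, tool nodes
embedding a value-CTD) and the fixtures module ships a generator for it.
Node kinds are `tool`, `input_files`, `output`, `loop_start`, `loop_end`;
anything else is rejected naming the node. Tool ports are the tool's
file-typed parameter paths, so connectivity is checked against the
embedded descriptors.

Loop collapse rewires connections around each loop pair and records the
sweep annotation on ports: generator on the in-port downstream of the
removed `loop_start`, collector on the out-port upstream of the
`loop_end`, `sweep_member` on every task strictly between them (computed
as reachable-from-start ∩ reaching-end). Nested pairs are rejected in this
version (single enclosing pairs cover the motivating pipelines), as are
flow-variable connections — both with explicit report tags rather than
best-effort guesses. Unconnected optional tool ports are omitted with a
`dropped` report entry; unconnected required ports are kept, which makes
the resulting net unsound and surfaces the defect.

## The gUSE-style bundle

The bundle is a versioned dialect, not a byte-exact clone of any portal
release: a ZIP archive with `abstract.xml` (the serialized abstract view)
and one `jobs/<id>.xml` per task carrying the exact argv, the ports
(sweep roles as a `sweep="generator|collector"` attribute — the property
keys are this dialect's own, chosen because the portal's internal keys are
not published), the embedded value-CTD and an opaque resource hint.
Entries are sorted and timestamps fixed to the ZIP epoch, so writing is
byte-stable from the first write. The reader restores the concrete layer
from the embedded value-CTDs and cross-checks the recorded argv against a
rebuild — a corrupted bundle fails loudly. One coarsening: bindings are
stored as values written into the CTD, so after a round trip a parameter's
default and its explicit binding are indistinguishable; rebuilt command
lines are unaffected (validation fills defaults either way), and the
round-trip suite checks them for equality.

## Synthetic corpora: what they emulate and what they don't

The generators are pure functions of their seed. Descriptor sampling
covers all twelve value types uniformly and both restriction kinds
(numeric range with probability 0.4 on numeric types, one open end with
probability 0.3; choice lists with probability 0.3 on strings), defaults
present with probability 0.75 and always restriction-satisfying, nesting
up to two groups. String values avoid commas so list values survive the
comma-joined Galaxy encoding — real tool descriptions with commas in list
defaults would need an escaped encoding that this version does not define.

Generated source workflows are linear tool chains with disjoint loop
sections, an input-files head and an output tail; ground truth (enclosed
nodes, sweep ports, boundary) is constructed alongside, never inferred, and
is the oracle for the collapse tests. Real workflows branch and merge;
branching topologies are exercised by the random-DAG generator in the
Petri-net suites, but the collapse tests' coverage of loops is restricted
to non-nested, chain-shaped sections — matching what the converter accepts.
Generated ToolConfig documents are assembled textually and independently of
the package's own emitter, so the Galaxy corpus tests parse genuinely
foreign input; they do not reproduce the full diversity of hand-written
Galaxy tools (macros, XML includes and Cheetah beyond the scanned tokens
are out of scope).

Passing these suites therefore shows the converters are exact on the
documented dialects and the declared convertible subset — not that every
historical CTD or toolshed document converts.

## Problem sizes

The property suites run at the sizes stated with them: 200 seeds for the
serialization round trips, the Galaxy partial inverse and the bundle round
trip; 100 + 100 ToolConfigs for rejection agreement; 500 nets (≤ 12
places) for the soundness cross-check; 500 graphs for the soundness
theorem. The whole suite completes in a few seconds on one CPU; the
acceptance script re-derives the same quantities in under a minute.
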