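# Methods

## The model

An experiment is modelled as a typed provenance DAG inside an
Investigation → Study hierarchy. Each study graph has exactly one root
node standing for the study; every other node is a biosource, a
container or an assay, and every arc must satisfy the typing table

    root → biosource        (inclusion of raw material; no protocol)
    biosource → container   (extraction)
    container → container   (processing / transfer)
    container → assay       (measurement)

Assays are sinks. Splitting is not a distinct operation: it is adding
several children to one container. Pooling creates one child with one
incoming arc per source; each of those arcs can carry its own protocol
application. Containers and assays may have multiple parents (a pooled
measurement consumes several samples at once); biosources never do —
they hang directly off the root. Where the one-sentence "multiple
parents only for containers" reading conflicts with pooling into an
assay, we follow the operation contract: pooled assays are legal, and
the `MULTIPARENT_KIND` check fires only for biosources.

`validate()` re-checks every invariant as a batch over the stored
nodes and arcs (unique root, typing table, acyclicity, reachability
from the root, protocol-free root arcs, multi-parent kinds), so graphs
assembled or mutated outside the constructive API are caught. The
constructive API itself can only produce valid graphs — this is a
tested property, not an assumption: random operation sequences are
validated in bulk, and single-edit corruptions of valid graphs are
checked against an independently written per-invariant brute-force
checker.

## Ontology lookup

Ontologies are OBO 1.2 flat files, parsed with `obonet`; only the
lookup-relevant tags (`id`, `name`, `synonym`, `def`, `is_obsolete`,
`alt_id`, `namespace`) are used, and a line-level pre-scan reports the
exact line of any `[Term]` stanza missing an id or name. The service
does lookup, not reasoning — no subsumption or `is_a` traversal — and
is fully decoupled from the graph model, so it can serve other callers;
`search_json` provides the wire form
(`{"query": …, "matches": [{"accession", "name", "source",
"match_type", "score"}]}`).

Matching is case-insensitive and four-tiered, with fixed scores:
exact name 1.0, exact synonym 0.9, token 0.7 (every query token occurs
as a whole token of the name or of a single synonym), substring 0.5.
The tiers were chosen to be deterministic and oracle-checkable; there
is deliberately no embedding or fuzzy model. A term is reported once at
its best tier; ties are broken by accession, ascending, so results are
total-ordered and reproducible. Obsolete terms stay in the index but
are excluded unless `include_obsolete` is set. Because the weakest tier
is a substring test, every query necessarily scans all candidate terms;
the "index" is therefore a precomputation of lowercased fields and
token sets rather than an inverted index, and correctness is checked
against a from-scratch linear scan over the raw term fields.

`terminize` walks the study breadth-first from the root; for each node
it submits the label and every annotation name and value, and after a
node the action text of the arcs arriving at it. Fields with no
candidates still appear with empty lists, so the report enumerates
exactly the annotatable surface of the graph (a tested structural
property). Empty or whitespace queries return no matches by contract.

## Protocols, templates, minimum information

A registered protocol's text can never change: the `text` attribute
refuses assignment and there is no other public mutation path (tested
by attempting each one). Deviations are recorded in the `action` field
of the protocol application on the arc; "editing" a protocol means
registering a new one. Comments are append-only, with injectable
timestamps so tests stay deterministic, and are searched together with
the body and name (case-insensitive substring, results ordered by
name). Search results are filtered to what the caller may read:
private (default), shared with everyone, or shared with one access
group.

Technology templates are ordered field lists with required flags;
completing one validates required fields and any number of data files
can be associated in one call. `compile_minimum_info` merges a
biosource's technology-independent MIABS fields (species, strain,
genetic modification, sex, age, tissue, treatment — an extensible set)
with the `tech:`-prefixed values of a completed template; the prefix
keeps the key sets disjoint so the merge is lossless.

## Access control

Every securable object carries a creator and a grants map
(group → read_only | full). `read_only` = {read};
`full` = {read, write, delete}. Checks succeed for the creator, or for
members of any granted group at a sufficient level; objects inside an
investigation take the union of their own grants and the
investigation's, so granting at either level suffices and granting
never removes a capability. Only holders of full permission (including
the investigation creator) administer grants; grant and revoke are
idempotent. User identities are trusted inputs — authentication and
session management are out of scope.

## ISA-Tab export

One investigation file, one study table per study, one assay table per
(study, modality). The study table has one data row per distinct path
from the root to an assay-input container, rows in lexicographic label
order. Biosource annotations become `Characteristics[...]` columns
(with `Term Source REF` / `Term Accession Number` columns where a term
is attached), each non-root arc a `Protocol REF` column valued with the
protocol name, arc parameters `Parameter Value[...]` columns, and each
container a `Sample Name` column with its own characteristics block.
Dialect choices where the tabular form is under-determined:
intermediate containers appear as additional Protocol REF + Sample Name
steps (so chain labels survive round-trip); repeated same-name
annotations are grouped into adjacent columns; only the first attached
term of a value is written; leaf containers without assays still get a
row; multiple raw data files are ";"-joined; MIABS fields are not part
of the tabular mapping (annotations are). Output is byte-reproducible:
UTF-8, LF, fixed file naming (`i_<inv>.txt`, `s_<study>.txt`,
`a_<study>_<modality>.txt`).

The validator checks a core structural rule set rather than shelling
out to an external tool: section order of the investigation file,
existence of every referenced file, Protocol REFs declared in STUDY
PROTOCOLS, Term Source REFs declared in the ONTOLOGY SOURCE REFERENCE,
and assay Sample Names present in their study table. The importer
rebuilds a graph as a prefix tree over sample paths; a pooled container
reappears as one node per contributing path, which preserves exactly
the invariant the round-trip test asserts: the multiset of
root-to-leaf paths with labels, annotations, attached terms and
protocol names. Node identity beyond that (e.g. one pooled node versus
its per-path copies) is not recoverable from the tabular form and is
not claimed.

Reports are deterministic structured text plus a minimal HTML
rendering, listing items and actions in traversal order.

## Synthetic fixtures

`FixtureSpec(seed, n_biosources=4, max_depth=3, p_split=0.3,
p_pool=0.25, n_assay_modalities=2)` drives the study generator. The
defaults mirror a small multi-modal bench experiment of the kind the
worked example depicts: a handful of source materials, container
chains a few steps deep, occasional splits and pools, two assay
modalities. Generated studies are *complete*: every biosource is
extracted into at least one container and every leaf container feeds
an assay — material that never reaches a sample path cannot appear in
the tabular export, so completeness is the precondition under which
the round-trip property is meaningful. Around 70 % of non-root arcs
get protocol applications (sometimes with parameters and deviation
notes) and about half the species annotations carry a toy ontology
term, so exports exercise every column type. The toy OBO generator
emits unique 1–3-word names over a fixed 44-word vocabulary with an
adjustable synonym rate. Everything derives from the seed: same seed,
byte-identical serializations, reports and bundles.

What the generator does not emulate: real ontology vocabulary
distributions (names are random word combinations), attachment file
contents (opaque paths and checksums only), concurrent multi-user
editing, and malformed user input beyond what the corruption tests
inject. Passing tests therefore demonstrate structural and contract
correctness, not robustness to arbitrary real-world OBO files or
hostile stores.

The canonical worked example fixes one interpretation where the
source sketch is ambiguous: four biosources (one chicken, three
bacterial replicates), exactly two petri dishes, one eppendorf tube,
one imaging assay per dish and one sequencing assay for the tube.

## Problem sizes and numerical choices

The bundled test suite validates 1000 random construction sequences,
corrupts 100 small graphs edit by edit, round-trips 100 random
investigations and compares 1000 queries against a 10,000-term
ontology — the same sizes `scripts/acceptance.py` re-measures; the
whole suite runs in well under a minute on one CPU. All scores,
orderings and serializations are exact (no floating-point tolerances
anywhere); determinism is asserted as byte equality. Identifiers come
from a counter when a seed is supplied (reproducible fixtures) and
from UUIDs otherwise.

## Known limitations

* The HTTP façade of the lookup service is not included; the JSON
  contract and the decoupled index are, and a web layer would be a
  thin wrapper.
* ISA-Tab import targets this writer's own dialect; arbitrary
  third-party ISA-Tab archives are out of scope.
* Deleting a node with children requires an explicit cascade flag;
  cascade removes descendants reachable only through the deleted node.
* Reports are text/HTML; no PDF typesetting.
* `external_link` on assays is an opaque string — no live integration
  with external data stores.
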