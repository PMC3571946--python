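# expgraph

Typed provenance graphs, ontology annotation and ISA-Tab export for
laboratory experiments.

## The problem

Multi-platform biological experiments (transcriptomics, proteomics,
imaging, …) need their sample-preparation history described precisely
enough to be analysed, shared and deposited in public repositories —
yet the people who know that history are bench scientists, not data
curators. `expgraph` captures an experiment the way it happens on the
bench: as a directed acyclic graph whose nodes are physical things and
whose arcs are the actions connecting them.

* An **Investigation** is the root of the data model: a container for
  **studies**, with a fixed set of declared OBO ontology sources and an
  access group created alongside it.
* A **study graph** has a single root node (the study itself) and only
  three other node kinds, with typing rules
  `root → biosource → container → container|assay`:
  **biosources** (raw biological input — an organism, a culture),
  **containers** (tubes, dishes; the ISA-Tab "sample"), and **assays**
  (measurement events: a sequencing run, an image acquisition).
  Splitting a sample adds several children to one container; pooling
  gives the pooled container one incoming arc per source.
* Arcs carry **protocol applications**: a reference to a registered,
  *immutable* protocol text plus an `action` field recording any
  deviation, and ordered parameter name/value pairs.
* Free name/value **annotations** on any node can be linked to
  **ontology terms**; the `terminize` traversal runs every text field
  of a graph through a ranked OBO term search
  (exact-name 1.0 > exact-synonym 0.9 > token 0.7 > substring 0.5) and
  collects candidates for the user to attach.
* Everything is **private by default**; access groups grant read-only
  or full (read/write/delete) rights at the object or investigation
  level.
* A finished investigation exports as a tab-delimited **ISA-Tab**
  bundle (`i_`/`s_`/`a_` files, one study-table row per
  source-to-sample path), with a structural validator and an importer
  for round-trip checking, plus human-readable study and protocol
  reports.

## A worked example

The canonical study ships as a fixture: one chicken and three bacterial
replicate cultures; chicken tissue is split across two petri dishes
(imaged), the replicates are pooled into one eppendorf tube
(sequenced).

```python
import expgraph as eg

repo, inv, study = eg.build_figure1_investigation()
print(len(study.nodes_of_kind("biosource")))          # 4
print(sorted({a.modality for a in study.nodes_of_kind("assay")}))
                                                       # ['imaging', 'sequencing']
print(study.validate())                                # []

bundle = eg.export_isatab(inv, "isatab_out")
print(eg.validate_isatab("isatab_out"))                # []
```

Running `python examples/03_export_isatab.py` prints:

```
study table: 5 data rows (3 pooled replicates + 2 chicken splits)
```

— five rows because the pooled tube repeats its Sample Name once per
contributing replicate and the split chicken repeats its Source Name
once per dish: exactly the path structure of the graph, which is why
`import_isatab(export_isatab(G))` preserves the multiset of
source-to-assay paths.

The `examples/` directory holds one short script per capability
(building and validating, ontology lookup, ISA-Tab export, protocols
and sharing), and the `expgraph` command drives the same library from
the shell (`expgraph --store lab.json init "My study"`, `add-biosource`,
`pool`, `terminize`, `export isatab`, `validate`, `fixture …`; exit
code 2 flags validation failures).

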