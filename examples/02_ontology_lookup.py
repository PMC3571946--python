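"""Ranked ontology lookup and the terminize traversal.

Loads a small OBO ontology, searches it directly, then lets terminize
walk the whole study graph and propose terms for every text field.
"""

import pathlib
import tempfile

import expgraph as eg

workdir = pathlib.Path(tempfile.mkdtemp())
obo = workdir / "toy.obo"
obo.write_text(eg.FIGURE1_OBO, encoding="utf-8")
index = eg.load_obo(obo)
print(f"indexed {index.term_count} terms from source {index.sources}")

for query in ("Gallus gallus", "chicken", "sequencing run"):
    hits = index.search(query, limit=3)
    shown = ", ".join(f"{m.term.name} ({m.match_type}, {m.score})"
                      for m in hits) or "no match"
    print(f"  {query!r:20} -> {shown}")

study = eg.build_figure1_study()
report = eg.terminize(study, index)
print(f"terminize scanned {len(report.entries)} text fields, "
      f"{len(report.non_empty())} with candidates:")
for entry in report.non_empty()[:5]:
    best = entry.matches[0]
    print(f"  {entry.field_path:22} {entry.query!r:22} "
          f"-> {best.term.accession} {best.term.name}")
# Each candidate is scored 1.0/0.9/0.7/0.5 for exact-name, exact-synonym,
# token and substring matches; the user picks which to attach.
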