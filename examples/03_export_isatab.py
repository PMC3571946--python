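"""Export the worked example as ISA-Tab, validate and re-import it.

The study table carries one row per source-to-sample path: the split
chicken appears twice (two dishes), the pooled tube three times (one row
per contributing replicate).
"""

import pathlib
import tempfile

import expgraph as eg

repo, inv, study = eg.build_figure1_investigation()
out = pathlib.Path(tempfile.mkdtemp()) / "isatab"
bundle = eg.export_isatab(inv, out)

print("bundle files:")
for p in sorted(out.iterdir()):
    print(f"  {p.name}")

print(f"\nstructural violations: {len(eg.validate_isatab(out))}")

rows = (out / f"s_{study.id}.txt").read_text(encoding="utf-8").splitlines()
print(f"study table: {len(rows) - 1} data rows "
      "(3 pooled replicates + 2 chicken splits)")
print("first data row:", rows[1].split("\t")[:2], "...")

back = eg.import_isatab(out)
print(f"re-imported: {back.title!r} with "
      f"{len(back.studies[0].nodes)} nodes")
# A clean validator run plus a successful re-import shows the bundle is
# internally consistent and loses no sample path.
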