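"""Build the canonical worked example and validate its structure.

One chicken and three bacterial replicate cultures enter the study;
chicken tissue is split across two petri dishes (imaged), the bacterial
replicates are pooled into one eppendorf tube (sequenced).
"""

import expgraph as eg

repo, inv, study = eg.build_figure1_investigation()

print(f"investigation: {inv.title}")
print(f"biosources:    {len(study.nodes_of_kind('biosource'))}")
print(f"containers:    {len(study.nodes_of_kind('container'))}")
print(f"assays:        {len(study.nodes_of_kind('assay'))} "
      f"({sorted({n.modality for n in study.nodes_of_kind('assay')})})")

tube = next(n for n in study.nodes.values() if n.label == "eppendorf_tube")
print(f"pooled sources into {tube.label}: {len(study.arcs_in(tube.id))}")

violations = study.validate()
print(f"structural violations: {len(violations)}")
# 4 biosources, a 3-way pool, two modalities and zero violations mean the
# graph obeys the root->biosource->container->assay typing rules.
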