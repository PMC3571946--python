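"""Seedable synthetic fixtures: study graphs, toy ontologies, and the
canonical worked example.

The generators exist so that every property of the system — graph
typing, export round-trips, search ranking — can be exercised on
arbitrarily many studies without shipping any data.  Generated studies
are "complete" experiments: every biosource is extracted into at least
one container and every leaf container feeds an assay, which is also
the precondition for the tabular export to capture all material.  All
output is deterministic for a given seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from .errors import SpecError
from .graph import NodeKind, StudyGraph, TermRef
from .investigation import Investigation, Repository
from .ontology import OntologySource
from .protocols import ProtocolRegistry

MODALITIES = ("sequencing", "imaging", "mass_spectrometry", "microarray")

_SPECIES = ("Gallus gallus", "Escherichia coli", "Mus musculus",
            "Homo sapiens", "Saccharomyces cerevisiae")

_PROTOCOLS = (
    ("sample extraction", "Extract the biomaterial from the source "
     "organism and transfer it to a sterile container."),
    ("aliquoting", "Divide the sample into equal aliquots under "
     "sterile conditions."),
    ("pooling", "Combine the replicate samples into a single vessel "
     "and mix gently."),
    ("library preparation", "Prepare the sequencing library following "
     "the kit instructions."),
    ("staining", "Apply the stain and incubate in the dark for 30 "
     "minutes before imaging."),
)

_WORDS = (
    "aerobic", "anaerobic", "bacterial", "basal", "cardiac", "cell",
    "chronic", "cortical", "culture", "cycle", "dermal", "dorsal",
    "embryonic", "enzyme", "epithelial", "fluid", "gene", "growth",
    "hepatic", "host", "immune", "infection", "larval", "lateral",
    "membrane", "metabolic", "microbial", "neural", "nutrient", "organ",
    "pathway", "phase", "plasma", "protein", "renal", "response",
    "sample", "serum", "signal", "stress", "tissue", "vascular",
    "ventral", "viral",
)


@dataclass
class FixtureSpec:
    """Knobs of the random-study generator."""

    seed: int = 0
    n_biosources: int = 4
    max_depth: int = 3
    p_split: float = 0.3
    p_pool: float = 0.25
    n_assay_modalities: int = 2

    def __post_init__(self):
        if self.n_biosources < 1:
            raise SpecError("n_biosources must be >= 1")
        if self.max_depth < 1:
            raise SpecError("max_depth must be >= 1")
        for name in ("p_split", "p_pool"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise SpecError(f"{name} must be in [0, 1]")
        if not 1 <= self.n_assay_modalities <= len(MODALITIES):
            raise SpecError(
                f"n_assay_modalities must be in [1, {len(MODALITIES)}]")


def generate_fixture_repository(spec: FixtureSpec) -> Repository:
    """A repository holding one random but always-valid study.

    The study has exactly ``spec.n_biosources`` biosources, container
    chains up to ``spec.max_depth`` deep with splits and pools, and one
    assay per leaf container cycling through the first
    ``n_assay_modalities`` modalities.  Some annotations carry toy
    ontology terms and some arcs carry protocol applications with
    parameters.
    """
    rng = random.Random(spec.seed)
    repo = Repository(seed=spec.seed)
    owner = repo.add_user("generator")
    source = OntologySource("TOY", "toy.obo", "1", "synthetic toy ontology")
    inv = repo.create_investigation(
        f"Synthetic investigation (seed {spec.seed})", [source], owner)
    study = repo.add_study(inv, f"synthetic study {spec.seed}", owner)
    protocols = [repo.protocols.register(name, text, owner)
                 for name, text in _PROTOCOLS]

    counter = {"c": 0}

    def clabel() -> str:
        counter["c"] += 1
        return f"container_{counter['c']}"

    # biosources with annotations (sometimes term-annotated) and miabs
    for i in range(spec.n_biosources):
        b = study.add_child(study.root_id, NodeKind.BIOSOURCE,
                            f"biosource_{i + 1}")
        sp_idx = rng.randrange(len(_SPECIES))
        ann = study.annotate(b.id, "species", _SPECIES[sp_idx])
        if rng.random() < 0.5:
            ann.value_terms.append(
                TermRef("TOY", f"TOY:{sp_idx + 1:07d}", _SPECIES[sp_idx]))
        if rng.random() < 0.5:
            study.annotate(b.id, "strain", f"strain_{rng.randrange(1, 100)}")
        if rng.random() < 0.3:
            study.annotate(b.id, "note", rng.choice(_WORDS))
        b.miabs["species"] = _SPECIES[sp_idx]

    def apply_random_protocol(parent_id: str, child_id: str) -> None:
        if rng.random() < 0.7:
            proto = rng.choice(protocols)
            params = []
            if rng.random() < 0.5:
                params.append(("temperature", f"{rng.randrange(4, 40)}C"))
            if rng.random() < 0.3:
                params.append(("duration", f"{rng.randrange(5, 120)}min"))
            action = "" if rng.random() < 0.7 else \
                f"deviation: incubated {rng.randrange(1, 10)} min longer"
            arc = study.arc_between(parent_id, child_id)
            study.apply_protocol(arc.id, proto, action, params,
                                 registry=repo.protocols)

    # extraction: every biosource gets >= 1 container, sometimes a split
    frontier: list[str] = []
    for b in study.nodes_of_kind(NodeKind.BIOSOURCE):
        n_first = 1 + (1 if rng.random() < spec.p_split else 0)
        for _ in range(n_first):
            c = study.add_child(b.id, NodeKind.CONTAINER, clabel())
            apply_random_protocol(b.id, c.id)
            if rng.random() < 0.3:
                study.annotate(c.id, "volume", f"{rng.randrange(1, 50)}ml")
            frontier.append(c.id)

    # deeper container chains
    for _depth in range(1, spec.max_depth):
        nxt: list[str] = []
        for cid in frontier:
            if rng.random() < spec.p_split:
                for _ in range(rng.randrange(1, 3)):
                    c = study.add_child(cid, NodeKind.CONTAINER, clabel())
                    apply_random_protocol(cid, c.id)
                    nxt.append(c.id)
            else:
                nxt.append(cid)
        frontier = nxt

    # pooling: merge a few same-level containers
    if len(frontier) >= 2 and rng.random() < spec.p_pool:
        k = min(len(frontier), rng.randrange(2, 4))
        chosen = sorted(rng.sample(range(len(frontier)), k))
        pooled_sources = [frontier[i] for i in chosen]
        pooled = study.pool(pooled_sources, NodeKind.CONTAINER, clabel())
        for pid in pooled_sources:
            apply_random_protocol(pid, pooled.id)
        frontier = [c for i, c in enumerate(frontier) if i not in chosen]
        frontier.append(pooled.id)

    # every leaf container feeds one assay
    for i, cid in enumerate(frontier):
        modality = MODALITIES[i % spec.n_assay_modalities]
        a = study.add_child(cid, NodeKind.ASSAY, f"assay_{i + 1}",
                            modality=modality)
        apply_random_protocol(cid, a.id)
        if rng.random() < 0.4:
            from .graph import FileAttachment
            study.attach_file(a.id, FileAttachment(
                filename=f"raw_{i + 1}.dat", checksum="0" * 8,
                size=rng.randrange(1, 10 ** 6)))
    return repo


def generate_fixture_investigation(spec: FixtureSpec) -> Investigation:
    """The investigation of :func:`generate_fixture_repository`."""
    repo = generate_fixture_repository(spec)
    return next(iter(repo.investigations.values()))


def generate_fixture_graph(spec: FixtureSpec) -> StudyGraph:
    """The study graph of :func:`generate_fixture_repository`."""
    return generate_fixture_investigation(spec).studies[0]


# ---------------------------------------------------------------------------
# toy OBO ontologies
# ---------------------------------------------------------------------------

def generate_toy_obo(seed: int, n_terms: int, synonym_rate: float = 0.3,
                     obsolete_rate: float = 0.0, path: str | Path | None = None,
                     ) -> str:
    """A deterministic OBO 1.2 document with ``n_terms`` [Term] stanzas.

    Term names are unique 1-3 word phrases over a small biological
    vocabulary; a fraction of terms get an EXACT synonym and, if asked,
    a fraction are flagged obsolete.
    """
    if n_terms < 1:
        raise SpecError("n_terms must be >= 1")
    rng = random.Random(seed)
    lines = ["format-version: 1.2", "ontology: toy", ""]
    used: set[str] = set()
    for i in range(1, n_terms + 1):
        for _ in range(100):
            name = " ".join(rng.sample(_WORDS, rng.randrange(1, 4)))
            if name not in used:
                break
        else:
            name = f"term {i}"
        used.add(name)
        lines.append("[Term]")
        lines.append(f"id: TOY:{i:07d}")
        lines.append(f"name: {name}")
        if rng.random() < synonym_rate:
            syn = " ".join(rng.sample(_WORDS, 2)) + f" {i}"
            lines.append(f'synonym: "{syn}" EXACT []')
        if rng.random() < 0.5:
            lines.append(f'def: "synthetic definition of {name}" []')
        if rng.random() < obsolete_rate:
            lines.append("is_obsolete: true")
        lines.append("")
    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# the canonical worked example
# ---------------------------------------------------------------------------

FIGURE1_OBO = """format-version: 1.2
ontology: toy

[Term]
id: TOY:0000001
name: Gallus gallus
synonym: "chicken" EXACT []
def: "the domestic chicken" []

[Term]
id: TOY:0000002
name: Escherichia coli
synonym: "bacterium" RELATED []
def: "a model gut bacterium" []

[Term]
id: TOY:0000003
name: petri dish
def: "a shallow cylindrical culture container" []

[Term]
id: TOY:0000004
name: DNA sequencing
synonym: "sequencing" EXACT []
def: "determination of a nucleotide sequence" []

[Term]
id: TOY:0000005
name: microscopy imaging
synonym: "imaging" EXACT []
def: "acquisition of microscope images" []
"""


def build_figure1_investigation(owner_name: str = "alice"
                                ) -> tuple[Repository, Investigation, StudyGraph]:
    """The canonical chick-infection worked example.

    One chicken and three bacterial replicate biosources; the chicken
    material is split across two petri dishes, the three bacterial
    replicates are pooled into one eppendorf tube; the dishes feed
    imaging assays and the tube feeds a sequencing assay.  The bacterial
    replicate count and the two petri dishes fix an interpretation of
    the canonical layout; see the methods note.
    """
    repo = Repository(seed=1)
    owner = repo.add_user(owner_name)
    source = OntologySource("TOY", "toy.obo", "1", "toy ontology")
    inv = repo.create_investigation("Chick infection study", [source], owner)
    study = repo.add_study(inv, "Chick infection study", owner)

    extract = repo.protocols.register(
        "tissue extraction",
        "Dissect the tissue and place it into a sterile dish.", owner)
    pool_p = repo.protocols.register(
        "culture pooling",
        "Combine the replicate cultures into one tube.", owner)
    imaging_p = repo.protocols.register(
        "confocal imaging",
        "Mount the dish and acquire a confocal z-stack.", owner)
    seq_p = repo.protocols.register(
        "genomic sequencing",
        "Extract DNA, prepare the library and sequence.", owner)

    chicken = study.add_child(study.root_id, NodeKind.BIOSOURCE, "chicken")
    ann = study.annotate(chicken.id, "species", "Gallus gallus")
    ann.value_terms.append(TermRef("TOY", "TOY:0000001", "Gallus gallus"))
    chicken.miabs.update({"species": "Gallus gallus", "sex": "female",
                          "age": "12 weeks"})

    replicates = []
    for i in range(1, 4):
        b = study.add_child(study.root_id, NodeKind.BIOSOURCE,
                            f"bacterial_replicate_{i}")
        a = study.annotate(b.id, "species", "Escherichia coli")
        a.value_terms.append(TermRef("TOY", "TOY:0000002", "Escherichia coli"))
        b.miabs["species"] = "Escherichia coli"
        replicates.append(b)

    dishes = []
    for i in range(1, 3):
        d = study.add_child(chicken.id, NodeKind.CONTAINER, f"petri_dish_{i}")
        study.annotate(d.id, "container_type", "petri dish")
        arc = study.arc_between(chicken.id, d.id)
        study.apply_protocol(arc.id, extract, registry=repo.protocols)
        dishes.append(d)

    tube = study.pool([b.id for b in replicates], NodeKind.CONTAINER,
                      "eppendorf_tube")
    study.annotate(tube.id, "container_type", "eppendorf tube")
    for b in replicates:
        arc = study.arc_between(b.id, tube.id)
        study.apply_protocol(arc.id, pool_p, registry=repo.protocols)

    for i, d in enumerate(dishes, start=1):
        a = study.add_child(d.id, NodeKind.ASSAY, f"imaging_{i}",
                            modality="imaging")
        arc = study.arc_between(d.id, a.id)
        study.apply_protocol(arc.id, imaging_p, registry=repo.protocols)

    seq = study.add_child(tube.id, NodeKind.ASSAY, "sequencing_1",
                          modality="sequencing")
    arc = study.arc_between(tube.id, seq.id)
    study.apply_protocol(arc.id, seq_p,
                         action="library input was 20% below protocol amount",
                         registry=repo.protocols)
    return repo, inv, study


def build_figure1_study() -> StudyGraph:
    """Just the study graph of the canonical worked example."""
    return build_figure1_investigation()[2]
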