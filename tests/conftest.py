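"""Shared fixtures: a retina/interneuron annotation set with a merged
anatomy+cell ontology, and small synthetic bundles."""

import pytest
from hypothesis import HealthCheck, settings

from ontoexpr import (
    Annotation,
    Condition,
    ConditionContext,
    ControlledVocabulary,
    SynthConfig,
    TaxonConstraints,
    parse_obo,
    simulate_bundle,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

HUMAN = 9606
FLY = 7227

RETINA_OBO = """format-version: 1.2

[Term]
id: UBERON:0000001
name: anatomical entity

[Term]
id: UBERON:0000970
name: eye
is_a: UBERON:0000001

[Term]
id: UBERON:0000966
name: retina
relationship: part_of UBERON:0000970

[Term]
id: CL:0000000
name: cell

[Term]
id: CL:0000540
name: neuron
is_a: CL:0000000

[Term]
id: CL:0000099
name: interneuron
is_a: CL:0000540

[Term]
id: CL:0000561
name: amacrine cell
is_a: CL:0000099

[Term]
id: CL:0000745
name: retina horizontal cell
is_a: CL:0000099

[Term]
id: CL:0000748
name: retinal bipolar neuron
is_a: CL:0000099

[Term]
id: CL:0000066
name: epithelial cell
is_a: CL:0000000

[Term]
id: FBbt:00100482
name: lobula columnar neuron Lcn10
is_a: CL:0000099
"""

STAGE_OBO = """format-version: 1.2

[Term]
id: UBERON:0000104
name: life cycle

[Term]
id: UBERON:0000113
name: post-juvenile adult stage
is_a: UBERON:0000104
"""


@pytest.fixture(scope="session")
def retina_ontology():
    return parse_obo(RETINA_OBO)


@pytest.fixture(scope="session")
def retina_ctx(retina_ontology):
    """Merged anatomy+cell ontology for human/fly with taxon constraints:
    every Uberon/CL term exists in both species, the FBbt term only in fly."""
    stages = parse_obo(STAGE_OBO)
    records = []
    for term in retina_ontology.terms:
        if term.startswith("FBbt:"):
            records.append((term, FLY, True))
        else:
            records.extend([(term, HUMAN, True), (term, FLY, True)])
    for term in stages.terms:
        records.extend([(term, HUMAN, True), (term, FLY, True)])
    return ConditionContext(
        anatomy=retina_ontology,
        stages=stages,
        sex=ControlledVocabulary("any sex", frozenset({"female", "male"})),
        strain=ControlledVocabulary("wild type", frozenset({"mixed"})),
        taxon_constraints=TaxonConstraints.from_records(records),
        anat_root="UBERON:0000001",
        cell_root="CL:0000000",
        stage_root="UBERON:0000104",
    )


def _ann(lib, cell, anat="UBERON:0000966", label="", data_type="sc_droplet"):
    return Annotation(
        library_id=lib,
        experiment_id="SRP222001",
        condition=Condition(
            anat, cell, "UBERON:0000113", "any sex", "wild type", HUMAN
        ),
        free_text_label=label,
        data_type=data_type,
    )


@pytest.fixture(scope="session")
def retina_annotations():
    """Three interneuron-subtype cell populations plus two distractor
    annotations (an epithelial population and one mapped to the parent term
    'neuron', which is *not* a child of 'interneuron')."""
    return [
        _ann("LIB1", "CL:0000745", label="horizontal cells"),
        _ann("LIB2", "CL:0000561", label="amacrine-like"),
        _ann("LIB3", "CL:0000748", label="retinal bipolar neuron type A"),
        _ann("LIB4", "CL:0000066", anat="UBERON:0000970", label="epithelium"),
        _ann("LIB5", "CL:0000540", label="unresolved neurons"),
    ]


@pytest.fixture(scope="session")
def small_bundle():
    """A fast synthetic bundle shared by io/cli tests."""
    cfg = SynthConfig(
        seed=5, n_genes=200, n_intergenic=60, n_dubious_intergenic=6,
        n_bulk_samples=4, n_cells=40, n_clusters=2, n_sc_libraries=1,
        depth=2, umi_per_cell=800,
    )
    return simulate_bundle(cfg)
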