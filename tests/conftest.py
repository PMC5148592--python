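"""Shared fixtures: worked-example records and small seeded corpora."""

import pytest

from aqlstore.engine import QueryEngine
from aqlstore.index import IndexService
from aqlstore.records import Record, archetype, attribute, leaf
from aqlstore.storage import DriverConfig, MemoryDriver
from aqlstore.bench import ingest
from aqlstore.synth import GeneratorProfile, build_structure_library, generate_corpus

# Synthetic worked-example record: a composition archetype containing six
# archetypes (seven in total), all children sharing the same
# path_from_parent — they sit in one list under /content[at0001], the
# composition's content slot.  The shape (root class, archetype count,
# shared relative path) is fixed; the concrete child classes and leaf
# values are this suite's own reconstruction.
FIG_ROOT_CLASS = "openEHR-EHR-COMPOSITION.encounter.v1.lbl-00001"
FIG_CHILD_CLASSES = [
    "openEHR-EHR-OBSERVATION.blood_pressure.v1",
    "openEHR-EHR-OBSERVATION.body_weight.v1",
    "openEHR-EHR-OBSERVATION.lab_result.v1",
    "openEHR-EHR-EVALUATION.problem_diagnosis.v1",
    "openEHR-EHR-INSTRUCTION.medication_order.v1",
    "openEHR-EHR-ACTION.procedure.v1",
]


def make_worked_example_record(record_id: str = "fig-1",
                               magnitude: float = 142.0) -> Record:
    children = []
    for cls in FIG_CHILD_CLASSES:
        data = attribute(
            "data[at0001]",
            attribute("events[at0006]", attribute("magnitude", leaf(magnitude))),
        )
        children.append(archetype(cls, data))
    root = archetype(FIG_ROOT_CLASS, attribute("content[at0001]", *children))
    return Record(record_id=record_id, ehr_id="ehr-1", root=root)


WORKED_QUERY = (
    "SELECT o/data[at0001]/events[at0006]/magnitude "
    f"FROM EHR e CONTAINS COMPOSITION c [{FIG_ROOT_CLASS}] "
    "CONTAINS OBSERVATION o [openEHR-EHR-OBSERVATION.blood_pressure.v1] "
    "WHERE o/data[at0001]/events[at0006]/magnitude > 120"
)


@pytest.fixture
def worked_record() -> Record:
    return make_worked_example_record()


@pytest.fixture(scope="session")
def small_profile() -> GeneratorProfile:
    return GeneratorProfile(n_base_structures=80, n_records=3000, seed=11)


@pytest.fixture(scope="session")
def small_library(small_profile):
    return build_structure_library(small_profile)


@pytest.fixture(scope="session")
def small_corpus(small_profile, small_library):
    lines, manifest = generate_corpus(small_profile, library=small_library)
    return lines, manifest


@pytest.fixture
def loaded_engine(small_corpus):
    lines, manifest = small_corpus
    index = IndexService()
    driver = MemoryDriver().connect(DriverConfig())
    ingest(lines, driver, index)
    return QueryEngine(driver, index), driver, index
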