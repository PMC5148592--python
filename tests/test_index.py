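"""Structure extraction, canonical ids, registration, containment lookup."""

import json
import random
import subprocess
import sys

import pytest

from aqlstore import baseline
from aqlstore.index import (
    ContainmentChain,
    IndexService,
    StructureNode,
    canonical_id,
    describe,
    extract_structure,
    structure_of_document,
)
from aqlstore.records import RelPath, from_document, resolve_path
from aqlstore.synth import instantiate_document, instantiate_library_records

from conftest import FIG_ROOT_CLASS, make_worked_example_record


# -- extraction --------------------------------------------------------------


def test_worked_example_structure_has_seven_nodes_six_sharing_path():
    desc = extract_structure(make_worked_example_record())
    assert desc.node_count == 7
    pfps = [c.path_from_parent for c in desc.root.children]
    assert len(pfps) == 6
    assert len(set(pfps)) == 1


def test_single_archetype_structure():
    from aqlstore.records import Record, archetype
    rec = Record(record_id="r", root=archetype("openEHR-EHR-OBSERVATION.one.v1"))
    desc = extract_structure(rec)
    assert desc.node_count == 1
    assert desc.root.path_from_parent == ""


def test_extraction_node_count_equals_dfs_archetype_count(small_library):
    def dfs(node):
        return (1 if node.kind == "archetype" else 0) + \
            sum(dfs(c) for c in node.children)

    for doc in instantiate_library_records(small_library[:30],
                                           per_structure=2, seed=3):
        rec = from_document(doc)
        assert extract_structure(rec).node_count == dfs(rec.root)
        # dict fast path agrees with the record-model path
        assert structure_of_document(doc).structure_id == \
            extract_structure(rec).structure_id


# -- canonical ids -----------------------------------------------------------


def independent_canonical(node: StructureNode):
    """Test-local canonical form: sort-then-compare, written separately."""
    kids = sorted((independent_canonical(c) for c in node.children),
                  key=lambda t: json.dumps(t))
    return [node.archetype_class, node.path_from_parent, kids]


def test_sibling_shuffles_do_not_change_the_id(small_library):
    rng = random.Random(17)
    for desc in small_library[:40]:
        base = instantiate_document(desc, random.Random(1), "r0", "e0",
                                    shuffle=False)
        sid0 = structure_of_document(base).structure_id
        for _ in range(3):
            shuffled = instantiate_document(desc, rng, "r1", "e1", shuffle=True)
            assert structure_of_document(shuffled).structure_id == sid0


def test_id_equality_agrees_with_independent_canonical_comparison(small_library):
    rng = random.Random(23)
    pool = small_library[:60]
    for _ in range(500):
        a, b = rng.choice(pool), rng.choice(pool)
        same_id = a.structure_id == b.structure_id
        same_canon = independent_canonical(a.root) == independent_canonical(b.root)
        assert same_id == same_canon


def test_canonical_id_is_stable_across_processes():
    snippet = (
        "from aqlstore.index import StructureNode, canonical_id;"
        "n = StructureNode('openEHR-EHR-OBSERVATION.one.v1', '', ());"
        "print(canonical_id(n))"
    )
    outs = {
        subprocess.run([sys.executable, "-c", snippet], capture_output=True,
                       text=True, check=True).stdout.strip()
        for _ in range(2)
    }
    assert len(outs) == 1
    local = canonical_id(StructureNode("openEHR-EHR-OBSERVATION.one.v1", "", ()))
    assert outs == {local}


# -- registration ------------------------------------------------------------


def test_register_is_idempotent():
    idx = IndexService()
    desc = extract_structure(make_worked_example_record())
    sid1 = idx.register(desc)
    sid2 = idx.register(desc)
    assert sid1 == sid2
    assert len(idx) == 1


def test_registry_size_equals_planted_distinct_forms(small_library):
    idx = IndexService()
    k = 25
    for doc in instantiate_library_records(small_library[:k],
                                           per_structure=4, seed=9):
        idx.register_record(doc)
    assert len(idx) == k
    stats = idx.index_stats()
    assert stats["structure_count"] == k
    assert stats["records_total"] == 4 * k


def test_empty_registry_stats():
    assert IndexService().index_stats()["structure_count"] == 0


def test_registry_export_import_round_trip(small_library):
    idx = IndexService()
    for desc in small_library[:15]:
        idx.register(desc)
    idx2 = IndexService()
    idx2.import_jsonl(idx.export_jsonl())
    assert sorted(idx2.export_jsonl()) == sorted(idx.export_jsonl())


# -- containment lookup ------------------------------------------------------


def test_worked_example_chain_yields_one_match_one_concatenated_path():
    idx = IndexService()
    rec = make_worked_example_record()
    sid = idx.register(extract_structure(rec))
    chain = ContainmentChain((FIG_ROOT_CLASS,
                              "openEHR-EHR-OBSERVATION.blood_pressure.v1"))
    matches = idx.lookup_containment(chain)
    assert len(matches) == 1
    assert matches[0].structure_id == sid
    assert len(matches[0].paths) == 1
    # the absolute path concatenates the relative paths along the spine and
    # resolves, on the record, to the innermost archetype of the chain
    hits = resolve_path(rec.root, matches[0].paths[0])
    classes = {n.archetype_class for n in hits if n.kind == "archetype"}
    assert "openEHR-EHR-OBSERVATION.blood_pressure.v1" in classes


def test_unregistered_class_yields_no_match():
    idx = IndexService()
    idx.register(extract_structure(make_worked_example_record()))
    chain = ContainmentChain(("openEHR-EHR-COMPOSITION.not_there.v1", "*"))
    assert idx.lookup_containment(chain) == []


def test_empty_chain_is_rejected():
    with pytest.raises(ValueError):
        IndexService().lookup_containment(ContainmentChain(()))


def _skeleton_doc(desc):
    return instantiate_document(desc, random.Random(0), "r", "e", shuffle=False)


def test_lookup_agrees_with_bruteforce_chain_oracle(small_library):
    """Soundness and completeness vs the recursive scanner's matcher."""
    rng = random.Random(31)
    idx = IndexService()
    lib = small_library[:50]
    for desc in lib:
        idx.register(desc)
    classes = sorted({n.archetype_class
                      for d in lib for n in d.root.iter_nodes()})
    for _ in range(40):
        length = rng.randint(1, 4)
        patterns = tuple(rng.choice(classes) for _ in range(length))
        matched = {m.structure_id for m in
                   idx.lookup_containment(ContainmentChain(patterns))}
        expected = {
            d.structure_id for d in lib
            if baseline.chain_instances(_skeleton_doc(d), patterns)
        }
        assert matched == expected


def test_lookup_paths_land_on_matching_archetypes(small_library):
    idx = IndexService()
    lib = small_library[:30]
    for desc in lib:
        idx.register(desc)
    by_id = {d.structure_id: d for d in lib}
    some_class = lib[5].root.children[0].archetype_class \
        if lib[5].root.children else lib[5].root.archetype_class
    for m in idx.lookup_containment(ContainmentChain((some_class,))):
        rec = from_document(_skeleton_doc(by_id[m.structure_id]))
        for p in m.paths:
            hits = [n for n in resolve_path(rec.root, p)
                    if n.kind == "archetype"]
            assert any(n.archetype_class == some_class for n in hits)


def test_lookup_needs_no_record_store():
    """The registry alone answers containment: no store handle exists on
    the service, and lookup works before any record is stored anywhere."""
    idx = IndexService()
    idx.register(extract_structure(make_worked_example_record()))
    assert not any("driver" in a or "store" in a for a in vars(idx))
    chain = ContainmentChain((FIG_ROOT_CLASS, "*"))
    assert idx.lookup_containment(chain)


def test_referential_integrity_after_ingest(loaded_engine):
    _engine, driver, index = loaded_engine
    for env in driver._containers["ehr"].values():
        assert env.versions[-1]["structure_id"] in index
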