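"""Driver contract: CRUD with versioning, encoding, sessions, execution."""

import json
import random

import pytest

from aqlstore import aql
from aqlstore.index import ContainmentChain, IndexService, extract_structure
from aqlstore.records import Record, archetype, attribute, leaf, record_equal
from aqlstore.storage import (
    DriverConfig,
    DriverNotInstalledError,
    DuplicateRecordError,
    MemoryDriver,
    NotConnectedError,
    RecordNotFoundError,
    create_driver,
    decode_keys,
    encode_keys,
    run_conformance,
)

from conftest import WORKED_QUERY, make_worked_example_record


def fresh_driver() -> MemoryDriver:
    return MemoryDriver().connect(DriverConfig())


def simple_record(rid="r1", value=1.0) -> Record:
    return Record(
        record_id=rid,
        root=archetype("openEHR-EHR-OBSERVATION.simple.v1",
                       attribute("data", attribute("value", leaf(value)))),
    )


# -- conformance and factory -------------------------------------------------


def test_reference_driver_passes_the_conformance_suite():
    assert run_conformance(MemoryDriver) == []


def test_reserved_driver_names_raise_not_installed():
    for name in ("mongodb", "elasticsearch"):
        with pytest.raises(DriverNotInstalledError):
            create_driver(DriverConfig(driver_name=name))


def test_fetch_threshold_must_be_non_negative():
    with pytest.raises(ValueError):
        DriverConfig(fetch_threshold=-1)


def test_driver_config_loads_from_yaml_and_json(tmp_path):
    y = tmp_path / "conf.yaml"
    y.write_text("driver:\n  driver_name: memory\n  fetch_threshold: 500\n"
                 "  parameters:\n    path: /tmp/s.jsonl\n")
    cfg = DriverConfig.from_file(str(y))
    assert cfg.driver_name == "memory"
    assert cfg.fetch_threshold == 500
    assert cfg.parameters["path"] == "/tmp/s.jsonl"
    j = tmp_path / "conf.json"
    j.write_text(json.dumps({"driver_name": "memory", "fetch_threshold": 7}))
    assert DriverConfig.from_file(str(j)).fetch_threshold == 7


# -- sessions ----------------------------------------------------------------


def test_disconnect_is_idempotent_and_blocks_operations():
    drv = fresh_driver()
    drv.disconnect()
    drv.disconnect()
    with pytest.raises(NotConnectedError):
        drv.get("nope")


def test_random_session_sequences_match_a_reference_state_machine():
    rng = random.Random(13)
    for _ in range(50):
        drv = MemoryDriver()
        connected = False
        for op in (rng.choice(("connect", "disconnect", "get"))
                   for _ in range(8)):
            if op == "connect":
                drv.connect(DriverConfig())
                connected = True
            elif op == "disconnect":
                drv.disconnect()
                connected = False
            else:
                if connected:
                    with pytest.raises(RecordNotFoundError):
                        drv.get("absent")
                else:
                    with pytest.raises(NotConnectedError):
                        drv.get("absent")


# -- CRUD and versioning -----------------------------------------------------


def test_put_get_round_trip_and_error_kinds():
    drv = fresh_driver()
    rec = simple_record()
    drv.put(rec)
    assert record_equal(drv.get("r1"), rec)
    with pytest.raises(DuplicateRecordError):
        drv.put(rec)
    with pytest.raises(RecordNotFoundError):
        drv.get("missing")
    with pytest.raises(RecordNotFoundError):
        drv.delete("missing")


def test_update_versions_and_rollback_restores_prior_root():
    drv = fresh_driver()
    drv.put(simple_record(value=10.0))
    v2 = drv.update("r1", simple_record(value=20.0).root)
    assert v2 == 2
    env = drv.version_history("r1")
    assert [v["version"] for v in env.versions] == [1, 2]
    assert drv.rollback("r1") == 1
    got = drv.get("r1")
    assert got.root.children[0].children[0].children[0].value == 10.0


def test_random_crud_sequences_match_independent_model():
    rng = random.Random(77)
    for _ in range(30):
        drv = fresh_driver()
        model: dict[str, list[float]] = {}  # id -> version stack of values
        tombstoned: set[str] = set()  # deleted ids keep history, not reusable
        for _ in range(25):
            op = rng.choice(("put", "update", "delete", "rollback", "get"))
            rid = f"r{rng.randint(0, 4)}"
            value = round(rng.uniform(0, 100), 3)
            if op == "put":
                if rid in model or rid in tombstoned:
                    with pytest.raises(DuplicateRecordError):
                        drv.put(simple_record(rid, value))
                else:
                    drv.put(simple_record(rid, value))
                    model[rid] = [value]
            elif op == "update":
                if rid in model:
                    drv.update(rid, simple_record(rid, value).root)
                    model[rid].append(value)
                else:
                    with pytest.raises(RecordNotFoundError):
                        drv.update(rid, simple_record(rid, value).root)
            elif op == "delete":
                if rid in model:
                    drv.delete(rid)
                    del model[rid]
                    tombstoned.add(rid)
                else:
                    with pytest.raises(RecordNotFoundError):
                        drv.delete(rid)
            elif op == "rollback":
                if rid in model and len(model[rid]) > 1:
                    drv.rollback(rid)
                    model[rid].pop()
                elif rid not in model:
                    with pytest.raises(RecordNotFoundError):
                        drv.rollback(rid)
            else:
                if rid in model:
                    got = drv.get(rid)
                    assert got.root.children[0].children[0].children[0].value \
                        == model[rid][-1]
                    assert got.version == len(model[rid])
                else:
                    with pytest.raises(RecordNotFoundError):
                        drv.get(rid)
        assert drv.record_count() == len(model)


# -- encoding ----------------------------------------------------------------


def test_special_characters_in_keys_survive_the_round_trip():
    drv = fresh_driver()
    rec = Record(
        record_id="r1",
        root=archetype("openEHR-EHR-OBSERVATION.odd.v1",
                       attribute("a.b$c%d", leaf("x"))),
    )
    doc = drv.encode(rec)
    assert "a.b$c%d" not in json.dumps(doc)
    assert record_equal(drv.decode(doc), rec)


def test_unicode_key_fuzz_round_trip():
    rng = random.Random(5)
    alphabet = "abcΔΩ中.$%_0"
    for _ in range(100):
        key = "k" + "".join(rng.choice(alphabet) for _ in range(6))
        obj = {key: {"inner" + key: [1, "two", None]}}
        assert decode_keys(encode_keys(obj)) == obj


def test_worked_example_record_encode_decode_round_trip():
    drv = fresh_driver()
    rec = make_worked_example_record()
    assert record_equal(drv.decode(drv.encode(rec)), rec)
    assert record_equal(drv.join_record(drv.split_record(rec)), rec)


# -- query execution ---------------------------------------------------------


def test_empty_matches_yield_count_zero():
    drv = fresh_driver()
    drv.put(simple_record())
    qom = aql.parse("SELECT e FROM EHR e")
    assert drv.execute_query(qom, [], mode="count") == 0


def test_worked_example_count_one_through_the_driver():
    drv = fresh_driver()
    idx = IndexService()
    rec = make_worked_example_record(magnitude=142.0)
    sid = idx.register(extract_structure(rec))
    rec.structure_id = sid
    drv.put(rec)
    qom = aql.parse(WORKED_QUERY)
    matches = idx.lookup_containment(aql.location_of(qom))
    assert drv.execute_query(qom, matches, mode="count") == 1
    rs = drv.execute_query(qom, matches, mode="fetch")
    assert rs.total_count == len(rs.rows) == 1
    assert rs.rows[0][0] == 142.0


def test_stale_structure_ids_in_matches_are_ignored():
    drv = fresh_driver()
    qom = aql.parse("SELECT e FROM EHR e CONTAINS OBSERVATION o")
    from aqlstore.index import StructureMatch
    from aqlstore.records import RelPath
    stale = [StructureMatch("deadbeefdeadbeef", (RelPath(),))]
    assert drv.execute_query(qom, stale, mode="count") == 0


def test_only_latest_active_version_is_queryable():
    drv = fresh_driver()
    idx = IndexService()
    rec = make_worked_example_record(magnitude=142.0)
    sid = idx.register(extract_structure(rec))
    rec.structure_id = sid
    drv.put(rec)
    qom = aql.parse(WORKED_QUERY)
    matches = idx.lookup_containment(aql.location_of(qom))
    # update to a non-matching magnitude: the old version must not answer
    low = make_worked_example_record(magnitude=90.0)
    drv.update(rec.record_id, low.root, structure_id=sid)
    assert drv.execute_query(qom, matches, mode="count") == 0
    drv.rollback(rec.record_id)
    assert drv.execute_query(qom, matches, mode="count") == 1
    drv.delete(rec.record_id)
    assert drv.execute_query(qom, matches, mode="count") == 0


# -- persistence -------------------------------------------------------------


def test_snapshot_round_trip(tmp_path):
    path = str(tmp_path / "store.jsonl")
    drv = MemoryDriver().connect(DriverConfig(parameters={"path": path}))
    drv.put(simple_record("r1", 1.5))
    drv.put(simple_record("r2", 2.5))
    drv.delete("r2")
    drv.disconnect()

    drv2 = MemoryDriver().connect(DriverConfig(parameters={"path": path}))
    assert drv2.record_count() == 1
    assert drv2.get("r1").root.children[0].children[0].children[0].value == 1.5
    with pytest.raises(RecordNotFoundError):
        drv2.get("r2")
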