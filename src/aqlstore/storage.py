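"""Storage drivers: the driver contract and the embedded reference store.

A driver owns the record database: connections, CRUD with versioning,
encoding/decoding between record objects and store documents (with
reversible escaping of characters that are special to document stores,
such as ``.`` and ``$`` in keys), container management, and execution of
parsed queries restricted to the structure matches supplied by the index
service.  Swapping the backing database means registering one new entry
in the driver factory and implementing this contract.

The reference driver is an in-process store with optional JSON-lines
snapshot persistence.  It keeps a secondary index from structure id to
record ids, so a query only ever touches records whose canonical
structure satisfied the containment constraints.  Records are held as
encoded document text and decoded lazily, which keeps memory per record
small and makes the "records examined" accounting explicit.
"""

from __future__ import annotations

import json
import logging
import os
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Any, Callable, Iterable

from . import aql
from .engine import ResultSet
from .index import StructureMatch, class_matches
from .records import (
    ARCHETYPE,
    LEAF,
    DataNode,
    Record,
    from_document,
    iter_archetype_nodes,
    resolve_path,
    to_document,
)

__all__ = [
    "ConnectionError_",
    "DriverConfig",
    "DriverNotInstalledError",
    "DuplicateContainerError",
    "DuplicateRecordError",
    "MemoryDriver",
    "RecordNotFoundError",
    "StorageError",
    "VersionEnvelope",
    "available_drivers",
    "create_driver",
    "decode_keys",
    "encode_keys",
    "register_driver",
    "run_conformance",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# errors


class StorageError(RuntimeError):
    pass


class ConnectionError_(StorageError):
    pass


class NotConnectedError(ConnectionError_):
    pass


class DuplicateRecordError(StorageError):
    pass


class RecordNotFoundError(StorageError):
    pass


class DuplicateContainerError(StorageError):
    pass


class CorruptDocumentError(StorageError):
    pass


class DriverNotInstalledError(StorageError):
    pass


# ---------------------------------------------------------------------------
# configuration


@dataclass
class DriverConfig:
    driver_name: str = "memory"
    parameters: dict[str, str] = field(default_factory=dict)
    fetch_threshold: int = 10_000

    def __post_init__(self) -> None:
        if self.fetch_threshold < 0:
            raise ValueError("fetch_threshold must be >= 0")

    @classmethod
    def from_file(cls, path: str) -> "DriverConfig":
        """Load the ``driver`` block of a YAML or JSON config file."""
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)  # JSON is a YAML subset
        block = data.get("driver", data) if isinstance(data, dict) else {}
        return cls(
            driver_name=str(block.get("driver_name", "memory")),
            parameters={str(k): str(v)
                        for k, v in (block.get("parameters") or {}).items()},
            fetch_threshold=int(block.get("fetch_threshold", 10_000)),
        )


# ---------------------------------------------------------------------------
# key escaping

_ESCAPES = [("%", "%25"), (".", "%2E"), ("$", "%24")]


def _escape_key(key: str) -> str:
    for ch, rep in _ESCAPES:
        key = key.replace(ch, rep)
    return key


def _unescape_key(key: str) -> str:
    for ch, rep in reversed(_ESCAPES):
        key = key.replace(rep, ch)
    return key


def encode_keys(obj: Any) -> Any:
    """Recursively escape store-hostile characters in mapping keys."""
    if isinstance(obj, dict):
        return {_escape_key(k): encode_keys(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [encode_keys(v) for v in obj]
    return obj


def decode_keys(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {_unescape_key(k): decode_keys(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [decode_keys(v) for v in obj]
    return obj


def _now() -> str:
    return datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ")


# ---------------------------------------------------------------------------
# versioning


@dataclass
class VersionEnvelope:
    """All stored versions of one record, oldest first."""

    record_id: str
    versions: list[dict[str, Any]] = field(default_factory=list)
    deleted: bool = False

    @property
    def latest(self) -> int:
        return self.versions[-1]["version"] if self.versions else 0


# ---------------------------------------------------------------------------
# the driver contract


class Driver(ABC):
    """Contract every storage driver must implement."""

    @abstractmethod
    def connect(self, config: DriverConfig) -> "Driver": ...

    @abstractmethod
    def disconnect(self) -> None: ...

    @abstractmethod
    def is_connected(self) -> bool: ...

    @abstractmethod
    def put(self, record: Record, container: str = "ehr") -> None: ...

    @abstractmethod
    def get(self, record_id: str, container: str = "ehr") -> Record: ...

    @abstractmethod
    def update(self, record_id: str, new_root: DataNode,
               structure_id: str = "", container: str = "ehr") -> int: ...

    @abstractmethod
    def delete(self, record_id: str, container: str = "ehr") -> None: ...

    @abstractmethod
    def rollback(self, record_id: str, container: str = "ehr") -> int: ...

    @abstractmethod
    def execute_query(self, qom: aql.QueryObjectModel,
                      matches: list[StructureMatch],
                      mode: str = "count") -> int | ResultSet: ...

    @abstractmethod
    def matching_ids(self, qom: aql.QueryObjectModel,
                     matches: list[StructureMatch]) -> set[str]: ...

    @abstractmethod
    def encode(self, record: Record) -> dict[str, Any]: ...

    @abstractmethod
    def decode(self, document: dict[str, Any]) -> Record: ...

    @abstractmethod
    def create_container(self, name: str) -> None: ...

    @abstractmethod
    def list_containers(self) -> list[str]: ...

    @abstractmethod
    def split_record(self, record: Record) -> list[str]: ...

    @abstractmethod
    def join_record(self, parts: list[str]) -> Record: ...


# ---------------------------------------------------------------------------
# reference driver


class MemoryDriver(Driver):
    """Embedded in-process reference store with versioning and an optional
    single-file JSON-lines snapshot (``parameters["path"]``)."""

    DEFAULT_CONTAINER = "ehr"

    def __init__(self) -> None:
        self._connected = False
        self._config: DriverConfig | None = None
        self._containers: dict[str, dict[str, VersionEnvelope]] = {}
        self._by_structure: dict[str, dict[str, set[str]]] = {}
        self.records_examined = 0  # decoded-record counter (query phase)
        # alternative WHERE scope: each predicate may be satisfied by any
        # innermost instance, instead of one consistent binding per record
        self.any_path_predicates = False

    # -- session ------------------------------------------------------------

    def connect(self, config: DriverConfig) -> "MemoryDriver":
        if self._connected:
            return self
        self._config = config
        self._connected = True
        self.any_path_predicates = (
            str(config.parameters.get("any_path_predicates", "")).lower()
            in ("1", "true", "yes"))
        if not self._containers:
            self._new_container(self.DEFAULT_CONTAINER)
        path = config.parameters.get("path")
        if path and os.path.exists(path):
            self.load_snapshot(path)
        return self

    def disconnect(self) -> None:
        # idempotent
        if self._connected:
            path = (self._config.parameters.get("path")
                    if self._config else None)
            if path:
                self.save_snapshot(path)
        self._connected = False

    def is_connected(self) -> bool:
        return self._connected

    def _check(self) -> None:
        if not self._connected:
            raise NotConnectedError("driver session is not connected")

    # -- containers ---------------------------------------------------------

    def _new_container(self, name: str) -> None:
        self._containers[name] = {}
        self._by_structure[name] = {}

    def create_container(self, name: str) -> None:
        self._check()
        if name in self._containers:
            raise DuplicateContainerError(f"container {name!r} already exists")
        self._new_container(name)

    def list_containers(self) -> list[str]:
        self._check()
        return sorted(self._containers)

    def _container(self, name: str) -> dict[str, VersionEnvelope]:
        self._check()
        try:
            return self._containers[name]
        except KeyError:
            raise StorageError(f"no such container {name!r}") from None

    # -- encoding -----------------------------------------------------------

    def encode(self, record: Record) -> dict[str, Any]:
        return encode_keys(to_document(record))

    def decode(self, document: dict[str, Any]) -> Record:
        try:
            return from_document(decode_keys(document))
        except (ValueError, KeyError, TypeError) as exc:
            raise CorruptDocumentError(f"undecodable store document: {exc}") from exc

    def split_record(self, record: Record) -> list[str]:
        """The reference store keeps whole documents: a single part."""
        return [json.dumps(self.encode(record), ensure_ascii=False,
                           separators=(",", ":"))]

    def join_record(self, parts: list[str]) -> Record:
        if len(parts) != 1:
            raise CorruptDocumentError("reference driver expects one part")
        return self.decode(json.loads(parts[0]))

    # -- CRUD ---------------------------------------------------------------

    def put(self, record: Record, container: str = "ehr") -> None:
        doc = self.encode(record)
        self.put_document(doc, container=container)

    def put_document(self, document: dict[str, Any],
                     container: str = "ehr") -> None:
        """Fast path for pre-encoded documents (corpus ingest)."""
        store = self._container(container)
        rid = str(document.get("record_id", ""))
        if not rid:
            raise StorageError("record_id is required")
        if rid in store:
            raise DuplicateRecordError(f"record {rid!r} already exists")
        version = int(document.get("version", 1))
        sid = str(document.get("structure_id", ""))
        env = VersionEnvelope(record_id=rid)
        env.versions.append({
            "version": version,
            "active": bool(document.get("active", True)),
            "structure_id": sid,
            "created_at": document.get("created_at") or _now(),
            "updated_at": document.get("updated_at") or _now(),
            "text": json.dumps(document, ensure_ascii=False,
                               separators=(",", ":")),
        })
        store[rid] = env
        self._index_add(container, sid, rid)

    def _index_add(self, container: str, sid: str, rid: str) -> None:
        self._by_structure[container].setdefault(sid, set()).add(rid)

    def _index_drop(self, container: str, sid: str, rid: str) -> None:
        bucket = self._by_structure[container].get(sid)
        if bucket:
            bucket.discard(rid)

    def _envelope(self, record_id: str, container: str) -> VersionEnvelope:
        store = self._container(container)
        env = store.get(record_id)
        if env is None or env.deleted:
            raise RecordNotFoundError(f"no record {record_id!r}")
        return env

    def get(self, record_id: str, container: str = "ehr") -> Record:
        env = self._envelope(record_id, container)
        return self.decode(json.loads(env.versions[-1]["text"]))

    def version_history(self, record_id: str,
                        container: str = "ehr") -> VersionEnvelope:
        return self._envelope(record_id, container)

    def update(self, record_id: str, new_root: DataNode,
               structure_id: str = "", container: str = "ehr") -> int:
        env = self._envelope(record_id, container)
        prev = env.versions[-1]
        old = self.decode(json.loads(prev["text"]))
        new = Record(
            record_id=record_id,
            ehr_id=old.ehr_id,
            version=old.version + 1,
            active=True,
            created_at=old.created_at,
            updated_at=_now(),
            structure_id=structure_id or old.structure_id,
            root=new_root,
            extra=old.extra,
        )
        doc = self.encode(new)
        env.versions.append({
            "version": new.version,
            "active": True,
            "structure_id": new.structure_id,
            "created_at": new.created_at,
            "updated_at": new.updated_at,
            "text": json.dumps(doc, ensure_ascii=False, separators=(",", ":")),
        })
        self._index_drop(container, prev["structure_id"], record_id)
        self._index_add(container, new.structure_id, record_id)
        return new.version

    def delete(self, record_id: str, container: str = "ehr") -> None:
        env = self._envelope(record_id, container)
        env.deleted = True  # history retained, hidden from reads and queries
        self._index_drop(container, env.versions[-1]["structure_id"], record_id)

    def rollback(self, record_id: str, container: str = "ehr") -> int:
        """Discard the latest version, reinstating the previous one."""
        env = self._envelope(record_id, container)
        if len(env.versions) < 2:
            raise StorageError(f"record {record_id!r} has no previous version")
        dropped = env.versions.pop()
        self._index_drop(container, dropped["structure_id"], record_id)
        self._index_add(container, env.versions[-1]["structure_id"], record_id)
        return env.versions[-1]["version"]

    def record_count(self, container: str = "ehr") -> int:
        return sum(1 for e in self._container(container).values() if not e.deleted)

    # -- query execution ----------------------------------------------------

    def _candidates(self, matches: list[StructureMatch],
                    container: str) -> list[tuple[str, StructureMatch]]:
        by_struct = self._by_structure[container]
        out: list[tuple[str, StructureMatch]] = []
        for m in matches:
            ids = by_struct.get(m.structure_id)
            if ids is None:
                logger.debug("stale structure id in matches: %s", m.structure_id)
                continue
            out.extend((rid, m) for rid in ids)
        out.sort(key=lambda t: t[0])
        return out

    def _decoded_root(self, rid: str, container: str) -> DataNode:
        env = self._envelope(rid, container)
        self.records_examined += 1
        return from_document(decode_keys(json.loads(env.versions[-1]["text"]))).root

    def execute_query(self, qom: aql.QueryObjectModel,
                      matches: list[StructureMatch],
                      mode: str = "count",
                      container: str = "ehr") -> int | ResultSet:
        self._check()
        candidates = self._candidates(matches, container)
        if mode == "count":
            if qom.condition is None:
                # structure ids certify containment: no record access needed
                return len(candidates)
            n = 0
            for rid, m in candidates:
                root = self._decoded_root(rid, container)
                if _record_hits(root, qom, m, rid,
                                any_path=self.any_path_predicates):
                    n += 1
            return n
        if mode != "fetch":
            raise ValueError(f"unknown mode {mode!r}")
        columns = tuple(item.column_name for item in qom.selection.items)
        rows: list[tuple[Any, ...]] = []
        for rid, m in candidates:
            root = self._decoded_root(rid, container)
            rows.extend(_record_rows(root, qom, m, rid))
        return ResultSet(columns=columns, rows=rows, total_count=len(rows))

    def matching_ids(self, qom: aql.QueryObjectModel,
                     matches: list[StructureMatch]) -> set[str]:
        candidates = self._candidates(matches, "ehr")
        if qom.condition is None:
            return {rid for rid, _ in candidates}
        out = set()
        for rid, m in candidates:
            root = self._decoded_root(rid, "ehr")
            if _record_hits(root, qom, m, rid,
                            any_path=self.any_path_predicates):
                out.add(rid)
        return out

    # -- persistence --------------------------------------------------------

    def save_snapshot(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name in sorted(self._containers):
                for rid in sorted(self._containers[name]):
                    env = self._containers[name][rid]
                    fh.write(json.dumps({
                        "container": name,
                        "record_id": rid,
                        "deleted": env.deleted,
                        "versions": env.versions,
                    }, ensure_ascii=False, separators=(",", ":")) + "\n")

    def load_snapshot(self, path: str) -> None:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                obj = json.loads(line)
                name = obj["container"]
                if name not in self._containers:
                    self._new_container(name)
                env = VersionEnvelope(record_id=obj["record_id"],
                                      versions=obj["versions"],
                                      deleted=obj["deleted"])
                self._containers[name][env.record_id] = env
                if not env.deleted:
                    self._index_add(name, env.versions[-1]["structure_id"],
                                    env.record_id)


# ---------------------------------------------------------------------------
# shared condition / projection evaluation (driver side)


def _instances(root: DataNode, qom: aql.QueryObjectModel,
               match: StructureMatch) -> list[DataNode]:
    """Innermost-archetype instances addressed by the match paths."""
    if not qom.location.chain:
        return [root]
    last_pattern = qom.location.chain[-1].class_pattern
    seen: list[DataNode] = []
    ids = set()
    for p in match.paths:
        for n in resolve_path(root, p):
            if (n.kind == ARCHETYPE
                    and class_matches(last_pattern, n.archetype_class or "")
                    and id(n) not in ids):
                ids.add(id(n))
                seen.append(n)
    return seen


def _nodes_for(root: DataNode, inst: DataNode, qom: aql.QueryObjectModel,
               variable: str, path) -> list[DataNode]:
    chain = qom.location.chain
    if chain and variable == chain[-1].variable:
        return resolve_path(inst, path)
    if variable == qom.location.ehr_variable:
        return resolve_path(root, path)
    # outer containment variable: any archetype of its class
    for spec in chain[:-1]:
        if spec.variable == variable:
            out: list[DataNode] = []
            for n in iter_archetype_nodes(root):
                if class_matches(spec.class_pattern, n.archetype_class or ""):
                    out.extend(resolve_path(n, path))
            return out
    return []


def _leaf_values(nodes: list[DataNode]) -> list[Any]:
    return [n.value for n in nodes if n.kind == LEAF]


def _compare(value: Any, op: str, literal: Any) -> bool:
    numeric = (isinstance(value, (int, float)) and not isinstance(value, bool)
               and isinstance(literal, (int, float))
               and not isinstance(literal, bool))
    if op == "=":
        return value == literal
    if op == "!=":
        return value != literal
    if not (numeric or (isinstance(value, str) and isinstance(literal, str))):
        return False
    if op == ">":
        return value > literal
    if op == ">=":
        return value >= literal
    if op == "<":
        return value < literal
    if op == "<=":
        return value <= literal
    return False


def _eval_predicate(pred: aql.Predicate, root: DataNode,
                    inst: DataNode | list[DataNode],
                    qom: aql.QueryObjectModel) -> bool:
    # any-path scope passes all instances: the predicate may be satisfied
    # at any of them, independently of the other predicates
    insts = inst if isinstance(inst, list) else [inst]
    nodes: list[DataNode] = []
    for i in insts:
        nodes.extend(_nodes_for(root, i, qom, pred.variable, pred.path))
    if pred.operator == "exists":
        return bool(nodes)
    values = _leaf_values(nodes)
    if pred.operator == "matches":
        return any(v in pred.values for v in values)
    return any(_compare(v, pred.operator, pred.literal) for v in values)


def _eval_condition(cond, root: DataNode, inst: DataNode,
                    qom: aql.QueryObjectModel) -> bool:
    if isinstance(cond, aql.Predicate):
        return _eval_predicate(cond, root, inst, qom)
    if isinstance(cond, aql.NotNode):
        return not _eval_condition(cond.child, root, inst, qom)
    if isinstance(cond, aql.AndNode):
        return all(_eval_condition(c, root, inst, qom) for c in cond.children)
    if isinstance(cond, aql.OrNode):
        return any(_eval_condition(c, root, inst, qom) for c in cond.children)
    raise TypeError(f"unknown condition node {cond!r}")


def _record_hits(root: DataNode, qom: aql.QueryObjectModel,
                 match: StructureMatch, record_id: str,
                 any_path: bool = False) -> bool:
    """True when some single innermost instance satisfies the condition
    (default), or — with ``any_path`` — when each predicate is satisfied
    by some instance, not necessarily the same one."""
    instances = _instances(root, qom, match)
    if qom.condition is None:
        return bool(instances)
    if any_path:
        return bool(instances) and _eval_condition(
            qom.condition, root, instances, qom)
    return any(_eval_condition(qom.condition, root, inst, qom)
               for inst in instances)


def _cell_value(nodes: list[DataNode], variable: str, path,
                qom: aql.QueryObjectModel, record_id: str) -> Any:
    if variable == qom.location.ehr_variable and not path:
        return record_id
    for n in nodes:
        if n.kind == LEAF:
            return n.value
        if n.kind == ARCHETYPE:
            return n.archetype_class
    return None


def _record_rows(root: DataNode, qom: aql.QueryObjectModel,
                 match: StructureMatch, record_id: str) -> list[tuple[Any, ...]]:
    """One row per innermost-archetype instance that satisfies the
    condition; a missing selection path yields an explicit null cell."""
    rows: list[tuple[Any, ...]] = []
    for inst in _instances(root, qom, match):
        if qom.condition is not None and not _eval_condition(
                qom.condition, root, inst, qom):
            continue
        cells = []
        for item in qom.selection.items:
            nodes = _nodes_for(root, inst, qom, item.variable, item.path)
            cells.append(_cell_value(nodes, item.variable, item.path, qom,
                                     record_id))
        rows.append(tuple(cells))
    return rows


# ---------------------------------------------------------------------------
# factory


_DRIVERS: dict[str, Callable[[], Driver]] = {}


def register_driver(name: str, constructor: Callable[[], Driver]) -> None:
    _DRIVERS[name] = constructor


def available_drivers() -> list[str]:
    return sorted(_DRIVERS) + ["mongodb", "elasticsearch"]


def create_driver(config: DriverConfig) -> Driver:
    """Build and connect a driver session for the given configuration."""
    name = config.driver_name
    if name in ("mongodb", "elasticsearch"):
        raise DriverNotInstalledError(
            f"driver {name!r} is reserved but not installed; "
            "install the optional extra and register it")
    try:
        ctor = _DRIVERS[name]
    except KeyError:
        raise StorageError(f"unknown driver {name!r}") from None
    return ctor().connect(config)


register_driver("memory", MemoryDriver)


# ---------------------------------------------------------------------------
# driver conformance suite


def run_conformance(make_driver: Callable[[], Driver],
                    config: DriverConfig | None = None) -> list[str]:
    """Exercise the driver contract; returns a list of failure messages
    (empty means the driver conforms).  Any new driver must pass this."""
    from .records import archetype, attribute, leaf, record_equal

    cfg = config or DriverConfig()
    failures: list[str] = []

    def check(ok: bool, message: str) -> None:
        if not ok:
            failures.append(message)

    drv = make_driver().connect(cfg)
    check(drv.is_connected(), "connect() must yield a connected session")

    rec = Record(
        record_id="conf-1",
        ehr_id="e-1",
        root=archetype(
            "openEHR-EHR-COMPOSITION.conformance.v1",
            attribute("data", attribute("magnitude", leaf(42))),
        ),
        structure_id="s-1",
    )
    drv.put(rec)
    got = drv.get("conf-1")
    check(record_equal(got, rec) or got.record_id == "conf-1",
          "get after put must return the stored record")
    try:
        drv.put(rec)
        check(False, "duplicate put must raise DuplicateRecordError")
    except DuplicateRecordError:
        pass

    new_root = archetype(
        "openEHR-EHR-COMPOSITION.conformance.v1",
        attribute("data", attribute("magnitude", leaf(43))),
    )
    v2 = drv.update("conf-1", new_root, structure_id="s-1")
    check(v2 == 2, "update must produce version 2")
    back = drv.rollback("conf-1")
    check(back == 1, "rollback must reinstate version 1")
    check(drv.get("conf-1").root.children[0].children[0].children[0].value == 42,
          "rollback must restore the prior root")

    try:
        drv.get("missing")
        check(False, "get of a missing id must raise RecordNotFoundError")
    except RecordNotFoundError:
        pass

    drv.delete("conf-1")
    try:
        drv.get("conf-1")
        check(False, "deleted records must be hidden")
    except RecordNotFoundError:
        pass

    odd = Record(
        record_id="conf-2",
        root=archetype(
            "openEHR-EHR-OBSERVATION.conformance.v1",
            attribute("weird.key$name", leaf("x")),
        ),
    )
    doc = drv.encode(odd)
    check("weird.key$name" not in json.dumps(doc),
          "encode must escape special characters in keys")
    check(record_equal(drv.decode(doc), odd),
          "decode(encode(r)) must be the identity")

    check(record_equal(drv.join_record(drv.split_record(odd)), odd),
          "join(split(r)) must be the identity")

    drv.create_container("aux")
    check("aux" in drv.list_containers(), "created container must be listed")
    try:
        drv.create_container("aux")
        check(False, "duplicate container must raise")
    except DuplicateContainerError:
        pass

    drv.disconnect()
    drv.disconnect()  # double disconnect is a no-op
    try:
        drv.get("conf-2")
        check(False, "operations on a disconnected session must fail")
    except (NotConnectedError, RecordNotFoundError):
        pass
    return failures
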