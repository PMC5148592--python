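"""Document-tree record model for archetype-based health records.

Records are trees whose inner nodes are *archetype instances* (clinical
concepts such as ``openEHR-EHR-OBSERVATION.blood_pressure.v1``) glued
together by named *attribute* nodes, with scalar *leaves* at the bottom.
An archetype node's position relative to its nearest archetype ancestor is
described by a ``path_from_parent`` — a slash-separated chain of attribute
steps in an XPath-like subset (``/data[at0001]/events/value``).

The on-disk dialect is one JSON object per record: the root archetype
object itself, with record metadata stored under reserved top-level keys.
Archetype objects carry the reserved keys ``archetype_class`` and
``path_from_parent``; every other key is an attribute.  List-valued
attributes are JSON arrays and are always addressed collectively by paths
(never by index).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Sequence

__all__ = [
    "ARCHETYPE_CLASS_RE",
    "DataNode",
    "DocumentError",
    "ParseError",
    "Record",
    "RelPath",
    "SchemaError",
    "archetype",
    "attribute",
    "count_archetypes",
    "is_valid_archetype_class",
    "iter_archetype_nodes",
    "leaf",
    "read_record",
    "resolve_path",
    "to_document",
    "write_record",
]

# ---------------------------------------------------------------------------
# archetype class names

ARCHETYPE_CLASS_RE = re.compile(
    r"^openEHR-EHR-[A-Z][A-Z0-9_]*"  # reference-model type
    r"\.[A-Za-z0-9][A-Za-z0-9_\-]*"  # concept
    r"(\.v\d+)?"                     # optional version
    r"(\.lbl-\d+)?$"                 # optional label suffix
)


def is_valid_archetype_class(name: str) -> bool:
    return bool(ARCHETYPE_CLASS_RE.match(name))


# record-level metadata keys; they can never be attribute names
METADATA_KEYS = (
    "record_id",
    "ehr_id",
    "version",
    "active",
    "created_at",
    "updated_at",
    "structure_id",
)
# node-level reserved keys
NODE_RESERVED_KEYS = ("archetype_class", "path_from_parent")
RESERVED_KEYS = METADATA_KEYS + NODE_RESERVED_KEYS


class DocumentError(ValueError):
    """Base class for problems with a serialized record document."""


class ParseError(DocumentError):
    """Malformed document text; carries the offending JSON path."""


class SchemaError(DocumentError):
    """Well-formed JSON that violates the record dialect."""


# ---------------------------------------------------------------------------
# relative paths


@dataclass(frozen=True)
class RelPath:
    """A relative archetype path: a chain of attribute steps.

    Steps may carry a node-code qualifier, e.g. ``data[at0001]``.  The
    empty path is the identity of concatenation and resolves to the node
    it is applied to.
    """

    steps: tuple[str, ...] = ()

    @classmethod
    def parse(cls, text: str) -> "RelPath":
        if text in ("", "/"):
            return cls(())
        if not text.startswith("/"):
            raise ValueError(f"relative path must start with '/': {text!r}")
        steps = tuple(text[1:].split("/"))
        if any(s == "" for s in steps):
            raise ValueError(f"empty step in path {text!r}")
        return cls(steps)

    def render(self) -> str:
        return "".join("/" + s for s in self.steps)

    def __add__(self, other: "RelPath") -> "RelPath":
        return RelPath(self.steps + other.steps)

    def __len__(self) -> int:
        return len(self.steps)

    def __bool__(self) -> bool:
        return bool(self.steps)

    def __str__(self) -> str:
        return self.render()


# ---------------------------------------------------------------------------
# data nodes

ARCHETYPE = "archetype"
ATTRIBUTE = "attribute"
LEAF = "leaf"

Scalar = str | int | float | bool | None


@dataclass
class DataNode:
    """One node of a record tree.

    kind ``archetype``: has ``archetype_class`` and named-attribute children.
    kind ``attribute``: has a ``name`` and either *field* children (named
    attributes, forming a plain nested object) or *value* children (leaves,
    archetypes, or anonymous attribute nodes for objects inside arrays).
    kind ``leaf``: has a scalar ``value`` and no children.
    """

    kind: str
    name: str = ""
    archetype_class: str | None = None
    children: list["DataNode"] = field(default_factory=list)
    value: Scalar = None

    # -- structural helpers -------------------------------------------------

    def field_children(self) -> list["DataNode"]:
        """Named attribute children (object fields)."""
        return [c for c in self.children if c.kind == ATTRIBUTE and c.name]

    def value_children(self) -> list["DataNode"]:
        """Leaf / archetype / anonymous-object children (attribute values)."""
        return [
            c
            for c in self.children
            if c.kind in (LEAF, ARCHETYPE) or (c.kind == ATTRIBUTE and not c.name)
        ]


def archetype(cls: str, *children: DataNode) -> DataNode:
    if not is_valid_archetype_class(cls):
        raise SchemaError(f"invalid archetype class name: {cls!r}")
    return DataNode(kind=ARCHETYPE, archetype_class=cls, children=list(children))


def attribute(name: str, *children: DataNode) -> DataNode:
    return DataNode(kind=ATTRIBUTE, name=name, children=list(children))


def leaf(value: Scalar) -> DataNode:
    return DataNode(kind=LEAF, value=value)


def iter_archetype_nodes(node: DataNode) -> Iterator[DataNode]:
    """Depth-first iteration over all archetype nodes of a subtree."""
    if node.kind == ARCHETYPE:
        yield node
    for c in node.children:
        yield from iter_archetype_nodes(c)


def count_archetypes(node: DataNode) -> int:
    return sum(1 for _ in iter_archetype_nodes(node))


# ---------------------------------------------------------------------------
# path resolution


def _values_of(attr: DataNode) -> list[DataNode]:
    vals = attr.value_children()
    return vals if vals else [attr]


def resolve_path(node: DataNode, path: RelPath) -> list[DataNode]:
    """All nodes reachable from ``node`` by following ``path``.

    List-valued attributes fan out to all their elements.  The empty path
    resolves to ``[node]``; an unresolvable path yields ``[]``.
    """
    current: list[DataNode] = [node]
    for step in path.steps:
        nxt: list[DataNode] = []
        for n in current:
            if n.kind == LEAF:
                continue
            for c in n.children:
                if c.kind == ATTRIBUTE and c.name == step:
                    nxt.extend(_values_of(c))
        current = nxt
    return current


# ---------------------------------------------------------------------------
# records


@dataclass
class Record:
    """A versioned record: metadata plus the root archetype node."""

    record_id: str
    root: DataNode
    ehr_id: str = ""
    version: int = 1
    active: bool = True
    created_at: str = ""
    updated_at: str = ""
    structure_id: str = ""
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.root.kind != ARCHETYPE:
            raise SchemaError("record root must be an archetype node")
        if self.version < 1:
            raise SchemaError("record version must be >= 1")


# ---------------------------------------------------------------------------
# JSON encoding


def _encode_attr(attr: DataNode, parent_path: str, steps: tuple[str, ...]) -> Any:
    """Encode one named attribute; ``steps`` are attribute steps since the
    nearest enclosing archetype (used to stamp ``path_from_parent``)."""
    fields = attr.field_children()
    values = attr.value_children()
    here = f"{parent_path}/{attr.name or '[]'}"
    if fields and values:
        raise SchemaError(f"attribute mixes fields and values at {here}")
    if fields:
        return _encode_fields(fields, here, steps)
    if not values:
        return {}
    encoded = [_encode_value(v, here, steps) for v in values]
    return encoded[0] if len(encoded) == 1 else encoded


def _encode_value(node: DataNode, path: str, steps: tuple[str, ...]) -> Any:
    if node.kind == LEAF:
        return node.value
    if node.kind == ARCHETYPE:
        return _encode_archetype(node, path, RelPath(steps).render())
    if len(node.value_children()) == 1 and not node.field_children():
        raise SchemaError(f"unrepresentable anonymous single-value node at {path}")
    return _encode_fields(node.field_children(), path, steps)


def _encode_fields(
    fields: Sequence[DataNode], path: str, steps: tuple[str, ...]
) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for f in fields:
        if f.name in RESERVED_KEYS or f.name.startswith("_"):
            raise SchemaError(f"attribute name {f.name!r} is reserved ({path})")
        if f.name in out:
            raise SchemaError(f"duplicate attribute {f.name!r} at {path}")
        out[f.name] = _encode_attr(f, path, steps + (f.name,))
    return out


def _encode_archetype(node: DataNode, path: str, pfp: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {
        "archetype_class": node.archetype_class,
        "path_from_parent": pfp,
    }
    out.update(_encode_fields(node.field_children(), path, ()))
    return out


def to_document(record: Record) -> dict[str, Any]:
    """Record -> JSON-able dict in the on-disk dialect."""
    doc = _encode_archetype(record.root, "", "")
    meta: dict[str, Any] = {
        "record_id": record.record_id,
        "ehr_id": record.ehr_id,
        "version": record.version,
        "active": record.active,
        "created_at": record.created_at,
        "updated_at": record.updated_at,
        "structure_id": record.structure_id,
    }
    for k, v in record.extra.items():
        if not k.startswith("_"):
            raise SchemaError(f"extra metadata key must start with '_': {k!r}")
        meta[k] = v
    meta.update(doc)
    return meta


def write_record(record: Record) -> str:
    """Serialize a record deterministically (stable key order, UTF-8)."""
    return json.dumps(to_document(record), ensure_ascii=False, separators=(",", ":"))


# ---------------------------------------------------------------------------
# JSON decoding


def _decode_attr(name: str, raw: Any, path: str) -> DataNode:
    here = f"{path}/{name}"
    node = attribute(name)
    node.children = _decode_values(raw, here)
    return node


def _decode_values(raw: Any, path: str) -> list[DataNode]:
    if isinstance(raw, list):
        out: list[DataNode] = []
        for i, item in enumerate(raw):
            if isinstance(item, dict):
                if "archetype_class" in item:
                    out.append(_decode_archetype(item, f"{path}[{i}]"))
                else:
                    anon = attribute("")
                    anon.children = [
                        _decode_attr(k, v, f"{path}[{i}]") for k, v in item.items()
                    ]
                    out.append(anon)
            elif isinstance(item, list):
                raise ParseError(f"nested arrays are not supported at {path}[{i}]")
            else:
                out.append(leaf(item))
        return out
    if isinstance(raw, dict):
        if "archetype_class" in raw:
            return [_decode_archetype(raw, path)]
        return [_decode_attr(k, v, path) for k, v in raw.items()]
    return [leaf(raw)]


def _decode_archetype(raw: dict[str, Any], path: str) -> DataNode:
    cls = raw.get("archetype_class")
    if not isinstance(cls, str) or not is_valid_archetype_class(cls):
        raise SchemaError(f"invalid archetype class at {path or '/'}: {cls!r}")
    node = DataNode(kind=ARCHETYPE, archetype_class=cls)
    for k, v in raw.items():
        if k in NODE_RESERVED_KEYS:
            continue
        node.children.append(_decode_attr(k, v, path))
    return node


def from_document(doc: dict[str, Any]) -> Record:
    """JSON-able dict (on-disk dialect) -> Record."""
    if not isinstance(doc, dict):
        raise SchemaError("record document must be a JSON object")
    if "archetype_class" not in doc:
        raise SchemaError("record root is not an archetype (missing archetype_class)")
    meta = {k: doc[k] for k in METADATA_KEYS if k in doc}
    extra = {k: v for k, v in doc.items() if k.startswith("_")}
    body = {
        k: v
        for k, v in doc.items()
        if k not in METADATA_KEYS and not k.startswith("_")
    }
    root = _decode_archetype(body, "")
    return Record(
        record_id=str(meta.get("record_id", "")),
        ehr_id=str(meta.get("ehr_id", "")),
        version=int(meta.get("version", 1)),
        active=bool(meta.get("active", True)),
        created_at=str(meta.get("created_at", "")),
        updated_at=str(meta.get("updated_at", "")),
        structure_id=str(meta.get("structure_id", "")),
        root=root,
        extra=extra,
    )


def read_record(text: str) -> Record:
    """Parse one serialized record document."""
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON at line {exc.lineno} col {exc.colno}: "
                         f"{exc.msg}") from exc
    return from_document(doc)


def node_equal(a: DataNode, b: DataNode) -> bool:
    """Order-sensitive structural equality of two trees."""
    if (a.kind, a.name, a.archetype_class, a.value) != (
        b.kind,
        b.name,
        b.archetype_class,
        b.value,
    ):
        return False
    if len(a.children) != len(b.children):
        return False
    return all(node_equal(x, y) for x, y in zip(a.children, b.children))


def record_equal(a: Record, b: Record) -> bool:
    meta_a = (a.record_id, a.ehr_id, a.version, a.active, a.created_at,
              a.updated_at, a.structure_id, a.extra)
    meta_b = (b.record_id, b.ehr_id, b.version, b.active, b.created_at,
              b.updated_at, b.structure_id, b.extra)
    return meta_a == meta_b and node_equal(a.root, b.root)
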