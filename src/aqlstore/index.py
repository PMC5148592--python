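"""Structure index service.

Every record's tree of archetype instances is reduced to a value-free
*canonical skeleton*: one node per archetype instance, each carrying its
class name and its path relative to the nearest containing archetype.
Sibling order is normalized away, so records that differ only by
permutations of list items share one skeleton.  Each distinct skeleton
gets a content-derived identifier and is registered once.

At query time a containment chain (the CONTAINS part of an AQL query) is
resolved against the registry alone: for every registered structure that
contains archetypes a1 ... an with class(ai) matching pattern i and each
a(i+1) a descendant of ai (any number of archetypes in between, including
none), the service reports the structure id together with every absolute
path to the innermost matched archetype — each path being the
concatenation of ``path_from_parent`` along the root-to-innermost spine.
The lookup never touches the record store, so its cost depends only on
the number of distinct structures.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Any, Iterable, Iterator

from .records import (
    ARCHETYPE,
    ATTRIBUTE,
    LEAF,
    DataNode,
    Record,
    RelPath,
    NODE_RESERVED_KEYS,
)

__all__ = [
    "ContainmentChain",
    "IndexService",
    "StructureDescriptor",
    "StructureMatch",
    "StructureNode",
    "canonical_id",
    "canonicalize",
    "class_matches",
    "extract_structure",
    "structure_of_document",
]

STRUCTURE_ID_HEX_CHARS = 16


# ---------------------------------------------------------------------------
# structure skeletons


@dataclass(frozen=True)
class StructureNode:
    """Value-free skeleton node: class, relative path, nested archetypes."""

    archetype_class: str
    path_from_parent: str  # rendered RelPath
    children: tuple["StructureNode", ...] = ()

    def iter_nodes(self) -> Iterator["StructureNode"]:
        yield self
        for c in self.children:
            yield from c.iter_nodes()


@dataclass(frozen=True)
class StructureDescriptor:
    root: StructureNode
    structure_id: str

    @property
    def node_count(self) -> int:
        return sum(1 for _ in self.root.iter_nodes())


def _canon_key(node: StructureNode) -> tuple:
    return (node.archetype_class, node.path_from_parent, _serialize(node))


def canonicalize(node: StructureNode) -> StructureNode:
    """Recursively sort children into the canonical total order."""
    children = tuple(sorted((canonicalize(c) for c in node.children), key=_canon_key))
    return StructureNode(node.archetype_class, node.path_from_parent, children)


def _serialize(node: StructureNode) -> str:
    return json.dumps(_to_jsonable(node), separators=(",", ":"), sort_keys=True)


def _to_jsonable(node: StructureNode) -> list:
    return [
        node.archetype_class,
        node.path_from_parent,
        [_to_jsonable(c) for c in node.children],
    ]


def _from_jsonable(data: list) -> StructureNode:
    cls, pfp, children = data
    return StructureNode(cls, pfp, tuple(_from_jsonable(c) for c in children))


def canonical_id(root_or_descriptor: StructureNode | StructureDescriptor) -> str:
    """Content hash of the canonical serialization (hex, 16 chars).

    Deterministic across processes; invariant under sibling permutations
    of the source record.
    """
    root = (
        root_or_descriptor.root
        if isinstance(root_or_descriptor, StructureDescriptor)
        else root_or_descriptor
    )
    canon = canonicalize(root)
    digest = hashlib.sha256(_serialize(canon).encode("utf-8")).hexdigest()
    return digest[:STRUCTURE_ID_HEX_CHARS]


def describe(root: StructureNode) -> StructureDescriptor:
    canon = canonicalize(root)
    return StructureDescriptor(root=canon, structure_id=canonical_id(canon))


# ---------------------------------------------------------------------------
# structure extraction


def extract_structure(record_or_node: Record | DataNode) -> StructureDescriptor:
    """Prune a record to its canonical archetype skeleton.

    One StructureNode per archetype node, with ``path_from_parent``
    relative to the nearest archetype ancestor; leaves and values are
    discarded.
    """
    node = (
        record_or_node.root if isinstance(record_or_node, Record) else record_or_node
    )
    if node.kind != ARCHETYPE:
        raise ValueError("structure extraction starts at an archetype node")
    return describe(_extract(node, ""))


def _extract(arch: DataNode, pfp: str) -> StructureNode:
    children: list[StructureNode] = []

    def walk(container: DataNode, steps: tuple[str, ...]) -> None:
        for c in container.children:
            if c.kind != ATTRIBUTE or not c.name:
                continue
            new = steps + (c.name,)
            vals = c.value_children() or [c]
            for v in vals:
                if v is c:
                    walk(c, new)
                elif v.kind == ARCHETYPE:
                    children.append(_extract(v, RelPath(new).render()))
                elif v.kind == ATTRIBUTE:  # anonymous object in an array
                    walk(v, new)
                # leaves carry no structure

    walk(arch, ())
    return StructureNode(arch.archetype_class or "", pfp, tuple(children))


def structure_of_document(doc: dict[str, Any]) -> StructureDescriptor:
    """Fast-path extraction straight from a decoded JSON document."""
    if "archetype_class" not in doc:
        raise ValueError("document root is not an archetype object")
    return describe(_extract_dict(doc, ""))


_SKIP_KEYS = set(NODE_RESERVED_KEYS) | {
    "record_id",
    "ehr_id",
    "version",
    "active",
    "created_at",
    "updated_at",
    "structure_id",
}


def _extract_dict(obj: dict[str, Any], pfp: str) -> StructureNode:
    children: list[StructureNode] = []

    def walk(d: dict[str, Any], steps: tuple[str, ...]) -> None:
        for k, v in d.items():
            if k in _SKIP_KEYS or k.startswith("_"):
                continue
            new = steps + (k,)
            _walk_value(v, new)

    def _walk_value(v: Any, steps: tuple[str, ...]) -> None:
        if isinstance(v, dict):
            if "archetype_class" in v:
                children.append(_extract_dict(v, RelPath(steps).render()))
            else:
                walk(v, steps)
        elif isinstance(v, list):
            for item in v:
                _walk_value(item, steps)
        # scalars carry no structure

    walk(obj, ())
    return StructureNode(str(obj["archetype_class"]), pfp, tuple(children))


# ---------------------------------------------------------------------------
# containment chains


@dataclass(frozen=True)
class ContainmentChain:
    """Ordered class patterns, outermost first; one per CONTAINS clause."""

    patterns: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.patterns)

    def __bool__(self) -> bool:
        return bool(self.patterns)


_VERSIONED_SUFFIX = (".v", ".lbl-")


def _has_version(pattern: str) -> bool:
    parts = pattern.split(".")
    return any(p.startswith("v") and p[1:].isdigit() for p in parts)


def class_matches(pattern: str, cls: str) -> bool:
    """``*`` matches anything; an exact id matches itself; a pattern
    without a version component matches any version of that concept."""
    if pattern == "*":
        return True
    if pattern == cls:
        return True
    if not _has_version(pattern):
        return cls.startswith(pattern + ".")
    return False


@dataclass(frozen=True)
class StructureMatch:
    """A structure satisfying a chain, with every absolute path (from the
    record root) to a distinct innermost-chain archetype."""

    structure_id: str
    paths: tuple[RelPath, ...]


def _chain_paths(root: StructureNode, patterns: tuple[str, ...]) -> list[RelPath]:
    """Absolute paths to every node that terminates the pattern chain.

    The chain may be rooted anywhere in the structure; outer patterns
    must match a subsequence of the node's archetype ancestors in order.
    """
    outer, last = patterns[:-1], patterns[-1]
    found: list[RelPath] = []

    def embeds(ancestors: list[str]) -> bool:
        i = 0
        for cls in ancestors:
            if i < len(outer) and class_matches(outer[i], cls):
                i += 1
        return i >= len(outer)

    def dfs(node: StructureNode, anc: list[str], abs_steps: tuple[str, ...]) -> None:
        here = abs_steps + RelPath.parse(node.path_from_parent).steps
        if class_matches(last, node.archetype_class) and embeds(anc):
            found.append(RelPath(here))
        anc.append(node.archetype_class)
        for c in node.children:
            dfs(c, anc, here)
        anc.pop()

    dfs(root, [], ())
    return found


# ---------------------------------------------------------------------------
# the registry


class RegistryError(RuntimeError):
    pass


class IndexService:
    """In-process structure registry with containment lookup."""

    def __init__(self) -> None:
        self._structures: dict[str, StructureDescriptor] = {}
        self._record_counts: dict[str, int] = {}

    def __len__(self) -> int:
        return len(self._structures)

    def __contains__(self, structure_id: str) -> bool:
        return structure_id in self._structures

    # -- registration -------------------------------------------------------

    def register(self, descriptor: StructureDescriptor) -> str:
        """Idempotently add a canonical structure; returns its id."""
        sid = descriptor.structure_id
        if sid not in self._structures:
            self._structures[sid] = describe(descriptor.root)
            self._record_counts[sid] = 0
        return sid

    def register_record(self, record_or_doc: Record | dict[str, Any]) -> str:
        """Extract, register, and count one ingested record's structure."""
        if isinstance(record_or_doc, dict):
            desc = structure_of_document(record_or_doc)
        else:
            desc = extract_structure(record_or_doc)
        sid = self.register(desc)
        self._record_counts[sid] += 1
        return sid

    def get(self, structure_id: str) -> StructureDescriptor:
        try:
            return self._structures[structure_id]
        except KeyError:
            raise RegistryError(f"unknown structure id {structure_id!r}") from None

    # -- lookup -------------------------------------------------------------

    def lookup_containment(self, chain: ContainmentChain) -> list[StructureMatch]:
        """All registered structures matching the chain, with their
        deduplicated, lexicographically ordered innermost paths."""
        if not chain:
            raise ValueError("containment chain must be non-empty")
        matches: list[StructureMatch] = []
        for sid in sorted(self._structures):
            desc = self._structures[sid]
            paths = _chain_paths(desc.root, chain.patterns)
            if paths:
                uniq = sorted(set(paths), key=RelPath.render)
                matches.append(StructureMatch(sid, tuple(uniq)))
        return matches

    def all_structures_match(self) -> list[StructureMatch]:
        """Fallback for queries with no CONTAINS: every structure, rooted
        at its record root."""
        return [StructureMatch(sid, (RelPath(),)) for sid in sorted(self._structures)]

    # -- stats / persistence ------------------------------------------------

    def index_stats(self) -> dict[str, Any]:
        depth_hist: dict[int, int] = {}
        for desc in self._structures.values():
            d = _archetype_depth(desc.root)
            depth_hist[d] = depth_hist.get(d, 0) + 1
        return {
            "structure_count": len(self._structures),
            "record_counts": dict(self._record_counts),
            "records_total": sum(self._record_counts.values()),
            "archetype_depth_histogram": dict(sorted(depth_hist.items())),
        }

    def export_jsonl(self) -> Iterator[str]:
        for sid in sorted(self._structures):
            desc = self._structures[sid]
            yield json.dumps(
                {"structure_id": sid, "structure": _to_jsonable(desc.root)},
                separators=(",", ":"),
            )

    def import_jsonl(self, lines: Iterable[str]) -> int:
        n = 0
        for line in lines:
            line = line.strip()
            if not line:
                continue
            obj = json.loads(line)
            root = _from_jsonable(obj["structure"])
            self.register(describe(root))
            n += 1
        return n


def _archetype_depth(node: StructureNode) -> int:
    if not node.children:
        return 1
    return 1 + max(_archetype_depth(c) for c in node.children)
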