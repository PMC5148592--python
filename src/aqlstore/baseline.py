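"""Index-free baseline: serial recursive search over a raw record corpus.

This is a single-process re-implementation of the classic brute-force
comparator: every record of a JSON-lines corpus is examined once, its
tree searched recursively for an archetype chain satisfying the
containment constraints, and the WHERE condition evaluated per innermost
archetype instance.  No structure registry, no store, no secondary
index.  It is deliberately written against the raw JSON dictionaries —
independent of the record model and of the driver-side evaluator — so
it doubles as the correctness oracle for the indexed engine.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator

from . import aql
from .engine import ResultSet
from .index import class_matches

__all__ = ["ScanReport", "compare", "scan"]

logger = logging.getLogger(__name__)

_META_KEYS = {
    "record_id", "ehr_id", "version", "active", "created_at", "updated_at",
    "structure_id", "archetype_class", "path_from_parent",
}


# ---------------------------------------------------------------------------
# recursive tree search on raw dictionaries


def _iter_archetypes(obj: dict, ancestors: tuple[str, ...]) -> Iterator[
        tuple[dict, tuple[str, ...]]]:
    """Yield (archetype object, ancestor class chain) depth-first."""
    yield obj, ancestors
    deeper = ancestors + (str(obj.get("archetype_class", "")),)

    def walk(value: Any) -> Iterator[tuple[dict, tuple[str, ...]]]:
        if isinstance(value, dict):
            if "archetype_class" in value:
                yield from _iter_archetypes(value, deeper)
            else:
                for k, v in value.items():
                    yield from walk(v)
        elif isinstance(value, list):
            for item in value:
                yield from walk(item)

    for key, value in obj.items():
        if key in _META_KEYS or key.startswith("_"):
            continue
        yield from walk(value)


def _chain_embeds(patterns: tuple[str, ...], ancestors: tuple[str, ...]) -> bool:
    i = 0
    for cls in ancestors:
        if i < len(patterns) and class_matches(patterns[i], cls):
            i += 1
    return i >= len(patterns)


def chain_instances(doc: dict, patterns: tuple[str, ...]) -> list[dict]:
    """Innermost archetype objects terminating the containment chain.

    Reused as the independent oracle for index-service lookups: a record
    (or bare structure skeleton) contains the chain iff this is non-empty.
    """
    if not patterns:
        return [doc]
    out: list[dict] = []
    for node, ancestors in _iter_archetypes(doc, ()):
        if class_matches(patterns[-1], str(node.get("archetype_class", ""))) and \
                _chain_embeds(patterns[:-1], ancestors):
            out.append(node)
    return out


# -- path resolution on raw dictionaries ------------------------------------


def _resolve(value: Any, steps: tuple[str, ...]) -> list[Any]:
    if not steps:
        return [value]
    if isinstance(value, list):
        out = []
        for item in value:
            out.extend(_resolve(item, steps))
        return out
    if isinstance(value, dict):
        if steps[0] in value:
            return _resolve(value[steps[0]], steps[1:])
        return []
    return []


def _scalar_values(resolved: list[Any]) -> list[Any]:
    return [v for v in resolved
            if not isinstance(v, (dict, list))]


# -- condition evaluation ----------------------------------------------------


def _pred_nodes(pred: aql.Predicate, doc: dict, inst: dict,
                qom: aql.QueryObjectModel) -> list[Any]:
    chain = qom.location.chain
    if chain and pred.variable == chain[-1].variable:
        return _resolve(inst, pred.path.steps)
    if pred.variable == qom.location.ehr_variable:
        return _resolve(doc, pred.path.steps)
    for spec in chain[:-1]:
        if spec.variable == pred.variable:
            out: list[Any] = []
            for node, _anc in _iter_archetypes(doc, ()):
                if class_matches(spec.class_pattern,
                                 str(node.get("archetype_class", ""))):
                    out.extend(_resolve(node, pred.path.steps))
            return out
    return []


def _holds(value: Any, op: str, literal: Any) -> bool:
    numeric = (isinstance(value, (int, float)) and not isinstance(value, bool)
               and isinstance(literal, (int, float))
               and not isinstance(literal, bool))
    stringy = isinstance(value, str) and isinstance(literal, str)
    if op == "=":
        return value == literal
    if op == "!=":
        return value != literal
    if not (numeric or stringy):
        return False
    return {"<": value < literal, "<=": value <= literal,
            ">": value > literal, ">=": value >= literal}[op]


def _eval(cond, doc: dict, inst: dict, qom: aql.QueryObjectModel) -> bool:
    if isinstance(cond, aql.Predicate):
        nodes = _pred_nodes(cond, doc, inst, qom)
        if cond.operator == "exists":
            return bool(nodes)
        values = _scalar_values(nodes)
        if cond.operator == "matches":
            return any(v in cond.values for v in values)
        return any(_holds(v, cond.operator, cond.literal) for v in values)
    if isinstance(cond, aql.NotNode):
        return not _eval(cond.child, doc, inst, qom)
    if isinstance(cond, aql.AndNode):
        return all(_eval(c, doc, inst, qom) for c in cond.children)
    if isinstance(cond, aql.OrNode):
        return any(_eval(c, doc, inst, qom) for c in cond.children)
    raise TypeError(f"unknown condition node {cond!r}")


# ---------------------------------------------------------------------------
# scan


@dataclass
class ScanReport:
    count: int = 0
    record_ids: set[str] = field(default_factory=set)
    records_examined: int = 0
    malformed_lines: int = 0
    result: ResultSet | None = None


def _record_rows(doc: dict, instances: list[dict],
                 qom: aql.QueryObjectModel) -> list[tuple[Any, ...]]:
    rid = str(doc.get("record_id", ""))
    rows = []
    for inst in instances:
        cells = []
        for item in qom.selection.items:
            if item.variable == qom.location.ehr_variable and not item.path:
                cells.append(rid)
                continue
            chain = qom.location.chain
            if chain and item.variable == chain[-1].variable:
                resolved = _resolve(inst, item.path.steps)
            else:
                resolved = _resolve(doc, item.path.steps)
            cell = None
            for v in resolved:
                if not isinstance(v, (dict, list)):
                    cell = v
                    break
                if isinstance(v, dict) and "archetype_class" in v:
                    cell = v["archetype_class"]
                    break
            cells.append(cell)
        rows.append(tuple(cells))
    return rows


def scan(qom: aql.QueryObjectModel, corpus: Iterable[str],
         mode: str = "count") -> ScanReport:
    """Evaluate a query over a JSON-lines corpus by exhaustive search.

    Each record is examined exactly once.  Malformed lines are counted
    and skipped with a warning.  ``mode`` is ``count`` or ``fetch``.
    """
    patterns = aql.location_of(qom).patterns
    report = ScanReport()
    rows: list[tuple[Any, ...]] = []
    hits: list[tuple[str, dict, list[dict]]] = []
    for line in corpus:
        line = line.strip()
        if not line:
            continue
        try:
            doc = json.loads(line)
            if not isinstance(doc, dict) or "archetype_class" not in doc:
                raise ValueError("not a record document")
        except ValueError as exc:
            report.malformed_lines += 1
            logger.warning("skipping malformed corpus line: %s", exc)
            continue
        report.records_examined += 1
        instances = chain_instances(doc, patterns)
        if qom.condition is not None:
            instances = [i for i in instances
                         if _eval(qom.condition, doc, i, qom)]
        if instances:
            rid = str(doc.get("record_id", ""))
            report.count += 1
            report.record_ids.add(rid)
            if mode == "fetch":
                hits.append((rid, doc, instances))
    if mode == "fetch":
        hits.sort(key=lambda t: t[0])
        for _rid, doc, instances in hits:
            rows.extend(_record_rows(doc, instances, qom))
        columns = tuple(i.column_name for i in qom.selection.items)
        report.result = ResultSet(columns=columns, rows=rows,
                                  total_count=len(rows))
    return report


def compare(qom: aql.QueryObjectModel, corpus: Iterable[str],
            engine) -> dict[str, Any]:
    """Equivalence report between the indexed engine and the baseline.

    The symmetric difference of record-id sets must be empty for the two
    systems to be considered in agreement.
    """
    text = aql.render(qom)
    engine_ids = engine.matching_record_ids(text)
    report = scan(qom, corpus, mode="count")
    only_engine = sorted(engine_ids - report.record_ids)
    only_baseline = sorted(report.record_ids - engine_ids)
    return {
        "engine_count": len(engine_ids),
        "baseline_count": report.count,
        "only_engine": only_engine,
        "only_baseline": only_baseline,
        "equal": not only_engine and not only_baseline,
    }
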