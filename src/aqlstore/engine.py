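"""Query engine: parse -> index lookup -> driver execution -> result set.

The engine wires a parsed query to the structure registry and a storage
driver.  The containment (CONTAINS) part of the query is resolved
against the registry alone, producing (structure id, absolute paths)
matches; only records whose structure id appears in those matches are
then examined by the driver.  In ``auto`` mode matching records are
fetched in full when the count does not exceed the configured fetch
threshold (inclusive), otherwise only the count is returned.

Per-phase wall-clock timings (index lookup, count, fetch) are recorded
on every run for the benchmark harness.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Any

from . import aql
from .index import IndexService, StructureMatch

__all__ = ["QueryEngine", "ResultSet"]

logger = logging.getLogger(__name__)

DEFAULT_FETCH_THRESHOLD = 10_000


@dataclass
class ResultSet:
    """Query results as named columns plus rows of projected values."""

    columns: tuple[str, ...]
    rows: list[tuple[Any, ...]] = field(default_factory=list)
    total_count: int = 0

    def __post_init__(self) -> None:
        for row in self.rows:
            if len(row) != len(self.columns):
                raise ValueError("row width does not match column count")

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class PhaseTimings:
    index_lookup_s: float = 0.0
    count_s: float = 0.0
    fetch_s: float = 0.0

    @property
    def total_s(self) -> float:
        return self.index_lookup_s + self.count_s + self.fetch_s


class QueryEngine:
    """Orchestrates the full query flow against one driver session."""

    def __init__(
        self,
        driver,
        index: IndexService,
        fetch_threshold: int = DEFAULT_FETCH_THRESHOLD,
    ) -> None:
        self.driver = driver
        self.index = index
        self.fetch_threshold = fetch_threshold
        self.last_timings = PhaseTimings()

    # -- internals ----------------------------------------------------------

    def _lookup(self, qom: aql.QueryObjectModel) -> list[StructureMatch]:
        chain = aql.location_of(qom)
        if not chain:
            logger.warning(
                "query has no CONTAINS clause; falling back to all %d structures",
                len(self.index),
            )
            return self.index.all_structures_match()
        return self.index.lookup_containment(chain)

    # -- public API ---------------------------------------------------------

    def run(self, query_text: str, mode: str = "auto") -> int | ResultSet:
        """Evaluate a query.  ``mode`` is ``count``, ``fetch`` or ``auto``."""
        if mode not in ("count", "fetch", "auto"):
            raise ValueError(f"unknown mode {mode!r}")
        qom = aql.parse(query_text)
        timings = PhaseTimings()

        t0 = time.perf_counter()
        matches = self._lookup(qom)
        timings.index_lookup_s = time.perf_counter() - t0

        t0 = time.perf_counter()
        count = self.driver.execute_query(qom, matches, mode="count")
        timings.count_s = time.perf_counter() - t0

        result: int | ResultSet = count
        if mode == "fetch" or (mode == "auto" and count <= self.fetch_threshold):
            t0 = time.perf_counter()
            result = self.driver.execute_query(qom, matches, mode="fetch")
            timings.fetch_s = time.perf_counter() - t0

        self.last_timings = timings
        return result

    def matching_record_ids(self, query_text: str) -> set[str]:
        """Ids of all records satisfying the query (for oracle comparison)."""
        qom = aql.parse(query_text)
        matches = self._lookup(qom)
        return self.driver.matching_ids(qom, matches)

    def explain(self, query_text: str) -> dict[str, Any]:
        """Plan summary from the registry only: no record-store access."""
        qom = aql.parse(query_text)
        matches = self._lookup(qom)
        return {
            "chain": list(aql.location_of(qom).patterns),
            "containment_level": qom.containment_level,
            "matched_structures": len(matches),
            "paths_per_structure": {
                m.structure_id: [p.render() for p in m.paths] for m in matches
            },
        }
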