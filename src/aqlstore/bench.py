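"""Corpus ingest and the desk-scale benchmark harness.

Ingest follows the production flow: every record is forwarded to the
index service, its structure is normalized and registered (new
structures are added, known ones reused), and the record is stored with
its structure id.

The benchmark reproduces the experimental procedure at a single-process
scale: generate a seeded corpus, ingest it, run the 20-query workload
(5 types x containment levels 2-5) repeatedly, and report per-phase
timings (index lookup, count, fetch) as mean +/- sd over the
repetitions, next to the index-free baseline.  A correctness gate —
engine counts and record-id sets must equal both the baseline scan and
the generator manifest — runs first; timings are never reported for a
configuration that fails it.  Wall-clock numbers are illustrative only
and depend on the host.
"""

from __future__ import annotations

import json
import logging
import statistics
import time
from dataclasses import dataclass, field
from typing import Any, Iterable

from . import aql, baseline
from .engine import QueryEngine
from .index import IndexService
from .storage import DriverConfig, MemoryDriver
from .synth import CorpusManifest, GeneratorProfile, emit_queries, generate_corpus

__all__ = ["BenchmarkGateError", "BenchmarkRun", "ingest", "run_benchmark"]

logger = logging.getLogger(__name__)


class BenchmarkGateError(RuntimeError):
    """The engine and the oracle disagreed; timings were not produced."""


# ---------------------------------------------------------------------------
# ingest


def ingest(corpus: Iterable[str], driver: MemoryDriver,
           index: IndexService) -> dict[str, Any]:
    """Store every record of a JSON-lines corpus, registering structures.

    Returns a report with records stored, structures registered and
    per-record failures (logged, not raised).
    """
    structures_before = len(index)
    stored = 0
    failed = 0
    for line in corpus:
        line = line.strip()
        if not line:
            continue
        try:
            doc = json.loads(line)
            sid = index.register_record(doc)
            doc["structure_id"] = sid
            driver.put_document(doc)
            stored += 1
        except Exception as exc:  # per-record failures are summarized
            failed += 1
            logger.warning("ingest failure: %s", exc)
    return {
        "records_stored": stored,
        "records_failed": failed,
        "structures_registered": len(index),
        "structures_new": len(index) - structures_before,
    }


# ---------------------------------------------------------------------------
# benchmark


@dataclass
class BenchmarkRun:
    design: str
    repetitions: int
    n_records: int
    rows: list[dict[str, Any]] = field(default_factory=list)

    def to_tsv(self) -> str:
        cols = ("query", "level", "count", "index_lookup_ms", "count_ms",
                "fetch_ms", "total_ms", "total_sd_ms", "baseline_ms")
        out = ["\t".join(cols)]
        for r in self.rows:
            out.append("\t".join(str(r.get(c, "")) for c in cols))
        return "\n".join(out)


def _gate(engine: QueryEngine, corpus: list[str], queries: dict[str, str],
          manifest: CorpusManifest, dataset: int) -> None:
    for key, text in queries.items():
        qom = aql.parse(text)
        report = baseline.compare(qom, corpus, engine)
        planted = manifest.counts.get(f"{key}-d{dataset}")
        if not report["equal"] or (
                planted is not None and report["engine_count"] != planted):
            raise BenchmarkGateError(
                f"correctness gate failed for {key}: "
                f"engine={report['engine_count']} "
                f"baseline={report['baseline_count']} planted={planted} "
                f"only_engine={report['only_engine'][:5]} "
                f"only_baseline={report['only_baseline'][:5]}")


def run_benchmark(profile: GeneratorProfile | None = None,
                  scale: float = 0.001,
                  repetitions: int = 3,
                  design: str = "cnr",
                  dataset: int = 0,
                  mode: str = "auto",
                  skip_gate: bool = False) -> BenchmarkRun:
    """Generate, ingest, gate and time the 20-query workload."""
    if profile is None:
        profile = (GeneratorProfile.cnr() if design == "cnr"
                   else GeneratorProfile.cl())
    lines, manifest = generate_corpus(profile, scale=scale)
    assert isinstance(lines, list)
    index = IndexService()
    driver = MemoryDriver().connect(DriverConfig(
        fetch_threshold=profile.fetch_threshold))
    ingest(lines, driver, index)
    engine = QueryEngine(driver, index,
                         fetch_threshold=profile.fetch_threshold)
    queries = emit_queries(profile, dataset=dataset)

    if not skip_gate:
        _gate(engine, lines, queries, manifest, dataset)

    run = BenchmarkRun(design=design, repetitions=repetitions,
                       n_records=manifest.n_records)
    for key, text in queries.items():
        t, level = key.split("-l")
        totals: list[float] = []
        phases = {"index_lookup_s": 0.0, "count_s": 0.0, "fetch_s": 0.0}
        count = 0
        for _ in range(repetitions):
            result = engine.run(text, mode=mode)
            count = result if isinstance(result, int) else result.total_count
            timings = engine.last_timings
            totals.append(timings.total_s)
            phases["index_lookup_s"] += timings.index_lookup_s
            phases["count_s"] += timings.count_s
            phases["fetch_s"] += timings.fetch_s
        t0 = time.perf_counter()
        baseline.scan(aql.parse(text), lines, mode="count")
        baseline_s = time.perf_counter() - t0
        run.rows.append({
            "query": t,
            "level": int(level),
            "count": count,
            "index_lookup_ms": round(1e3 * phases["index_lookup_s"] / repetitions, 3),
            "count_ms": round(1e3 * phases["count_s"] / repetitions, 3),
            "fetch_ms": round(1e3 * phases["fetch_s"] / repetitions, 3),
            "total_ms": round(1e3 * statistics.mean(totals), 3),
            "total_sd_ms": round(
                1e3 * (statistics.stdev(totals) if len(totals) > 1 else 0.0), 3),
            "baseline_ms": round(1e3 * baseline_s, 3),
        })
    return run
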