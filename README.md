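# aqlstore

Structure-indexed storage and querying for deeply nested, heterogeneous
structured biomedical records.

## The problem

Clinical and biomedical pipelines produce records in the two-level
modelling style of openEHR: a generic reference model plus *archetypes* —
computable definitions of single clinical concepts (blood pressure,
lab result, encounter) identified by names like
`openEHR-EHR-OBSERVATION.blood_pressure.v1`. Real records are trees in
which archetypes nest inside each other through attribute paths, and
collections are wildly heterogeneous: thousands of distinct shapes,
nesting dozens of levels deep. The natural query language, AQL, asks
questions at the archetype level:

```sql
SELECT o/data[at0001]/events[at0006]/magnitude
FROM EHR e
CONTAINS COMPOSITION c [openEHR-EHR-COMPOSITION.encounter.v1.lbl-00001]
CONTAINS OBSERVATION o [openEHR-EHR-OBSERVATION.blood_pressure.v1]
WHERE o/data[at0001]/events[at0006]/magnitude > 120
```

`CONTAINS` demands that one archetype appear *anywhere* inside another —
with any number of archetypes in between. Evaluated naively, every such
query must recursively search every record.

## The core idea

Records sharing a shape share all containment answers. At ingest, each
record is pruned of values and reduced to its canonical structure: one
node per archetype instance carrying its class and its path relative to
the nearest containing archetype (`path_from_parent`), with sibling
order normalized away so permutations of list items collapse to one
structure. The canonical form is content-hashed into a structure id and
registered once.

A query's containment chain c₁ ⊐ c₂ ⊐ … ⊐ cₙ is then resolved against
the registry alone: a structure matches iff it holds archetypes
a₁ … aₙ with class(aᵢ) matching cᵢ and each aᵢ₊₁ a descendant of aᵢ.
The index returns the matching structure ids together with every
absolute path to the innermost archetype — the concatenation of
`path_from_parent` along the spine — so the storage driver examines
only records whose structure id matched, and evaluates the WHERE
condition only along the returned paths. Lookup cost depends on the
number of distinct structures, not the number of records.

The package provides the full stack: the record model and JSON dialect,
the structure index, an AQL-subset parser, a versioned storage-driver
abstraction with an embedded reference store, the query engine, an
index-free recursive baseline used as correctness oracle, a seeded
synthetic-corpus generator with planted ground truth, and a
correctness-gated benchmark harness.

## Worked example

```python
import sys; sys.path.insert(0, "tests")       # run from the repo root
from conftest import make_worked_example_record, WORKED_QUERY

from aqlstore import IndexService, QueryEngine, extract_structure
from aqlstore.storage import DriverConfig, MemoryDriver

index = IndexService()
driver = MemoryDriver().connect(DriverConfig())

record = make_worked_example_record(magnitude=142.0)   # 7 nested archetypes
record.structure_id = index.register(extract_structure(record))
driver.put(record)

engine = QueryEngine(driver, index)
print(engine.explain(WORKED_QUERY))
print(engine.run(WORKED_QUERY, mode="count"))
```

prints

```
{'chain': ['openEHR-EHR-COMPOSITION.encounter.v1.lbl-00001',
           'openEHR-EHR-OBSERVATION.blood_pressure.v1'],
 'containment_level': 2, 'matched_structures': 1,
 'paths_per_structure': {'810351768b3ca2fa': ['/content[at0001]']}}
1
```

One structure matches the two-level chain; its single absolute path
`/content[at0001]` leads to the blood-pressure observation, whose
magnitude 142.0 satisfies the WHERE clause, so exactly one record is
counted.

From the shell, the same flow at corpus scale:

```sh
aqlstore generate --design cnr --scale 0.001 --seed 1 \
    --out corpus.jsonl --manifest manifest.json --queries queries.aql
aqlstore ingest corpus.jsonl --store ./store
aqlstore query "SELECT o/data/magnitude FROM EHR e CONTAINS OBSERVATION o \
    [openEHR-EHR-OBSERVATION.signal-q1d0.v1]" --store ./store --mode count
aqlstore bench --design cnr --scale 0.001 --seed 1
```

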