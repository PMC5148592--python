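"""Synthetic benchmark corpus generator with planted ground truth.

Emulates large collections of deeply nested, heterogeneous structured
health records as produced by biomedical pipelines.  A library of
~2600 distinct base structures is sampled so that, per structure,

* the maximum archetype nesting depth is ~normal (mean 6.7, sd 1.7),
  truncated to [1, 12] — at most 12 archetypes on one branch;
* the maximum overall element depth (archetypes plus the attribute
  objects between them) has mean ~66: each archetype nesting step is a
  chain of ~11 attribute objects;
* the maximum width (elements at the widest tree level) has mode 8
  with a heavy right tail that can exceed 150.

Corpora come in two designs.  CNR ("constant number of records"):
half the records are filler matching no query, the other half form
five equal datasets, each carrying its own query family planted in a
different place of the structures.  CL ("constant load"): data grows
in ten equal steps, each 10% query-responding and 90% filler.

Each dataset answers a workload of 20 AQL queries — 5 types ("match
single", "match multi", "hit single where", "hit multi and where",
"hit multi or where") at containment levels 2-5.  Responder sets are
nested across levels: a record matching at level k+1 also matches at
level k, so counts shrink as the chain grows.  Per-level responder
counts are planted exactly (rounded from the profile fractions) and
recorded in a manifest that serves as ground truth for oracle tests.
Intermediate-level fractions are geometric interpolations between the
level-2 and level-5 endpoints.
"""

from __future__ import annotations

import json
import math
import random
from collections import Counter
from dataclasses import dataclass, field, asdict
from typing import Any, Iterator

import numpy as np

from .index import StructureDescriptor, StructureNode, describe
from .records import RelPath

__all__ = [
    "CorpusManifest",
    "GeneratorProfile",
    "ProfileError",
    "build_structure_library",
    "emit_queries",
    "generate_cl_steps",
    "generate_corpus",
    "instantiate_document",
    "instantiate_library_records",
    "structure_statistics",
    "validate_statistics",
]


class ProfileError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# profile

QUERY_TYPES = (1, 2, 3, 4, 5)
LEVELS = (2, 3, 4, 5)


def _interp_fractions(level2: float, level5: float) -> dict[int, float]:
    r = (level5 / level2) ** (1.0 / 3.0)
    return {2: level2, 3: level2 * r, 4: level2 * r * r, 5: level5}


def default_match_fractions() -> dict[int, dict[int, float]]:
    """Corpus-wide responder fractions per query type and level."""
    out: dict[int, dict[int, float]] = {}
    for t in (1, 2):
        out[t] = _interp_fractions(0.10, 0.0175)
    for t in (3, 4, 5):
        out[t] = _interp_fractions(0.001, 0.000175)
    return out


@dataclass
class GeneratorProfile:
    """All statistical parameters of the synthetic corpus."""

    n_records: int = 10_000_000
    filler_fraction: float = 0.5
    n_datasets: int = 5
    n_base_structures: int = 2600
    archetype_depth_mean: float = 6.7
    archetype_depth_sd: float = 1.7
    element_depth_mean: float = 66.0
    element_depth_sd: float = 15.7
    width_mode: int = 8
    width_sigma: float = 1.0
    width_tail_prob: float = 0.01
    width_tail_max: int = 200
    max_archetype_chain: int = 12
    match_fraction: dict[int, dict[int, float]] = field(
        default_factory=default_match_fractions)
    fetch_threshold: int = 10_000
    seed: int = 20161216

    @classmethod
    def cnr(cls, **overrides: Any) -> "GeneratorProfile":
        return cls(**overrides)

    @classmethod
    def cl(cls, **overrides: Any) -> "GeneratorProfile":
        overrides.setdefault("filler_fraction", 0.9)
        overrides.setdefault("n_datasets", 1)
        return cls(**overrides)

    # derived: attribute steps per archetype nesting so that element depth
    # comes out at the configured mean (1 + (D-1)*L levels along the spine)
    @property
    def path_len_mean(self) -> float:
        return (self.element_depth_mean - 1.0) / (self.archetype_depth_mean - 1.0)

    def validate(self) -> None:
        if self.n_records < 0:
            raise ProfileError("n_records must be >= 0")
        if not 0.0 <= self.filler_fraction <= 1.0:
            raise ProfileError("filler_fraction must be in [0, 1]")
        if self.n_datasets < 1:
            raise ProfileError("n_datasets must be >= 1")
        if self.archetype_depth_mean <= 1 or self.archetype_depth_sd <= 0:
            raise ProfileError("archetype depth parameters must be positive")
        if self.archetype_depth_mean - 3 * self.archetype_depth_sd \
                > self.max_archetype_chain:
            raise ProfileError("depth cap below mean - 3 sd is infeasible")
        if self.max_archetype_chain < 1:
            raise ProfileError("max_archetype_chain must be >= 1")
        total = 0.0
        dataset_fraction = (1.0 - self.filler_fraction) / self.n_datasets
        for t, per_level in self.match_fraction.items():
            prev = None
            for k in LEVELS:
                f = per_level[k]
                if not 0.0 <= f <= 1.0:
                    raise ProfileError(f"match fraction out of range: t{t} l{k}")
                if prev is not None and f > prev + 1e-12:
                    raise ProfileError(
                        f"match fractions must not grow with level: t{t}")
                prev = f
            if per_level[2] > dataset_fraction + 1e-9:
                raise ProfileError(
                    f"type-{t} level-2 fraction exceeds the dataset share")
            total = max(total, per_level[2])
        if dataset_fraction * self.n_datasets > 1.0 - self.filler_fraction + 1e-9:
            raise ProfileError("responder share exceeds 1 - filler_fraction")


# ---------------------------------------------------------------------------
# vocabularies

_RM_TYPES = ("COMPOSITION", "SECTION", "OBSERVATION", "EVALUATION",
             "INSTRUCTION", "ACTION", "CLUSTER", "ADMIN_ENTRY")

# sibling attribute groups must start with distinct steps, so spine and
# width branches draw from disjoint step pools
_SPINE_STEPS = ("data", "events", "items", "content", "state", "protocol",
                "activities", "description", "details", "segments",
                "results", "body")
_WIDE_STEPS = ("entries", "nodes", "payload", "summary", "context",
               "other_context")

_PLANT_LEAVES = ("magnitude", "secondary")


def _base_class_pool(rng: np.random.Generator, size: int = 400) -> list[str]:
    pool = []
    for i in range(size):
        rm = _RM_TYPES[int(rng.integers(0, len(_RM_TYPES)))]
        pool.append(f"openEHR-EHR-{rm}.base-{i:04d}.v1")
    return pool


def _step(rng: np.random.Generator, names: tuple[str, ...]) -> str:
    name = names[int(rng.integers(0, len(names)))]
    if rng.random() < 0.4:
        return f"{name}[at{int(rng.integers(1, 10000)):04d}]"
    return name


# ---------------------------------------------------------------------------
# structure library


def _trunc_normal_int(rng: np.random.Generator, mean: float, sd: float,
                      low: int, high: int) -> int:
    for _ in range(1000):
        x = int(round(rng.normal(mean, sd)))
        if low <= x <= high:
            return x
    raise GenerationError("truncated normal sampling failed; check profile")


def _sample_width(rng: np.random.Generator, profile: GeneratorProfile) -> int:
    if rng.random() < profile.width_tail_prob:
        return int(rng.uniform(50, profile.width_tail_max))
    base = int(round(math.exp(rng.normal(0.0, profile.width_sigma))))
    return profile.width_mode - 1 + base


def _sample_structure(rng: np.random.Generator, profile: GeneratorProfile,
                      class_pool: list[str]) -> StructureNode:
    depth = _trunc_normal_int(
        rng, profile.archetype_depth_mean, profile.archetype_depth_sd,
        1, profile.max_archetype_chain)
    path_sd = 1.2

    def pick_class() -> str:
        return class_pool[int(rng.integers(0, len(class_pool)))]

    def spine_path() -> str:
        n_steps = max(1, int(round(rng.normal(profile.path_len_mean, path_sd))))
        return RelPath(tuple(_step(rng, _SPINE_STEPS)
                             for _ in range(n_steps))).render()

    # build the spine bottom-up
    node = StructureNode(pick_class(), spine_path(), ())
    spine: list[StructureNode] = [node]
    for _ in range(depth - 2):
        node = StructureNode(pick_class(), spine_path(), (node,))
        spine.append(node)

    wide_at = -1
    wide: tuple[StructureNode, ...] = ()
    if depth >= 2:
        width = _sample_width(rng, profile)
        # the widest level holds (width - 1) planted siblings plus the one
        # spine element passing through it
        wide_path = RelPath((_step(rng, _WIDE_STEPS),
                             _step(rng, _SPINE_STEPS))).render()
        wide = tuple(StructureNode(pick_class(), wide_path, ())
                     for _ in range(max(1, width - 1)))
        wide_at = int(rng.integers(0, depth - 1))  # spine index from the top

    # assemble from the root down; spine[-1] is the child of the root
    if depth == 1:
        return StructureNode(pick_class(), "", ())

    def attach(level: int, below: StructureNode | None) -> tuple[StructureNode, ...]:
        kids: tuple[StructureNode, ...] = (below,) if below is not None else ()
        if level == wide_at:
            kids = kids + wide
        return kids

    # rebuild top-down so the wide branch lands at the sampled spine index
    chain: list[tuple[str, str]] = []  # (class, path) for spine nodes 1..depth-1
    node = spine[-1]
    while True:
        chain.append((node.archetype_class, node.path_from_parent))
        if not node.children:
            break
        node = node.children[0]

    below: StructureNode | None = None
    for level in range(depth - 1, 0, -1):
        cls, pfp = chain[level - 1]
        below = StructureNode(cls, pfp, attach(level, below))
    return StructureNode(pick_class(), "", attach(0, below))


def build_structure_library(profile: GeneratorProfile,
                            seed: int | None = None) -> list[StructureDescriptor]:
    """Exactly ``n_base_structures`` pairwise-distinct canonical skeletons."""
    profile.validate()
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    class_pool = _base_class_pool(rng)
    seen: set[str] = set()
    out: list[StructureDescriptor] = []
    attempts = 0
    while len(out) < profile.n_base_structures:
        attempts += 1
        if attempts > 20 * profile.n_base_structures:
            raise GenerationError("cannot reach the requested number of "
                                  "distinct structures; profile too narrow")
        desc = describe(_sample_structure(rng, profile, class_pool))
        if desc.structure_id in seen:
            continue
        seen.add(desc.structure_id)
        out.append(desc)
    return out


# ---------------------------------------------------------------------------
# statistics

_META = {"archetype_class", "path_from_parent"}


def _skeleton(node: StructureNode) -> dict[str, Any]:
    return _materialize(node, None, shuffle=False, values=False)


def structure_statistics(desc: StructureDescriptor) -> dict[str, int]:
    """Depth/width metrics of one structure, computed on its JSON skeleton.

    Element depth counts every JSON object along a path (arrays are
    transparent); archetype depth counts only archetype objects.
    """
    doc = _skeleton(desc.root)
    level_counts: Counter[int] = Counter()
    max_elem = 0
    max_arch = 0

    def walk(value: Any, level: int, arch_depth: int) -> None:
        nonlocal max_elem, max_arch
        if isinstance(value, dict):
            is_arch = "archetype_class" in value
            arch_depth += 1 if is_arch else 0
            level_counts[level] += 1
            max_elem = max(max_elem, level)
            max_arch = max(max_arch, arch_depth)
            for k, v in value.items():
                if k in _META:
                    continue
                walk(v, level + 1, arch_depth)
        elif isinstance(value, list):
            for item in value:
                walk(item, level, arch_depth)
        else:
            level_counts[level] += 1
            max_elem = max(max_elem, level)

    walk(doc, 1, 0)
    return {
        "max_archetype_depth": max_arch,
        "max_element_depth": max_elem,
        "max_width": max(level_counts.values()),
        "max_archetype_chain": max_arch,
    }


def validate_statistics(library: list[StructureDescriptor]) -> dict[str, Any]:
    """Summary report of the library's depth/width distributions."""
    stats = [structure_statistics(d) for d in library]
    arch = np.array([s["max_archetype_depth"] for s in stats], dtype=float)
    elem = np.array([s["max_element_depth"] for s in stats], dtype=float)
    width = [s["max_width"] for s in stats]
    mode_width = Counter(width).most_common(1)[0][0] if width else 0
    return {
        "n_structures": len(library),
        "mean_max_archetype_depth": float(arch.mean()) if len(arch) else 0.0,
        "sd_max_archetype_depth": float(arch.std()) if len(arch) else 0.0,
        "mean_max_element_depth": float(elem.mean()) if len(elem) else 0.0,
        "sd_max_element_depth": float(elem.std()) if len(elem) else 0.0,
        "modal_max_width": int(mode_width),
        "max_width": int(max(width)) if width else 0,
        "max_archetype_chain": int(arch.max()) if len(arch) else 0,
    }


# ---------------------------------------------------------------------------
# instantiation


def _materialize(node: StructureNode, rng: random.Random | None,
                 shuffle: bool, values: bool) -> dict[str, Any]:
    obj: dict[str, Any] = {
        "archetype_class": node.archetype_class,
        "path_from_parent": node.path_from_parent,
    }
    groups: dict[str, list[StructureNode]] = {}
    for c in node.children:
        groups.setdefault(c.path_from_parent, []).append(c)
    keys = list(groups)
    if shuffle and rng is not None:
        rng.shuffle(keys)
    for path in keys:
        kids = list(groups[path])
        if shuffle and rng is not None:
            rng.shuffle(kids)
        steps = RelPath.parse(path).steps
        target = obj
        for s in steps[:-1]:
            target = target.setdefault(s, {})
            if not isinstance(target, dict):
                raise GenerationError(f"path collision at step {s!r}")
        kid_objs = [_materialize(k, rng, shuffle, values) for k in kids]
        last = steps[-1]
        if last in target:
            raise GenerationError(f"path collision at step {last!r}")
        target[last] = kid_objs[0] if len(kid_objs) == 1 else kid_objs
    if values and rng is not None:
        obj["uid"] = rng.randrange(10 ** 9)
    return obj


def instantiate_document(desc: StructureDescriptor, rng: random.Random,
                         record_id: str, ehr_id: str,
                         shuffle: bool = True) -> dict[str, Any]:
    """A fresh record document instantiating one base structure."""
    doc: dict[str, Any] = {
        "record_id": record_id,
        "ehr_id": ehr_id,
        "version": 1,
        "active": True,
        "created_at": "2016-12-16T00:00:00Z",
        "updated_at": "2016-12-16T00:00:00Z",
        "structure_id": "",
    }
    doc.update(_materialize(desc.root, rng, shuffle=shuffle, values=True))
    return doc


def instantiate_library_records(library: list[StructureDescriptor],
                                per_structure: int,
                                seed: int,
                                shuffle: bool = True) -> Iterator[dict[str, Any]]:
    """``per_structure`` records per base structure, sibling order shuffled."""
    rng = random.Random(seed)
    i = 0
    for desc in library:
        for _ in range(per_structure):
            yield instantiate_document(desc, rng, f"r{i:08d}", f"e{i:08d}",
                                       shuffle=shuffle)
            i += 1


# ---------------------------------------------------------------------------
# query families and workload


def _family_classes(query_type: int, dataset: int) -> dict[str, Any]:
    tag = f"q{query_type}d{dataset}"
    return {
        "outer": f"openEHR-EHR-COMPOSITION.encounter-{tag}.v1."
                 f"lbl-{10000 + dataset * 100 + query_type:05d}",
        "mids": tuple(f"openEHR-EHR-SECTION.stage{i}-{tag}.v1"
                      for i in (1, 2, 3)),
        "inner": f"openEHR-EHR-OBSERVATION.signal-{tag}.v1",
    }


def _chain_for(query_type: int, dataset: int, level: int) -> tuple[str, ...]:
    fam = _family_classes(query_type, dataset)
    return (fam["outer"],) + fam["mids"][: level - 2] + (fam["inner"],)


def _rm_type(cls: str) -> str:
    return cls.split(".", 1)[0].rsplit("-", 1)[-1]


MAGNITUDE_THRESHOLD = 120.0
SECONDARY_THRESHOLD = 80.0


def emit_queries(profile: GeneratorProfile,
                 dataset: int = 0) -> dict[str, str]:
    """The 20-query workload (5 types x levels 2-5) for one dataset family."""
    out: dict[str, str] = {}
    for t in QUERY_TYPES:
        for k in LEVELS:
            chain = _chain_for(t, dataset, k)
            n = len(chain)
            froms = " FROM EHR e"
            for i, cls in enumerate(chain):
                var = "o" if i == n - 1 else f"c{i + 1}"
                froms += f" CONTAINS {_rm_type(cls)} {var} [{cls}]"
            if t == 1:
                select = "SELECT o/data/magnitude"
            elif t == 2:
                select = "SELECT o/data/magnitude, o/data/secondary"
            else:
                select = "SELECT o/data/magnitude"
            where = ""
            p1 = f"o/data/magnitude > {MAGNITUDE_THRESHOLD}"
            p2 = f"o/data/secondary < {SECONDARY_THRESHOLD}"
            if t == 3:
                where = f" WHERE {p1}"
            elif t == 4:
                where = f" WHERE {p1} AND {p2}"
            elif t == 5:
                where = f" WHERE {p1} OR {p2}"
            out[f"t{t}-l{k}"] = select + froms + where
    return out


# ---------------------------------------------------------------------------
# corpus generation


@dataclass
class CorpusManifest:
    """Planted ground truth: the oracle for every benchmark query."""

    seed: int
    n_records: int
    filler_count: int
    n_datasets: int
    counts: dict[str, int] = field(default_factory=dict)
    record_ids: dict[str, list[str]] = field(default_factory=dict)
    profile: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), separators=(",", ":"), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CorpusManifest":
        return cls(**json.loads(text))


def _planted_counts(profile: GeneratorProfile, n: int) -> dict[int, dict[int, int]]:
    return {
        t: {k: int(round(profile.match_fraction[t][k] * n)) for k in LEVELS}
        for t in QUERY_TYPES
    }


def _graft_values(query_type: int, j: int,
                  rng: random.Random) -> tuple[float, float]:
    hi = round(rng.uniform(MAGNITUDE_THRESHOLD + 1.0,
                           MAGNITUDE_THRESHOLD + 80.0), 2)
    lo_mag = round(rng.uniform(1.0, MAGNITUDE_THRESHOLD - 1.0), 2)
    lo_sec = round(rng.uniform(1.0, SECONDARY_THRESHOLD - 1.0), 2)
    hi_sec = round(rng.uniform(SECONDARY_THRESHOLD + 1.0,
                               SECONDARY_THRESHOLD + 80.0), 2)
    if query_type in (1, 2, 3):
        return hi, hi_sec  # types 1-2 unconditioned; type 3 needs magnitude
    if query_type == 4:
        return hi, lo_sec  # both predicates hold
    # type 5: either disjunct suffices; alternate which one
    return (hi, hi_sec) if j % 2 == 0 else (lo_mag, lo_sec)


def _doc_archetype_objects(doc: dict[str, Any]) -> list[dict[str, Any]]:
    out: list[dict[str, Any]] = []

    def walk(value: Any) -> None:
        if isinstance(value, dict):
            if "archetype_class" in value:
                out.append(value)
                for k, v in value.items():
                    if k not in _META:
                        walk(v)
            else:
                for v in value.values():
                    walk(v)
        elif isinstance(value, list):
            for item in value:
                walk(item)

    walk(doc)
    return out


def _graft_chain(doc: dict[str, Any], classes: tuple[str, ...],
                 query_type: int, attach_idx: int,
                 leaf_values: tuple[float, float]) -> None:
    nodes = _doc_archetype_objects(doc)
    attach = nodes[min(attach_idx, len(nodes) - 1)]
    key = f"planted-t{query_type}"
    cur = attach
    for cls in classes:
        child: dict[str, Any] = {"archetype_class": cls,
                                 "path_from_parent": f"/{key}"}
        cur[key] = child
        cur = child
    cur["data"] = {"magnitude": leaf_values[0], "secondary": leaf_values[1]}


def generate_corpus(profile: GeneratorProfile, scale: float = 1.0,
                    library: list[StructureDescriptor] | None = None,
                    out_path: str | None = None,
                    id_offset: int = 0,
                    seed: int | None = None,
                    ) -> tuple[list[str] | int, CorpusManifest]:
    """Emit a seeded JSON-lines corpus plus its ground-truth manifest.

    ``scale`` shrinks ``n_records`` proportionally; planted responder
    counts are ``round(match_fraction * n_records * scale)`` exactly.
    Dataset ``d`` uses placement variant ``d`` (the query chains are
    planted at a different position in the base structures).  With
    ``out_path`` set, lines stream to disk and the record total is
    returned instead of the line list.
    """
    profile.validate()
    if not 0.0 < scale <= 1.0:
        raise ProfileError("scale must be in (0, 1]")
    the_seed = profile.seed if seed is None else seed
    if library is None:
        library = build_structure_library(profile, seed=the_seed)
    rng = random.Random(the_seed + 1)
    n = int(profile.n_records * scale)
    counts = _planted_counts(profile, n)
    dataset_size = counts[1][2]
    if counts[2][2] != dataset_size:
        raise GenerationError("type-1 and type-2 level-2 counts must agree "
                              "(both span a full dataset)")
    n_responders = dataset_size * profile.n_datasets
    if n_responders > n:
        raise GenerationError("responder allocation exceeds the corpus size")
    filler_count = n - n_responders

    manifest = CorpusManifest(
        seed=the_seed,
        n_records=n,
        filler_count=filler_count,
        n_datasets=profile.n_datasets,
        profile={"n_records": profile.n_records, "scale": scale,
                 "filler_fraction": profile.filler_fraction,
                 "n_base_structures": profile.n_base_structures},
    )
    for d in range(profile.n_datasets):
        for t in QUERY_TYPES:
            for k in LEVELS:
                manifest.counts[f"t{t}-l{k}-d{d}"] = counts[t][k]
                manifest.record_ids[f"t{t}-l{k}-d{d}"] = []

    sink: list[str] = []
    fh = open(out_path, "w", encoding="utf-8") if out_path else None
    written = 0

    def emit(doc: dict[str, Any]) -> None:
        nonlocal written
        line = json.dumps(doc, ensure_ascii=False, separators=(",", ":"))
        if fh is not None:
            fh.write(line + "\n")
        else:
            sink.append(line)
        written += 1

    try:
        i = id_offset
        for d in range(profile.n_datasets):
            # placement variant: plant the chains progressively deeper
            for j in range(dataset_size):
                rid = f"r{i:08d}"
                base = library[rng.randrange(len(library))]
                doc = instantiate_document(base, rng, rid, f"e{i:08d}")
                n_arch = len(_doc_archetype_objects(doc))
                if profile.n_datasets > 1:
                    attach_idx = (d * (n_arch - 1)) // (profile.n_datasets - 1)
                else:
                    attach_idx = 0
                for t in QUERY_TYPES:
                    level = 0
                    for k in reversed(LEVELS):  # deepest band first
                        if j < counts[t][k]:
                            level = k
                            break
                    if level == 0:
                        continue
                    chain = _chain_for(t, d, level)
                    _graft_chain(doc, chain, t, attach_idx,
                                 _graft_values(t, j, rng))
                    for k in LEVELS:
                        if j < counts[t][k]:
                            manifest.record_ids[f"t{t}-l{k}-d{d}"].append(rid)
                emit(doc)
                i += 1
        for _ in range(filler_count):
            rid = f"r{i:08d}"
            base = library[rng.randrange(len(library))]
            emit(instantiate_document(base, rng, rid, f"e{i:08d}"))
            i += 1
    finally:
        if fh is not None:
            fh.close()

    for key, ids in manifest.record_ids.items():
        if len(ids) != manifest.counts[key]:
            raise GenerationError(f"planted count mismatch for {key}")
    return (written if fh is not None else sink), manifest


def generate_cl_steps(profile: GeneratorProfile, scale: float = 1.0,
                      n_steps: int = 10,
                      ) -> Iterator[tuple[int, list[str], CorpusManifest]]:
    """Constant-load design: the corpus grows in equal steps, each with
    the same 10/90 responder/filler composition."""
    profile.validate()
    library = build_structure_library(profile)
    step_records = int(profile.n_records * scale) // n_steps
    step_profile = GeneratorProfile(**{**asdict(profile),
                                       "n_records": step_records,
                                       "match_fraction": profile.match_fraction})
    for s in range(n_steps):
        lines, manifest = generate_corpus(
            step_profile, scale=1.0, library=library,
            id_offset=s * step_records, seed=profile.seed + 1000 + s)
        assert isinstance(lines, list)
        yield s, lines, manifest
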