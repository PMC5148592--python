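"""Synthetic corpus generator: profile validation, library statistics,
planted counts, determinism, filler purity."""

import random

import pytest

from aqlstore import aql, baseline
from aqlstore.index import IndexService
from aqlstore.records import from_document, read_record
from aqlstore.synth import (
    GeneratorProfile,
    ProfileError,
    build_structure_library,
    emit_queries,
    generate_cl_steps,
    generate_corpus,
    instantiate_document,
    structure_statistics,
    validate_statistics,
)


# -- profile -----------------------------------------------------------------


def test_profile_defaults_reflect_the_benchmark_design():
    p = GeneratorProfile.cnr()
    assert p.n_records == 10_000_000
    assert p.filler_fraction == 0.5 and p.n_datasets == 5
    assert p.match_fraction[1][2] == 0.10
    assert p.match_fraction[1][5] == 0.0175
    assert p.match_fraction[3][2] == 0.001
    assert p.match_fraction[3][5] == 0.000175
    # intermediate levels interpolate geometrically between the endpoints
    r = (0.0175 / 0.10) ** (1 / 3)
    assert p.match_fraction[1][3] == pytest.approx(0.10 * r)
    assert p.match_fraction[1][4] == pytest.approx(0.10 * r * r)
    cl = GeneratorProfile.cl()
    assert cl.filler_fraction == 0.9 and cl.n_datasets == 1
    p.validate(), cl.validate()


def test_infeasible_profiles_are_rejected():
    with pytest.raises(ProfileError):
        GeneratorProfile(filler_fraction=1.5).validate()
    with pytest.raises(ProfileError):
        GeneratorProfile(archetype_depth_mean=30.0).validate()
    with pytest.raises(ProfileError):
        bad = GeneratorProfile()
        bad.match_fraction[3][5] = 0.5  # grows with level
        bad.validate()
    with pytest.raises(ProfileError):
        generate_corpus(GeneratorProfile(n_base_structures=5, n_records=100),
                        scale=0.0)


# -- structure library -------------------------------------------------------


def test_single_structure_library():
    lib = build_structure_library(GeneratorProfile(n_base_structures=1))
    assert len(lib) == 1
    stats = validate_statistics(lib)
    assert stats["n_structures"] == 1


def test_library_canonical_ids_are_pairwise_distinct(small_library):
    ids = [d.structure_id for d in small_library]
    assert len(set(ids)) == len(ids)
    idx = IndexService()
    for d in small_library:
        idx.register(d)
    assert len(idx) == len(small_library)


def independent_structure_stats(desc):
    """Recompute the depth metrics straight from the skeleton tree: an
    archetype nested at a relative path of L steps sits L element levels
    below its parent archetype."""
    from aqlstore.records import RelPath

    def arch_depth(n):
        return 1 + max((arch_depth(c) for c in n.children), default=0)

    def elem_depth(n):
        return max(
            [1] + [len(RelPath.parse(c.path_from_parent)) + elem_depth(c)
                   for c in n.children])

    return elem_depth(desc.root), arch_depth(desc.root)


def test_statistics_report_matches_independent_recomputation(small_library):
    for desc in small_library[:25]:
        stats = structure_statistics(desc)
        elem, arch = independent_structure_stats(desc)
        assert stats["max_archetype_depth"] == arch
        assert stats["max_element_depth"] == elem
        assert stats["max_archetype_chain"] <= 12


def test_depth_and_width_distributions_on_a_midsize_library():
    lib = build_structure_library(GeneratorProfile(n_base_structures=400,
                                                   seed=3))
    stats = validate_statistics(lib)
    assert abs(stats["mean_max_archetype_depth"] - 6.7) < 0.5
    assert abs(stats["mean_max_element_depth"] - 66.0) < 5.0
    assert stats["modal_max_width"] == 8
    assert stats["max_archetype_chain"] <= 12


# -- corpus ------------------------------------------------------------------


def test_empty_corpus(small_library):
    prof = GeneratorProfile(n_base_structures=80, n_records=0, seed=11)
    lines, manifest = generate_corpus(prof, library=small_library)
    assert lines == []
    assert manifest.filler_count == 0
    assert all(v == 0 for v in manifest.counts.values())


def test_planted_counts_are_rounded_fractions(small_profile, small_corpus):
    lines, manifest = small_corpus
    n = small_profile.n_records
    for t in (1, 2, 3, 4, 5):
        for k in (2, 3, 4, 5):
            expected = round(small_profile.match_fraction[t][k] * n)
            for d in range(small_profile.n_datasets):
                assert manifest.counts[f"t{t}-l{k}-d{d}"] == expected
    assert manifest.filler_count == n - 5 * manifest.counts["t1-l2-d0"]


def test_responder_sets_nest_across_levels(small_corpus):
    _, manifest = small_corpus
    for t in (1, 2, 3, 4, 5):
        for d in range(manifest.n_datasets):
            prev = None
            for k in (5, 4, 3, 2):
                ids = set(manifest.record_ids[f"t{t}-l{k}-d{d}"])
                if prev is not None:
                    assert prev <= ids
                prev = ids


def test_same_seed_gives_byte_identical_corpus_and_manifest(small_library,
                                                            small_profile):
    a = generate_corpus(small_profile, library=small_library)
    b = generate_corpus(small_profile, library=small_library)
    assert a[0] == b[0]
    assert a[1].to_json() == b[1].to_json()


def test_filler_records_match_no_query(small_corpus, small_profile):
    lines, manifest = small_corpus
    responders = {rid for ids in manifest.record_ids.values() for rid in ids}
    filler = [l for l in lines
              if read_record(l).record_id not in responders]
    assert len(filler) == manifest.filler_count
    for d in range(small_profile.n_datasets):
        for text in emit_queries(small_profile, dataset=d).values():
            assert baseline.scan(aql.parse(text), filler).count == 0


def test_counts_are_identical_across_placement_variants(small_corpus,
                                                        small_profile):
    """The five datasets plant the same counts at different positions."""
    _, manifest = small_corpus
    for t in (1, 2, 3, 4, 5):
        for k in (2, 3, 4, 5):
            counts = {manifest.counts[f"t{t}-l{k}-d{d}"]
                      for d in range(small_profile.n_datasets)}
            assert len(counts) == 1


# -- queries -----------------------------------------------------------------


def test_workload_shape_follows_the_five_types(small_profile):
    queries = emit_queries(small_profile)
    assert len(queries) == 20
    for (key, text) in queries.items():
        t, level = key.split("-l")
        qom = aql.parse(text)
        assert qom.containment_level == int(level)
        n_sel = len(qom.selection.items)
        if t == "t1":
            assert n_sel == 1 and qom.condition is None
            assert "WHERE" not in text.upper()
        elif t == "t2":
            assert n_sel == 2 and qom.condition is None
        elif t == "t3":
            assert isinstance(qom.condition, aql.Predicate)
        elif t == "t4":
            assert isinstance(qom.condition, aql.AndNode)
            assert len(qom.condition.children) == 2
        else:
            assert isinstance(qom.condition, aql.OrNode)
            assert len(qom.condition.children) == 2
    levels = {aql.parse(q).containment_level for q in queries.values()}
    assert levels == {2, 3, 4, 5}


# -- constant-load design ----------------------------------------------------


def test_cl_steps_grow_with_constant_composition():
    prof = GeneratorProfile.cl(n_base_structures=40, n_records=400, seed=19)
    steps = list(generate_cl_steps(prof, scale=1.0, n_steps=4))
    assert len(steps) == 4
    seen_ids = set()
    for _s, lines, manifest in steps:
        assert len(lines) == 100
        assert manifest.filler_count == 90
        assert manifest.counts["t1-l2-d0"] == 10
        ids = {read_record(l).record_id for l in lines}
        assert not (ids & seen_ids)  # cumulative growth, disjoint blocks
        seen_ids |= ids
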