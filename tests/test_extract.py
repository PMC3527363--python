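"""Radius-scoped extraction against spec'd examples and brute-force
oracles."""

from __future__ import annotations

import random

import pytest

from helpers import HUMAN, MOUSE, build_kb, gene, record, ref
from interactograph import (
    ConfigurationError,
    InteractionType,
    NodeRole,
    QuerySpec,
    RadiusMode,
    generate_fixture,
)
from interactograph.extract import (
    effective_query_set,
    extract,
    extract_r0,
    extract_r0_intermediates,
    extract_r1,
    extract_r2,
    filter_records,
    merge_edges,
)
from oracles import (
    graph_record_ids,
    oracle_intermediates,
    oracle_nodes,
    oracle_r0,
    oracle_r0_intermediates,
    oracle_r1,
    oracle_r2,
)

A, B, C, D, X, Y = (ref(i) for i in range(1, 7))


def test_r0_keeps_only_in_query_edges():
    records = [record(1, A, B), record(2, A, C)]
    g = extract_r0({A, B}, records)
    assert graph_record_ids(g) == {1}
    assert C not in g.nodes


def test_r0_keeps_isolated_query_nodes():
    g = extract_r0({A, B}, [record(1, C, D)])
    assert g.nodes == {A, B}
    assert g.edges == []
    assert g.node_role[A.gene_id] is NodeRole.query


def test_intermediate_needs_two_distinct_query_neighbors():
    records = [record(1, A, X), record(2, B, X), record(3, A, Y)]
    g = extract_r0_intermediates({A, B}, records)
    assert X in g.nodes and g.node_role[X.gene_id] is NodeRole.intermediate
    assert Y not in g.nodes
    assert graph_record_ids(g) == {1, 2}


def test_two_records_to_one_query_gene_is_not_an_intermediate():
    records = [record(1, A, X), record(2, A, X, InteractionType.genetic)]
    g = extract_r0_intermediates({A, B}, records)
    assert X not in g.nodes


def test_intermediate_intermediate_edges_excluded():
    records = [
        record(1, A, X), record(2, B, X),
        record(3, A, Y), record(4, B, Y),
        record(5, X, Y),  # between two intermediates: not drawn
    ]
    g = extract_r0_intermediates({A, B}, records)
    assert graph_record_ids(g) == {1, 2, 3, 4}


def test_r1_star_around_query_hub():
    records = [record(i, A, r) for i, r in enumerate([B, C, D, X], start=1)]
    g = extract_r1({A}, records)
    assert len(g.edges) == 4
    assert all(
        g.node_role[r.gene_id] is NodeRole.neighbor for r in (B, C, D, X)
    )


def test_r1_path_leaf_query():
    records = [record(1, A, B), record(2, B, C)]
    g = extract_r1({A}, records)
    assert graph_record_ids(g) == {1}
    assert C not in g.nodes


def test_r2_path_stops_at_second_shell():
    records = [record(1, A, B), record(2, B, C), record(3, C, D)]
    g = extract_r2({A}, records)
    assert graph_record_ids(g) == {1, 2}
    assert g.node_role[C.gene_id] is NodeRole.second_shell
    assert D not in g.nodes


def test_r2_includes_first_shell_triangle():
    records = [
        record(1, A, B), record(2, A, C), record(3, A, D),
        record(4, B, C), record(5, C, D), record(6, B, D),
    ]
    g = extract_r2({A}, records)
    assert graph_record_ids(g) == {1, 2, 3, 4, 5, 6}


def test_direction_ignored_for_neighborhood_membership():
    # A regulates B (protein->DNA): B is a neighbor of query {A}, and the
    # target of query {B}'s R1 too
    records = [record(1, A, B, InteractionType.protein_dna)]
    assert B in extract_r1({A}, records).nodes
    assert A in extract_r1({B}, records).nodes
    edge = extract_r1({A}, records).edges[0]
    assert edge.directed and edge.subject == A


def test_duplicate_documentation_merges_into_one_edge():
    records = [record(1, A, B), record(2, B, A)]
    edges = merge_edges(records)
    assert len(edges) == 1
    assert edges[0].record_ids == (1, 2)


def test_merge_keeps_distinct_types_apart():
    records = [record(1, A, B), record(2, A, B, InteractionType.genetic)]
    assert len(merge_edges(records)) == 2


def _random_case(seed: int):
    rng = random.Random(seed)
    kb = generate_fixture(
        n_genes=rng.randint(10, 200),
        n_taxa=rng.randint(1, 3),
        n_interactions=rng.randint(0, 800),
        ortholog_fraction=rng.uniform(0, 0.6),
        seed=seed,
    )
    refs = [info.gene for info in kb.genes.values()]
    queryset = set(rng.sample(refs, rng.randint(1, min(8, len(refs)))))
    return kb.interactions, queryset


@pytest.mark.parametrize("seed", range(25))
def test_extractors_match_brute_force_oracles(seed):
    records, queryset = _random_case(seed)
    cases = [
        (extract_r0, oracle_r0),
        (extract_r0_intermediates, oracle_r0_intermediates),
        (extract_r1, oracle_r1),
        (extract_r2, oracle_r2),
    ]
    for extractor, oracle in cases:
        g = extractor(queryset, records)
        expected_ids = oracle(queryset, records)
        assert graph_record_ids(g) == expected_ids, extractor.__name__
        assert g.nodes == oracle_nodes(queryset, records, expected_ids)


@pytest.mark.parametrize("seed", range(10))
def test_edge_nesting_chain(seed):
    records, queryset = _random_case(seed + 1000)
    e0 = graph_record_ids(extract_r0(queryset, records))
    e0i = graph_record_ids(extract_r0_intermediates(queryset, records))
    e1 = graph_record_ids(extract_r1(queryset, records))
    e2 = graph_record_ids(extract_r2(queryset, records))
    assert e0 <= e0i <= e1 <= e2


@pytest.mark.parametrize("seed", range(5))
def test_intermediate_set_matches_oracle(seed):
    records, queryset = _random_case(seed + 2000)
    g = extract_r0_intermediates(queryset, records)
    got = {
        r for r in g.nodes if g.node_role[r.gene_id] is NodeRole.intermediate
    }
    assert got == oracle_intermediates(queryset, records)


class TestFilters:
    def _mixed_kb(self):
        return build_kb(
            [gene(1, "A"), gene(2, "B"), gene(3, "C"),
             gene(4, "Am", MOUSE), gene(5, "Bm", MOUSE)],
            [
                record(1, ref(1), ref(2)),
                record(2, ref(2), ref(3), InteractionType.protein_dna),
                record(3, ref(1), ref(3), InteractionType.genetic),
                record(4, ref(1), ref(4, MOUSE)),   # human-mouse cross-taxon
                record(5, ref(4, MOUSE), ref(5, MOUSE)),
                record(6, ref(2), ref(3), submitter="alice"),
            ],
        )

    def test_type_filter_drops_other_types(self):
        kb = self._mixed_kb()
        spec = QuerySpec(groups=(("g", (1,)),),
                         include_types=frozenset({InteractionType.protein_protein}))
        kept = filter_records(kb, spec)
        assert {r.record_id for r in kept} == {1, 4, 5, 6}

    def test_status_filter(self):
        from interactograph import AnnotationStatus
        kb = self._mixed_kb()
        spec = QuerySpec(groups=(("g", (1,)),),
                         include_status=frozenset({AnnotationStatus.user_submitted}))
        assert {r.record_id for r in filter_records(kb, spec)} == {6}

    def test_single_organism_requires_both_endpoints(self):
        kb = self._mixed_kb()
        spec = QuerySpec(groups=(("g", (1,)),), organism=HUMAN)
        kept = {r.record_id for r in filter_records(kb, spec)}
        assert 4 not in kept  # the cross-taxon record is removed
        assert kept == {1, 2, 3, 6}

    def test_empty_type_filter_is_configuration_error(self):
        kb = self._mixed_kb()
        spec = QuerySpec(groups=(("g", (1,)),), include_types=frozenset())
        with pytest.raises(ConfigurationError):
            filter_records(kb, spec)

    def test_shrinking_type_filter_never_adds_elements(self):
        kb = generate_fixture(n_genes=60, n_taxa=2, n_interactions=250,
                              ortholog_fraction=0.3, seed=42)
        gid = sorted(kb.genes)[0]
        full = frozenset(InteractionType)
        smaller = frozenset({InteractionType.protein_protein, InteractionType.protein_dna})
        for mode in RadiusMode:
            g_full = extract(QuerySpec(groups=(("g", (gid,)),), radius_mode=mode,
                                       include_types=full), kb)
            g_small = extract(QuerySpec(groups=(("g", (gid,)),), radius_mode=mode,
                                        include_types=smaller), kb)
            assert g_small.nodes <= g_full.nodes
            assert graph_record_ids(g_small) <= graph_record_ids(g_full)

    def test_filter_soundness_on_output_edges(self):
        kb = generate_fixture(n_genes=80, n_taxa=3, n_interactions=300,
                              ortholog_fraction=0.4, seed=7)
        gid = sorted(kb.genes)[2]
        types = frozenset({InteractionType.genetic, InteractionType.protein_dna})
        spec = QuerySpec(groups=(("g", (gid,)),), radius_mode=RadiusMode.R2,
                         include_types=types)
        g = extract(spec, kb)
        assert all(e.interaction_type in types for e in g.edges)
        org = kb.genes[gid].tax_id
        spec_org = QuerySpec(groups=(("g", (gid,)),), radius_mode=RadiusMode.R2,
                             organism=org)
        g_org = extract(spec_org, kb)
        assert all(r.tax_id == org for r in g_org.nodes)


class TestEffectiveQuerySet:
    def test_single_organism_keeps_resolved_members_only(self, ipsc_kb):
        spec = QuerySpec(groups=(("g", (5460, 6657)),), organism=HUMAN)
        refs, membership = effective_query_set(spec, ipsc_kb)
        assert refs == {ref(5460), ref(6657)}

    def test_ortholog_expansion_counts(self):
        kb = build_kb(
            [gene(1, "A", HUMAN), gene(2, "Am", MOUSE), gene(3, "Ar", 10116),
             gene(4, "B", HUMAN), gene(5, "Bm", MOUSE), gene(6, "Br", 10116)],
            groups={1: [ref(1), ref(2, MOUSE), ref(3, 10116)],
                    2: [ref(4), ref(5, MOUSE), ref(6, 10116)]},
        )
        spec = QuerySpec(groups=(("g", (1, 4)),))
        refs, _ = effective_query_set(spec, kb)
        assert len(refs) == 6

    def test_orthologs_inherit_group_membership(self, ipsc_kb):
        spec = QuerySpec(groups=(("g1", (5460,)), ("g2", (5460, 6657))))
        _, membership = effective_query_set(spec, ipsc_kb)
        # mouse Pou5f1 (18999) pulled in by POU5F1, member of both groups
        assert membership[18999] == frozenset({0, 1})
        assert membership[20674] == frozenset({1})

    def test_matches_brute_force_union_over_homology(self):
        kb = generate_fixture(n_genes=90, n_taxa=3, n_interactions=0,
                              ortholog_fraction=0.5, seed=21)
        members = tuple(sorted(kb.genes)[:6])
        spec = QuerySpec(groups=(("g", members),))
        refs, _ = effective_query_set(spec, kb)
        expected = set()
        for gid in members:
            expected.add(kb.genes[gid].gene)
            hid = kb.homologene_id_of(gid)
            if hid is not None:
                expected |= set(kb.homology_groups[hid].members)
        assert refs == expected


def test_extract_on_empty_knowledgebase_keeps_query_nodes(ipsc_kb=None):
    kb = build_kb([gene(1, "A"), gene(2, "B")], [])
    spec = QuerySpec(groups=(("g", (1, 2)),), radius_mode=RadiusMode.R2)
    g = extract(spec, kb)
    assert g.nodes == {ref(1), ref(2)}
    assert g.edges == []


def test_extract_merges_duplicates_end_to_end():
    kb = build_kb(
        [gene(1, "A"), gene(2, "B")],
        [record(1, ref(1), ref(2)), record(2, ref(1), ref(2))],
    )
    spec = QuerySpec(groups=(("g", (1, 2)),), radius_mode=RadiusMode.R0)
    g = extract(spec, kb)
    assert len(g.edges) == 1
    assert g.edges[0].record_ids == (1, 2)
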