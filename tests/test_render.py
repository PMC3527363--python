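"""DOT emission: grammar validity, element conservation, encodings,
hypernode semantics, URL totality, determinism."""

from __future__ import annotations

import shutil

import pytest

from dotcheck import parse_dot
from helpers import HUMAN, MOUSE, build_kb, gene, record, ref
from interactograph import (
    InteractionType,
    QuerySpec,
    RadiusMode,
    RenderEnvironmentError,
    StyleConfig,
    generate_fixture,
)
from interactograph.extract import extract
from interactograph.render import build_legend, render, to_dot
from interactograph.stacking import build_partition


def _pipeline(kb, spec):
    g = extract(spec, kb)
    part = build_partition(g, kb, spec)
    return g, part, to_dot(g, part, spec, kb=kb)


def _simple_kb():
    return build_kb(
        [gene(1, "A"), gene(2, "B"), gene(3, "C")],
        [record(1, ref(1), ref(2))],
    )


def test_single_pp_edge_document():
    kb = _simple_kb()
    spec = QuerySpec(groups=(("g", (1, 2)),), radius_mode=RadiusMode.R0)
    g, part, doc = _pipeline(kb, spec)
    parsed = parse_dot(doc.dot_text)
    assert len(parsed.body_nodes()) == 2
    assert len(parsed.body_edges()) == 1
    edge = parsed.body_edges()[0]
    assert edge.attrs["color"] == "black"
    assert edge.attrs["dir"] == "none"


def test_protein_dna_edge_is_red_directed():
    kb = build_kb(
        [gene(1, "A"), gene(2, "B")],
        [record(1, ref(1), ref(2), InteractionType.protein_dna)],
    )
    spec = QuerySpec(groups=(("g", (1, 2)),), radius_mode=RadiusMode.R0)
    _, _, doc = _pipeline(kb, spec)
    edge = parse_dot(doc.dot_text).body_edges()[0]
    assert edge.attrs["color"] == "red"
    assert edge.attrs["dir"] == "forward"
    assert edge.src == "g1"  # arrowhead at the regulated gene


def test_hypernode_rule_one_statement_per_gene():
    # X has a PP edge to Y and an incoming PD arrow from Z, yet X is
    # drawn once: the node stands for every molecular role
    kb = build_kb(
        [gene(1, "X"), gene(2, "Y"), gene(3, "Z")],
        [record(1, ref(1), ref(2)),
         record(2, ref(3), ref(1), InteractionType.protein_dna)],
    )
    spec = QuerySpec(groups=(("g", (1, 2, 3)),), radius_mode=RadiusMode.R0)
    _, _, doc = _pipeline(kb, spec)
    parsed = parse_dot(doc.dot_text)
    assert sum(1 for n in parsed.body_nodes() if n.node_id == "g1") == 1
    assert len(parsed.body_nodes()) == 3
    assert len(parsed.body_edges()) == 2


def test_element_conservation_and_url_totality_on_fixtures():
    for seed in range(5):
        kb = generate_fixture(n_genes=60, n_taxa=3, n_interactions=200,
                              ortholog_fraction=0.5, seed=seed)
        members = tuple(sorted(kb.genes)[: 4 + seed])
        spec = QuerySpec(groups=(("g", members),), radius_mode=RadiusMode.R1)
        g, part, doc = _pipeline(kb, spec)
        parsed = parse_dot(doc.dot_text)
        assert len(parsed.body_nodes()) == len(part.stacks) + len(part.singletons)
        assert len(parsed.body_edges()) == len(g.edges)
        for n in parsed.body_nodes():
            assert "URL" in n.attrs
            assert doc.url_map[n.node_id] == n.attrs["URL"]
        for e in parsed.body_edges():
            assert "URL" in e.attrs
            assert doc.url_map[e.attrs["id"]] == e.attrs["URL"]


def test_stack_rendered_as_record_node_with_member_urls():
    kb = build_kb(
        [gene(1, "A", HUMAN), gene(2, "Am", MOUSE),
         gene(3, "B", HUMAN), gene(4, "Bm", MOUSE)],
        [record(1, ref(1), ref(3)), record(2, ref(2, MOUSE), ref(4, MOUSE))],
        groups={7: [ref(1), ref(2, MOUSE)], 8: [ref(3), ref(4, MOUSE)]},
    )
    spec = QuerySpec(groups=(("g", (1, 2)),), radius_mode=RadiusMode.R1)
    g, part, doc = _pipeline(kb, spec)
    parsed = parse_dot(doc.dot_text)
    stacks = [n for n in parsed.body_nodes() if n.node_id.startswith("hg")]
    assert len(stacks) == 2
    assert all(n.attrs["shape"] == "record" for n in stacks)
    # per-member URLs are exposed through the url map
    assert doc.url_map["hg7:g1"].endswith("/1")
    assert doc.url_map["hg7:g2"].endswith("/2")


def test_group_colors_and_multigroup_marker():
    kb = _simple_kb()
    spec = QuerySpec(groups=(("g1", (1, 2)), ("g2", (2, 3))),
                     radius_mode=RadiusMode.R0)
    _, _, doc = _pipeline(kb, spec)
    parsed = parse_dot(doc.dot_text)
    by_id = {n.node_id: n for n in parsed.body_nodes()}
    style = StyleConfig()
    assert by_id["g1"].attrs["color"] == style.group_colors[0]
    assert by_id["g3"].attrs["color"] == style.group_colors[1]
    # gene 2 sits in both groups: lowest group's color plus marker
    assert by_id["g2"].attrs["color"] == style.group_colors[0]
    assert by_id["g2"].attrs["peripheries"] == "2"


def test_layout_engine_hint_present():
    kb = _simple_kb()
    spec = QuerySpec(groups=(("g", (1,)),), radius_mode=RadiusMode.R0)
    _, _, doc = _pipeline(kb, spec)
    assert 'layout="sfdp"' in doc.dot_text


def test_submitter_surfaces_in_edge_tooltip():
    kb = build_kb(
        [gene(1, "A"), gene(2, "B")],
        [record(1, ref(1), ref(2), submitter="jdoe")],
    )
    spec = QuerySpec(groups=(("g", (1, 2)),), radius_mode=RadiusMode.R0)
    _, _, doc = _pipeline(kb, spec)
    edge = parse_dot(doc.dot_text).body_edges()[0]
    assert "jdoe" in edge.attrs["tooltip"]


def test_empty_graph_is_valid_dot_with_legend_only():
    kb = build_kb([gene(1, "A")], [])
    spec = QuerySpec(groups=(("g", (1,)),), radius_mode=RadiusMode.R0)
    g, part, doc = _pipeline(kb, spec)
    parsed = parse_dot(doc.dot_text)
    assert parsed.body_edges() == []
    assert any(s.startswith("cluster_legend") for s in parsed.subgraphs)


def test_determinism_byte_identical_output():
    kb = generate_fixture(n_genes=50, n_taxa=2, n_interactions=150,
                          ortholog_fraction=0.4, seed=3)
    members = tuple(sorted(kb.genes)[:5])
    spec = QuerySpec(groups=(("g", members),), radius_mode=RadiusMode.R2)
    _, _, doc1 = _pipeline(kb, spec)
    _, _, doc2 = _pipeline(kb, spec)
    assert doc1.dot_text == doc2.dot_text
    assert doc1.url_map == doc2.url_map


class TestLegend:
    def test_pp_only_single_group_has_one_item(self):
        kb = _simple_kb()
        spec = QuerySpec(groups=(("Query Group 1", (1, 2)),), radius_mode=RadiusMode.R0)
        g = extract(spec, kb)
        items = build_legend(g, spec)
        assert len(items) == 1
        assert items[0][1] == "protein-protein interaction"

    def test_two_named_groups_with_two_types_has_four_items(self):
        kb = build_kb(
            [gene(1, "A"), gene(2, "B"), gene(3, "C")],
            [record(1, ref(1), ref(2)),
             record(2, ref(2), ref(3), InteractionType.protein_dna)],
        )
        spec = QuerySpec(groups=(("Up", (1, 2)), ("Down", (3,))),
                         radius_mode=RadiusMode.R0)
        g = extract(spec, kb)
        items = build_legend(g, spec)
        assert len(items) == 4
        assert [label for _, label in items] == [
            "protein-protein interaction", "protein->DNA interaction", "Up", "Down",
        ]

    def test_items_match_brute_force_distinct_encodings(self):
        kb = generate_fixture(n_genes=40, n_taxa=1, n_interactions=200, seed=8)
        members = tuple(sorted(kb.genes)[:6])
        spec = QuerySpec(groups=(("Query Group 1", members),), radius_mode=RadiusMode.R1)
        g = extract(spec, kb)
        items = build_legend(g, spec)
        distinct_types = {e.interaction_type for e in g.edges}
        assert len(items) == len(distinct_types)  # one group, default name


class TestRender:
    def _doc(self):
        kb = _simple_kb()
        spec = QuerySpec(groups=(("g", (1, 2)),), radius_mode=RadiusMode.R0)
        return _pipeline(kb, spec)[2]

    def test_dot_format_writes_text_verbatim(self, tmp_path):
        doc = self._doc()
        out = render(doc, "dot", tmp_path / "g.dot")
        assert out.read_text() == doc.dot_text

    def test_other_formats_depend_on_graphviz_binary(self, tmp_path):
        doc = self._doc()
        available = shutil.which(doc.layout_engine) or shutil.which("dot")
        if available is None:
            with pytest.raises(RenderEnvironmentError, match="GraphViz"):
                render(doc, "svg", tmp_path / "g.svg")
        else:
            out = render(doc, "svg", tmp_path / "g.svg")
            text = out.read_text()
            assert text.lstrip().startswith("<?xml")

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            render(self._doc(), "png", tmp_path / "g.png")


def test_style_config_overrides_from_file(tmp_path):
    cfg = tmp_path / "style.cfg"
    cfg.write_text(
        "# demo style\n"
        "edge_color_GI = purple\n"
        "group_color_1 = orange\n"
        "layout_engine = neato\n"
        "record_url_template = https://example.org/rec/{record_id}\n"
    )
    style = StyleConfig.from_file(cfg)
    assert style.edge_color[InteractionType.genetic] == "purple"
    assert style.group_colors[0] == "orange"
    assert style.layout_engine == "neato"
    kb = _simple_kb()
    spec = QuerySpec(groups=(("g", (1, 2)),), radius_mode=RadiusMode.R0)
    g = extract(spec, kb)
    part = build_partition(g, kb, spec)
    doc = to_dot(g, part, spec, style=style, kb=kb)
    assert doc.url_map["e1"] == "https://example.org/rec/1"
    assert 'layout="neato"' in doc.dot_text


def test_inconsistent_partition_rejected():
    kb = _simple_kb()
    spec = QuerySpec(groups=(("g", (1, 2)),), radius_mode=RadiusMode.R0)
    g = extract(spec, kb)
    from interactograph.stacking import CompoundPartition

    with pytest.raises(ValueError, match="inconsistent"):
        to_dot(g, CompoundPartition(), spec, kb=kb)
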