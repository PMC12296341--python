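"""GO graph handling: OBO parsing, aspect splits, pruning and Â."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gofuse.ontology import (
    GoGraph,
    GoTerm,
    build_label_matrix,
    normalized_adjacency,
    prune_by_frequency,
    read_obo,
    split_subontology,
)


def annotations_from_counts(counts: dict[str, int]) -> pd.DataFrame:
    rows = [
        (f"P{i}_{tid}", tid, "BP")
        for tid, c in counts.items()
        for i in range(c)
    ]
    return pd.DataFrame(rows, columns=["protein_id", "go_id", "aspect"])


def chain_graph(ids, rel="is_a", aspect="BP"):
    terms = [GoTerm(id=i, aspect=aspect) for i in ids]
    edges = {(ids[i], ids[i + 1], rel) for i in range(len(ids) - 1)}
    return GoGraph(terms=terms, edges=edges, aspect=aspect)


class TestReadObo:
    def test_minimal_two_term_file(self, tmp_path):
        path = tmp_path / "mini.obo"
        path.write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:0000001\nname: a\n"
            "namespace: molecular_function\n\n[Term]\nid: GO:0000002\n"
            "name: b\nnamespace: molecular_function\nis_a: GO:0000001\n"
        )
        terms, edges = read_obo(path)
        assert len(terms) == 2
        assert edges == {("GO:0000002", "GO:0000001", "is_a")}

    def test_five_term_fixture(self, five_term_obo):
        terms, edges = read_obo(five_term_obo)
        ids = {t.id for t in terms}
        # obsolete stanza excluded
        assert "GO:0000006" not in ids
        assert len(terms) == 5
        # regulates edge dropped, is_a and part_of kept (hand count: 3)
        assert edges == {
            ("GO:0000002", "GO:0000001", "is_a"),
            ("GO:0000003", "GO:0000001", "part_of"),
            ("GO:0000004", "GO:0000001", "is_a"),
        }

    def test_definition_stripped_of_quotes_and_citations(self, five_term_obo):
        terms, _ = read_obo(five_term_obo)
        by_id = {t.id: t for t in terms}
        assert by_id["GO:0000001"].definition == "The root process."

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_obo(tmp_path / "nope.obo")

    def test_stanza_without_namespace(self, tmp_path):
        path = tmp_path / "bad.obo"
        path.write_text(
            "format-version: 1.2\n\n[Term]\nid: GO:0000009\nname: lost\n"
        )
        with pytest.raises(ValueError, match="GO:0000009"):
            read_obo(path)


class TestSplitSubontology:
    def test_aspect_counts(self, five_term_obo):
        terms, edges = read_obo(five_term_obo)
        assert split_subontology(terms, edges, "MF").gamma == 1
        assert split_subontology(terms, edges, "BP").gamma == 4

    def test_empty_aspect_errors(self, five_term_obo):
        terms, edges = read_obo(five_term_obo)
        with pytest.raises(ValueError, match="no terms for aspect"):
            split_subontology(terms, edges, "CC")

    def test_single_aspect_is_identity(self, five_term_obo):
        terms, edges = read_obo(five_term_obo)
        bp_terms = [t for t in terms if t.aspect == "BP"]
        bp_edges = {e for e in edges if not e[0] == "GO:0000005"}
        graph = split_subontology(bp_terms, bp_edges, "BP")
        assert [t.id for t in graph.terms] == sorted(t.id for t in bp_terms)
        assert graph.edges == bp_edges

    def test_index_is_lexicographic_bijection(self, five_term_obo):
        terms, edges = read_obo(five_term_obo)
        graph = split_subontology(terms, edges, "BP")
        assert sorted(graph.index.values()) == list(range(graph.gamma))
        assert [t.id for t in graph.terms] == sorted(graph.index, key=graph.index.get)


class TestPruneByFrequency:
    def test_threshold_zero_is_noop(self):
        graph = chain_graph(["GO:0000001", "GO:0000002", "GO:0000003"])
        space = prune_by_frequency(graph, annotations_from_counts({}), 0)
        assert space.gamma == 3
        assert {e[:2] for e in space.graph.edges} == {e[:2] for e in graph.edges}

    def test_toy_counts(self):
        graph = GoGraph(
            terms=[GoTerm(id=i, aspect="BP") for i in ("GO:0000001", "GO:0000002", "GO:0000003")],
            edges=set(),
            aspect="BP",
        )
        ann = annotations_from_counts(
            {"GO:0000001": 5, "GO:0000002": 2, "GO:0000003": 1}
        )
        space = prune_by_frequency(graph, ann, 2)
        assert space.term_ids == ["GO:0000001", "GO:0000002"]
        assert space.frequencies == {
            "GO:0000001": 5, "GO:0000002": 2, "GO:0000003": 1
        }

    def test_empty_label_space_errors(self):
        graph = chain_graph(["GO:0000001", "GO:0000002"])
        with pytest.raises(ValueError, match="empty label space"):
            prune_by_frequency(graph, annotations_from_counts({}), 1)

    def test_pruned_node_reconnects_parents_to_children(self):
        # c -> b -> a; prune b: expect edge c -> a
        graph = chain_graph(["GO:0000003", "GO:0000002", "GO:0000001"])
        ann = annotations_from_counts(
            {"GO:0000001": 5, "GO:0000002": 1, "GO:0000003": 5}
        )
        space = prune_by_frequency(graph, ann, 2)
        assert space.term_ids == ["GO:0000001", "GO:0000003"]
        assert {(c, p) for c, p, _ in space.graph.edges} == {
            ("GO:0000003", "GO:0000001")
        }

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(0, 8), min_size=1))
    def test_pruning_monotonicity(self, thresholds):
        """Raising the threshold never increases the retained-term count."""
        graph = chain_graph([f"GO:{i:07d}" for i in range(1, 7)])
        ann = annotations_from_counts(
            {f"GO:{i:07d}": i for i in range(1, 7)}
        )
        sizes = []
        for t in sorted(thresholds):
            try:
                sizes.append(prune_by_frequency(graph, ann, t).gamma)
            except ValueError:
                sizes.append(0)
        assert sizes == sorted(sizes, reverse=True)

    @pytest.mark.parametrize("seed", range(8))
    def test_reconnection_preserves_reachability(self, seed):
        """Ancestor reachability among retained terms must match a
        transitive-closure oracle on the original graph."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 30))
        ids = [f"GO:{i:07d}" for i in range(1, n + 1)]
        edges = set()
        for i in range(1, n):
            for p in rng.choice(i, size=min(int(rng.integers(1, 3)), i), replace=False):
                edges.add((ids[i], ids[int(p)], "is_a"))
        graph = GoGraph(
            terms=[GoTerm(id=i, aspect="BP") for i in ids], edges=edges, aspect="BP"
        )
        counts = {i: int(rng.integers(0, 5)) for i in ids}
        threshold = 2
        if max(counts.values()) < threshold:
            counts[ids[0]] = threshold
        space = prune_by_frequency(graph, annotations_from_counts(counts), threshold)
        closure = nx.transitive_closure(graph.to_networkx())
        pruned_closure = nx.transitive_closure(space.graph.to_networkx())
        retained = space.term_ids
        for a in retained:
            for b in retained:
                if a == b:
                    continue
                assert pruned_closure.has_edge(a, b) == closure.has_edge(a, b)


class TestNormalizedAdjacency:
    def test_isolated_node(self):
        graph = GoGraph(terms=[GoTerm(id="GO:0000001", aspect="BP")], edges=set())
        assert normalized_adjacency(graph) == pytest.approx(np.array([[1.0]]))

    def test_three_node_path(self):
        # a—b—c: degrees (with self-loop) 2, 3, 2
        graph = chain_graph(["GO:0000001", "GO:0000002", "GO:0000003"])
        a_hat = normalized_adjacency(graph)
        assert np.diag(a_hat) == pytest.approx([1 / 2, 1 / 3, 1 / 2])
        assert a_hat[0, 1] == pytest.approx(1 / np.sqrt(6))
        assert a_hat[1, 2] == pytest.approx(1 / np.sqrt(6))
        assert a_hat[0, 2] == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_spectral_bound(self, seed):
        graph = _random_graph(seed)
        a_hat = normalized_adjacency(graph)
        assert np.array_equal(a_hat, a_hat.T)
        eigvals = np.linalg.eigvalsh(a_hat)
        assert eigvals.min() >= -1 - 1e-10
        assert eigvals.max() <= 1 + 1e-10
        assert (a_hat >= 0).all()


def _random_graph(seed, max_n=15):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, max_n))
    ids = [f"GO:{i:07d}" for i in range(1, n + 1)]
    edges = set()
    for i in range(1, n):
        if rng.random() < 0.8:
            p = int(rng.integers(0, i))
            edges.add((ids[i], ids[p], "is_a"))
    return GoGraph(
        terms=[GoTerm(id=i, aspect="BP") for i in ids], edges=edges, aspect="BP"
    )


class TestBuildLabelMatrix:
    def _space(self):
        graph = chain_graph(["GO:0000002", "GO:0000001"])  # child -> parent
        ann = annotations_from_counts({"GO:0000001": 1, "GO:0000002": 1})
        return prune_by_frequency(graph, ann, 0)

    def test_hand_written_table(self):
        space = self._space()
        ann = pd.DataFrame(
            [("pA", "GO:0000001", "BP"), ("pB", "GO:0000002", "BP")],
            columns=["protein_id", "go_id", "aspect"],
        )
        y = build_label_matrix(space, ann, ["pA", "pB"])
        assert y.tolist() == [[1, 0], [0, 1]]

    def test_empty_annotations(self):
        space = self._space()
        y = build_label_matrix(
            space, pd.DataFrame(columns=["protein_id", "go_id"]), ["pA", "pB"]
        )
        assert not y.any()

    def test_propagation_sets_ancestors(self):
        space = self._space()
        ann = pd.DataFrame(
            [("pA", "GO:0000002", "BP")], columns=["protein_id", "go_id", "aspect"]
        )
        y_off = build_label_matrix(space, ann, ["pA"], propagate=False)
        y_on = build_label_matrix(space, ann, ["pA"], propagate=True)
        assert y_off.tolist() == [[0, 1]]
        assert y_on.tolist() == [[1, 1]]

    def test_propagation_matches_reachability_oracle(self):
        graph = _random_graph(3, max_n=12)
        ann = pd.DataFrame(
            [("pA", t.id, "BP") for t in graph.terms[-2:]],
            columns=["protein_id", "go_id", "aspect"],
        )
        space = prune_by_frequency(graph, annotations_from_counts({}), 0)
        y = build_label_matrix(space, ann, ["pA"], propagate=True)
        expected = set()
        g = graph.to_networkx()
        for t in graph.terms[-2:]:
            expected |= {t.id} | nx.descendants(g, t.id)
        assert {tid for tid in space.term_ids if y[0, space.graph.index[tid]]} == expected

    def test_column_sums_equal_frequencies_without_propagation(self, small_cohort):
        cohort, graphs = small_cohort
        space = prune_by_frequency(graphs["BP"], cohort.annotations, 3)
        y = build_label_matrix(space, cohort.annotations, cohort.protein_ids)
        for tid in space.term_ids:
            assert y[:, space.graph.index[tid]].sum() == space.frequencies[tid]
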