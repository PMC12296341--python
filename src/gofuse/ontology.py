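"""Gene Ontology graph handling: OBO parsing, per-aspect subontologies,
frequency pruning of the label space and the normalized adjacency used by
the graph-convolution head.

GO organizes gene-product function as a directed acyclic graph in three
aspects — biological process (BP), molecular function (MF) and cellular
component (CC).  Each aspect is modeled separately: its terms define the
columns of a binary label matrix, and its ``is_a``/``part_of`` hierarchy
supplies relational structure to the predictor via a degree-normalized,
self-looped symmetric adjacency Â = D^{-1/2}(A + I)D^{-1/2}.

Because the GO label space is extremely long-tailed, terms annotated to
fewer proteins than a frequency threshold are pruned before training.
Pruned nodes are contracted rather than simply dropped: each pruned node's
children are reconnected to its parents, so ancestor paths between retained
terms survive pruning.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

ASPECTS = ("BP", "MF", "CC")
_NAMESPACE_TO_ASPECT = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}
KEPT_RELATIONS = ("is_a", "part_of")
_GO_ID_RE = re.compile(r"^GO:\d{7}$")
_DEF_RE = re.compile(r'^"(?P<text>.*)"\s*(?:\[.*\])?\s*$', re.DOTALL)


@dataclass(frozen=True)
class GoTerm:
    """A single GO term (one node of an aspect DAG)."""

    id: str
    name: str = ""
    definition: str = ""
    aspect: str = ""
    obsolete: bool = False

    def __post_init__(self):
        if self.aspect and self.aspect not in ASPECTS:
            raise ValueError(f"unknown aspect {self.aspect!r} for {self.id}")


@dataclass
class GoGraph:
    """One aspect's DAG with a deterministic term ordering.

    ``edges`` holds directed child→parent pairs typed ``is_a`` or
    ``part_of``; ``index`` maps term id to its column in the label space
    (lexicographic by GO id).
    """

    terms: list[GoTerm]
    edges: set[tuple[str, str, str]]
    aspect: str = ""
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.terms = sorted(self.terms, key=lambda t: t.id)
        if not self.index:
            self.index = {t.id: i for i, t in enumerate(self.terms)}
        ids = set(self.index)
        for child, parent, rel in self.edges:
            if child not in ids or parent not in ids:
                raise ValueError(f"edge endpoint not in graph: {child}->{parent}")
            if rel not in KEPT_RELATIONS:
                raise ValueError(f"unsupported relation {rel!r}")
        if not nx.is_directed_acyclic_graph(self.to_networkx()):
            raise ValueError("GO graph contains a cycle")

    @property
    def gamma(self) -> int:
        return len(self.terms)

    def term(self, term_id: str) -> GoTerm:
        return self.terms[self.index[term_id]]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(t.id for t in self.terms)
        for child, parent, rel in self.edges:
            g.add_edge(child, parent, relation=rel)
        return g

    def ancestors(self, term_id: str) -> set[str]:
        """All terms reachable from ``term_id`` along child→parent edges."""
        return nx.descendants(self.to_networkx(), term_id)


@dataclass
class LabelSpace:
    """Pruned per-aspect label space with its normalized adjacency."""

    graph: GoGraph
    adjacency_hat: np.ndarray
    frequencies: dict[str, int]
    threshold: int

    @property
    def gamma(self) -> int:
        return self.graph.gamma

    @property
    def term_ids(self) -> list[str]:
        return [t.id for t in self.graph.terms]

    def save(self, prefix: str | Path) -> None:
        """Write manifest JSON and the dense adjacency with a sidecar."""
        prefix = Path(prefix)
        manifest = {
            "aspect": self.graph.aspect,
            "threshold": self.threshold,
            "term_order": self.term_ids,
            "frequencies": self.frequencies,
        }
        prefix.with_suffix(".json").write_text(json.dumps(manifest, indent=1))
        np.save(prefix.with_suffix(".adjacency.npy"), self.adjacency_hat)
        prefix.with_suffix(".adjacency.json").write_text(
            json.dumps({"term_order": self.term_ids})
        )


def read_obo(path: str | Path) -> tuple[list[GoTerm], set[tuple[str, str, str]]]:
    """Parse an OBO ontology into terms and typed child→parent edges.

    Obsolete terms are excluded, ``def:`` strings are stripped of quotes and
    trailing citation brackets, and only ``is_a``/``part_of`` edges are kept.
    A term stanza without a namespace is a parse error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms: list[GoTerm] = []
    for node, data in graph.nodes(data=True):
        namespace = data.get("namespace")
        if namespace is None:
            raise ValueError(f"term stanza {node} has no namespace")
        if namespace not in _NAMESPACE_TO_ASPECT:
            raise ValueError(f"term stanza {node}: unknown namespace {namespace!r}")
        definition = data.get("def", "")
        m = _DEF_RE.match(definition)
        if m:
            definition = m.group("text")
        terms.append(
            GoTerm(
                id=node,
                name=data.get("name", ""),
                definition=definition,
                aspect=_NAMESPACE_TO_ASPECT[namespace],
            )
        )
    edges = {
        (child, parent, rel)
        for child, parent, rel in graph.edges(keys=True)
        if rel in KEPT_RELATIONS
    }
    return terms, edges


def split_subontology(
    terms: list[GoTerm], edges: set[tuple[str, str, str]], aspect: str
) -> GoGraph:
    """Induced subgraph on one aspect; cross-aspect edges are discarded."""
    if aspect not in ASPECTS:
        raise ValueError(f"aspect must be one of {ASPECTS}, got {aspect!r}")
    kept = [t for t in terms if t.aspect == aspect]
    if not kept:
        raise ValueError(f"no terms for aspect {aspect}")
    ids = {t.id for t in kept}
    kept_edges = {
        (c, p, r) for c, p, r in edges if c in ids and p in ids
    }
    return GoGraph(terms=kept, edges=kept_edges, aspect=aspect)


def _count_frequencies(graph: GoGraph, annotations: pd.DataFrame) -> dict[str, int]:
    """Annotation count per term (unique proteins), zero for unannotated."""
    freqs = dict.fromkeys(graph.index, 0)
    in_graph = annotations[annotations["go_id"].isin(freqs)]
    counts = in_graph.drop_duplicates(["protein_id", "go_id"])["go_id"].value_counts()
    freqs.update(counts.to_dict())
    return freqs


def prune_by_frequency(
    graph: GoGraph, annotations: pd.DataFrame, threshold: int = 21
) -> LabelSpace:
    """Drop terms annotated fewer than ``threshold`` times, reconnecting
    each pruned node's parents to its children so hierarchy paths survive.

    ``annotations`` is a table with ``protein_id`` and ``go_id`` columns.
    The default threshold of 21 corresponds to roughly 0.015% of a
    CAFA5-sized cohort; pass 0 to disable pruning.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    freqs = _count_frequencies(graph, annotations)
    retained = [t for t in graph.terms if freqs[t.id] >= threshold]
    if not retained:
        raise ValueError(
            f"threshold {threshold} prunes every term: empty label space"
        )
    g = graph.to_networkx()
    for node in [t.id for t in graph.terms if freqs[t.id] < threshold]:
        children = list(g.predecessors(node))
        parents = list(g.successors(node))
        for c in children:
            for p in parents:
                if c != p and not g.has_edge(c, p):
                    g.add_edge(c, p, relation="is_a")
        g.remove_node(node)
    edges = {
        (c, p, d.get("relation", "is_a")) for c, p, d in g.edges(data=True)
    }
    pruned_graph = GoGraph(terms=retained, edges=edges, aspect=graph.aspect)
    return LabelSpace(
        graph=pruned_graph,
        adjacency_hat=normalized_adjacency(pruned_graph),
        frequencies=freqs,
        threshold=threshold,
    )


def auto_threshold(n_samples: int, fraction: float = 0.00015) -> int:
    """Frequency threshold as a fraction of the cohort size (≥ 1)."""
    return max(1, round(n_samples * fraction))


def normalized_adjacency(graph: GoGraph) -> np.ndarray:
    """Â = D^{-1/2}(A + I)D^{-1/2} over the undirected is_a ∪ part_of edges.

    A is the symmetrized 0/1 edge matrix and D the degree matrix of A + I;
    the result is symmetric with entries in (0, 1] and spectrum in [-1, 1].
    """
    gamma = graph.gamma
    a = np.zeros((gamma, gamma))
    for child, parent, _ in graph.edges:
        i, j = graph.index[child], graph.index[parent]
        a[i, j] = a[j, i] = 1.0
    a_tilde = a + np.eye(gamma)
    d_inv_sqrt = 1.0 / np.sqrt(a_tilde.sum(axis=1))
    a_hat = a_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    return (a_hat + a_hat.T) / 2.0  # enforce exact symmetry


def build_label_matrix(
    label_space: LabelSpace,
    annotations: pd.DataFrame,
    protein_order: list[str],
    propagate: bool = False,
) -> np.ndarray:
    """Binary n×γ matrix: Y[i, j] = 1 iff protein i carries retained term j.

    Annotations to pruned terms are dropped.  With ``propagate=True`` each
    positive term also sets all its ancestors within the aspect (the GO
    true-path rule); off by default because CAFA-style label files are
    conventionally pre-propagated.
    """
    graph = label_space.graph
    y = np.zeros((len(protein_order), graph.gamma), dtype=np.int8)
    row = {p: i for i, p in enumerate(protein_order)}
    anc_cache: dict[str, set[str]] = {}
    g = graph.to_networkx()
    for protein_id, go_id in annotations[["protein_id", "go_id"]].itertuples(
        index=False
    ):
        if protein_id not in row or go_id not in graph.index:
            continue
        i = row[protein_id]
        y[i, graph.index[go_id]] = 1
        if propagate:
            if go_id not in anc_cache:
                anc_cache[go_id] = nx.descendants(g, go_id)
            for anc in anc_cache[go_id]:
                y[i, graph.index[anc]] = 1
    empty = [p for p in protein_order if not y[row[p]].any()]
    if empty:
        logger.warning(
            "%d protein(s) have no annotations after pruning (all-zero rows)",
            len(empty),
        )
    return y
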