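"""Synthetic desk-scale cohorts with planted, recoverable signal.

The generator emulates the structure the fusion pipeline exploits, without
pretending to reproduce real embedding geometry:

* a rooted random DAG per aspect plays the GO subontology, with synthetic
  names/definitions attached to each term;
* labels are drawn at leaf terms and propagated to ancestors, so they are
  true-path-consistent — the hierarchical coherence the graph-convolution
  head presupposes;
* per-residue sequence embeddings are a label-driven mean shift
  ``signal_strength · G·y`` (G a fixed random mixing matrix) broadcast over
  residues plus i.i.d. Gaussian noise, mimicking a protein language model
  whose pooled embedding is linearly predictive of function;
* term-description embeddings share the same mixing matrix (projected to
  the text width d′), so the cosine relevance filter has genuine signal
  to find;
* species ids modulate the prevalence of a fraction of leaf terms, giving
  the taxonomy encoder a weak but real cue.

Everything is driven by a single seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .data_io import Cohort, EmbeddingArchive
from .ontology import ASPECTS, GoGraph, GoTerm

_ASPECT_OFFSET = {"BP": 1_000_000, "MF": 2_000_000, "CC": 3_000_000}
_ASPECT_NAMESPACE = {
    "BP": "biological_process",
    "MF": "molecular_function",
    "CC": "cellular_component",
}


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort.

    Defaults are sized so a full train+evaluate cycle runs in well under a
    minute on one CPU while leaving enough signal for the pipeline to
    recover (held-out micro-AUPR ≈ 0.9+ at the default signal strength).
    """

    n_proteins: int = 500
    gamma_per_aspect: int = 30
    d: int = 64                      # sequence embedding width
    d_prime: int = 48                # text embedding width
    seq_length_range: tuple[int, int] = (20, 60)    # residues l
    text_length_range: tuple[int, int] = (5, 15)    # tokens l'
    signal_strength: float = 5.0     # scale of the label-driven mean shift
    noise_sd: float = 1.0
    text_relevance: float = 0.8      # 0..1: term-text correlation with its signal
    taxonomy_effect: float = 0.2     # fraction of leaf terms modulated by species
    n_species: int = 10
    leaf_rate: float = 0.12          # per-leaf positive probability
    aspects: tuple[str, ...] = ASPECTS
    seed: int = 0

    def __post_init__(self):
        if min(self.n_proteins, self.gamma_per_aspect, self.d, self.d_prime) < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.text_relevance <= 1:
            raise ValueError("text_relevance must lie in [0, 1]")
        for a in self.aspects:
            if a not in ASPECTS:
                raise ValueError(f"unknown aspect {a!r}")


def synthetic_term_id(aspect: str, i: int) -> str:
    return f"GO:{_ASPECT_OFFSET[aspect] + i + 1:07d}"


def generate_dag(gamma: int, seed: int, aspect: str = "BP") -> GoGraph:
    """Random rooted DAG: node 0 is the root, each later node gets 1–2
    parents drawn from earlier nodes (acyclic by construction)."""
    if gamma < 1:
        raise ValueError("gamma must be >= 1")
    rng = np.random.default_rng(seed)
    terms = []
    edges: set[tuple[str, str, str]] = set()
    for i in range(gamma):
        tid = synthetic_term_id(aspect, i)
        terms.append(
            GoTerm(
                id=tid,
                name=f"synthetic {aspect} term {i}",
                definition=f"Synthetic {aspect} activity number {i} "
                f"planted for desk-scale benchmarking.",
                aspect=aspect,
            )
        )
        if i == 0:
            continue
        n_parents = int(rng.integers(1, 3)) if i > 1 else 1
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            rel = "part_of" if rng.random() < 0.2 else "is_a"
            edges.add((tid, synthetic_term_id(aspect, int(p)), rel))
    return GoGraph(terms=terms, edges=edges, aspect=aspect)


def _leaf_indices(graph: GoGraph) -> np.ndarray:
    g = graph.to_networkx()
    return np.array(
        [graph.index[t.id] for t in graph.terms if g.in_degree(t.id) == 0],
        dtype=np.intp,
    )


def _ancestor_matrix(graph: GoGraph) -> np.ndarray:
    """Boolean γ×γ: M[i, j] = 1 iff j is i itself or an ancestor of i."""
    g = graph.to_networkx()
    m = np.eye(graph.gamma, dtype=bool)
    for tid in graph.index:
        i = graph.index[tid]
        for anc in nx.descendants(g, tid):
            m[i, graph.index[anc]] = True
    return m


def generate_cohort(
    config: SimConfig, graphs: dict[str, GoGraph] | None = None
) -> tuple[Cohort, dict[str, GoGraph]]:
    """Draw a full cohort (labels, embeddings, taxonomy) from the config."""
    rng = np.random.default_rng(config.seed)
    if graphs is None:
        graphs = {
            a: generate_dag(config.gamma_per_aspect, config.seed + 7 * k, a)
            for k, a in enumerate(config.aspects)
        }
    else:
        for a in config.aspects:
            if a not in graphs:
                raise ValueError(f"no graph supplied for aspect {a}")
            if graphs[a].gamma != config.gamma_per_aspect:
                raise ValueError(
                    f"graph for {a} has {graphs[a].gamma} terms, "
                    f"config says {config.gamma_per_aspect}"
                )

    n = config.n_proteins
    protein_ids = [f"P{i:05d}" for i in range(n)]
    species = rng.integers(1, config.n_species + 1, size=n)

    # --- labels: leaf sampling + ancestor propagation, species-modulated ---
    labels: dict[str, np.ndarray] = {}
    term_ids: dict[str, list[str]] = {}
    for aspect in config.aspects:
        graph = graphs[aspect]
        leaves = _leaf_indices(graph)
        anc = _ancestor_matrix(graph)
        n_mod = int(round(config.taxonomy_effect * graph.gamma))
        modulated = rng.choice(leaves, size=min(n_mod, leaves.size), replace=False)
        # each modulated leaf prefers half the species
        preferred = {
            int(j): set(
                rng.choice(
                    np.arange(1, config.n_species + 1),
                    size=max(1, config.n_species // 2),
                    replace=False,
                ).tolist()
            )
            for j in modulated
        }
        y = np.zeros((n, graph.gamma), dtype=np.int8)
        for i in range(n):
            p = np.full(leaves.size, config.leaf_rate)
            for pos, j in enumerate(leaves):
                if int(j) in preferred:
                    p[pos] *= 2.0 if int(species[i]) in preferred[int(j)] else 0.4
            draws = rng.random(leaves.size) < p
            if not draws.any():
                draws[rng.integers(leaves.size)] = True
            pos_leaves = leaves[draws]
            y[i] = anc[pos_leaves].any(axis=0)
        labels[aspect] = y
        term_ids[aspect] = [t.id for t in graph.terms]

    y_full = np.concatenate([labels[a] for a in config.aspects], axis=1)
    gamma_total = y_full.shape[1]

    # --- embeddings -------------------------------------------------------
    mixing = rng.normal(size=(config.d, gamma_total)) / np.sqrt(gamma_total)
    text_proj = rng.normal(size=(config.d_prime, config.d)) / np.sqrt(config.d)

    lo, hi = config.seq_length_range
    seq_entries: dict[str, np.ndarray] = {}
    for i, pid in enumerate(protein_ids):
        length = int(rng.integers(lo, hi + 1))
        mean = config.signal_strength * (mixing @ y_full[i])
        seq_entries[pid] = mean[:, None] + config.noise_sd * rng.normal(
            size=(config.d, length)
        )
    seq_archive = EmbeddingArchive(
        entries=seq_entries,
        dim=config.d,
        metadata={"source": "synthetic", "seed": config.seed},
    )

    tlo, thi = config.text_length_range
    text_entries: dict[str, np.ndarray] = {}
    col = 0
    for aspect in config.aspects:
        for tid in term_ids[aspect]:
            length = int(rng.integers(tlo, thi + 1))
            base = text_proj @ (config.signal_strength * mixing[:, col])
            text_entries[tid] = config.text_relevance * base[
                :, None
            ] + config.noise_sd * rng.normal(size=(config.d_prime, length))
            col += 1
    text_archive = EmbeddingArchive(
        entries=text_entries,
        dim=config.d_prime,
        metadata={"source": "synthetic", "seed": config.seed},
    )

    annotations = _labels_to_annotations(protein_ids, labels, term_ids)
    cohort = Cohort(
        protein_ids=protein_ids,
        seq_archive=seq_archive,
        text_archive=text_archive,
        taxonomy={pid: int(s) for pid, s in zip(protein_ids, species)},
        labels=labels,
        label_term_ids=term_ids,
        annotations=annotations,
    )
    return cohort, graphs


def _labels_to_annotations(
    protein_ids: list[str],
    labels: dict[str, np.ndarray],
    term_ids: dict[str, list[str]],
) -> pd.DataFrame:
    rows = []
    for aspect, y in labels.items():
        ids = term_ids[aspect]
        for i, j in zip(*np.nonzero(y)):
            rows.append((protein_ids[i], ids[j], aspect))
    return pd.DataFrame(rows, columns=["protein_id", "go_id", "aspect"])


# --- on-disk cohort ---------------------------------------------------------

def write_obo(graphs: dict[str, GoGraph], path) -> None:
    """Serialize synthetic term DAGs as a minimal OBO 1.2 document."""
    lines = ["format-version: 1.2", ""]
    for aspect in sorted(graphs):
        graph = graphs[aspect]
        children: dict[str, list[tuple[str, str]]] = {t.id: [] for t in graph.terms}
        for c, p, rel in sorted(graph.edges):
            children[c].append((p, rel))
        for term in graph.terms:
            lines.append("[Term]")
            lines.append(f"id: {term.id}")
            lines.append(f"name: {term.name}")
            lines.append(f"namespace: {_ASPECT_NAMESPACE[term.aspect]}")
            lines.append(f'def: "{term.definition}" []')
            for parent, rel in children[term.id]:
                if rel == "is_a":
                    lines.append(f"is_a: {parent}")
                else:
                    lines.append(f"relationship: {rel} {parent}")
            lines.append("")
    with open(path, "w") as f:
        f.write("\n".join(lines))


def write_cohort(cohort: Cohort, graphs: dict[str, GoGraph], out_dir) -> None:
    """Emit a complete on-disk cohort consumable by every pipeline stage:
    OBO ontology, annotation TSV, taxonomy TSV and both embedding archives."""
    from pathlib import Path

    from .data_io import write_archive

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_obo(graphs, out / "ontology.obo")
    cohort.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "protein_id": cohort.protein_ids,
            "species_id": [cohort.taxonomy[p] for p in cohort.protein_ids],
        }
    ).to_csv(out / "taxonomy.tsv", sep="\t", index=False)
    write_archive(cohort.seq_archive, out / "sequence_embeddings.h5")
    write_archive(cohort.text_archive, out / "text_embeddings.h5")


def load_cohort(cohort_dir) -> tuple[Cohort, dict[str, GoGraph]]:
    """Read a cohort directory written by :func:`write_cohort`."""
    from pathlib import Path

    from .data_io import read_annotations, read_archive, read_taxonomy
    from .ontology import build_label_matrix, prune_by_frequency, read_obo, split_subontology

    d = Path(cohort_dir)
    terms, edges = read_obo(d / "ontology.obo")
    aspects = sorted({t.aspect for t in terms}, key=ASPECTS.index)
    graphs = {a: split_subontology(terms, edges, a) for a in aspects}
    annotations = read_annotations(d / "annotations.tsv")
    taxonomy = read_taxonomy(d / "taxonomy.tsv")
    seq_archive = read_archive(d / "sequence_embeddings.h5")
    text_archive = read_archive(d / "text_embeddings.h5")
    protein_ids = list(seq_archive.entries)
    labels, term_ids = {}, {}
    for a, graph in graphs.items():
        space = prune_by_frequency(graph, annotations, threshold=0)
        labels[a] = build_label_matrix(space, annotations, protein_ids)
        term_ids[a] = space.term_ids
    return (
        Cohort(
            protein_ids=protein_ids,
            seq_archive=seq_archive,
            text_archive=text_archive,
            taxonomy=taxonomy,
            labels=labels,
            label_term_ids=term_ids,
            annotations=annotations,
        ),
        graphs,
    )
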