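"""Cohort I/O: embedding archives, annotation/taxonomy tables and
reproducible train/test splits.

Per-residue sequence embeddings (d × l per protein) and per-token GO-term
description embeddings (d′ × l′ per term) are produced upstream by a
protein language model / biomedical language model and exchanged through
:class:`EmbeddingArchive` — an HDF5 container plus a JSON sidecar that
pins entry order, dimensionality and provenance, with a bit-exact
round-trip guarantee.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

UNKNOWN_SPECIES = 0


@dataclass
class EmbeddingArchive:
    """Ordered map from entity id (protein or GO term) to a dense
    (dim × length) matrix of per-position embeddings."""

    entries: dict[str, np.ndarray]
    dim: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for key, mat in self.entries.items():
            if mat.ndim != 2 or mat.shape[0] != self.dim:
                raise ValueError(
                    f"entry {key!r} has shape {mat.shape}, expected ({self.dim}, L)"
                )
            if mat.shape[1] < 1:
                raise ValueError(f"entry {key!r} has zero length")

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.entries[key]

    def __contains__(self, key: str) -> bool:
        return key in self.entries

    def subset(self, keys: list[str]) -> "EmbeddingArchive":
        return EmbeddingArchive(
            entries={k: self.entries[k] for k in keys},
            dim=self.dim,
            metadata=dict(self.metadata),
        )


def _sidecar(path: str | Path) -> Path:
    return Path(str(path) + ".json")


def write_archive(archive: EmbeddingArchive, path: str | Path) -> None:
    """Write HDF5 container + JSON sidecar (ids, dim, metadata)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for i, (key, mat) in enumerate(archive.entries.items()):
            f.create_dataset(f"e{i}", data=mat)
    _sidecar(path).write_text(
        json.dumps(
            {
                "ids": list(archive.entries),
                "dim": archive.dim,
                "metadata": archive.metadata,
            }
        )
    )


def read_archive(path: str | Path) -> EmbeddingArchive:
    """Inverse of :func:`write_archive`; round-trip is bit-exact."""
    path = Path(path)
    if not path.exists() or not _sidecar(path).exists():
        raise FileNotFoundError(f"archive {path} (or its JSON sidecar) missing")
    meta = json.loads(_sidecar(path).read_text())
    with h5py.File(path, "r") as f:
        entries = {key: f[f"e{i}"][()] for i, key in enumerate(meta["ids"])}
    return EmbeddingArchive(entries=entries, dim=meta["dim"], metadata=meta["metadata"])


def read_taxonomy(path: str | Path) -> dict[str, int]:
    """Read a ``protein_id<TAB>species_id`` table.

    Missing/empty species map to the reserved code 0; duplicated protein
    rows with conflicting species raise.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    if list(df.columns[:2]) != ["protein_id", "species_id"]:
        raise ValueError("taxonomy table must have protein_id/species_id columns")
    out: dict[str, int] = {}
    for pid, sid in df[["protein_id", "species_id"]].itertuples(index=False):
        code = UNKNOWN_SPECIES if pd.isna(sid) else int(sid)
        if pid in out and out[pid] != code:
            raise ValueError(f"conflicting species for protein {pid!r}")
        out[pid] = code
    return out


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a ``protein_id<TAB>go_id<TAB>aspect`` annotation table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "go_id"}
    if not required.issubset(df.columns):
        raise ValueError("annotation table must have protein_id/go_id columns")
    return df


def fasta_lengths(path: str | Path) -> dict[str, int]:
    """Extract id → sequence length from a FASTA file (validation only)."""
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


@dataclass
class Cohort:
    """n proteins with their embeddings, species codes and label matrices.

    ``labels`` maps aspect → binary (n × γ) matrix aligned with
    ``protein_ids`` rows and ``label_term_ids[aspect]`` columns.
    """

    protein_ids: list[str]
    seq_archive: EmbeddingArchive
    text_archive: EmbeddingArchive
    taxonomy: dict[str, int]
    labels: dict[str, np.ndarray] = field(default_factory=dict)
    label_term_ids: dict[str, list[str]] = field(default_factory=dict)
    annotations: pd.DataFrame | None = None

    def __post_init__(self):
        for pid in self.protein_ids:
            if pid not in self.seq_archive:
                raise ValueError(f"protein {pid!r} missing from sequence archive")
            if pid not in self.taxonomy:
                raise ValueError(f"protein {pid!r} missing from taxonomy")
        for aspect, y in self.labels.items():
            if y.shape[0] != len(self.protein_ids):
                raise ValueError(f"label matrix for {aspect} has wrong row count")

    @property
    def n(self) -> int:
        return len(self.protein_ids)

    def species_codes(self) -> np.ndarray:
        return np.array([self.taxonomy[p] for p in self.protein_ids], dtype=np.intp)

    def take(self, rows: np.ndarray) -> "Cohort":
        ids = [self.protein_ids[i] for i in rows]
        return replace(
            self,
            protein_ids=ids,
            seq_archive=self.seq_archive.subset(ids),
            labels={a: y[rows] for a, y in self.labels.items()},
        )


def split_cohort(
    cohort: Cohort, test_fraction: float = 0.1, seed: int = 0
) -> tuple[Cohort, Cohort]:
    """Seeded random partition with a training-coverage guarantee.

    Every label-space term must have at least one positive training
    example; after the random split, each uncovered term's lowest-indexed
    carrier protein is reassigned to the train side.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    n = cohort.n
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(n * test_fraction)))
    test_mask = np.zeros(n, dtype=bool)
    test_mask[perm[:n_test]] = True
    for aspect, y in cohort.labels.items():
        uncovered = np.flatnonzero(y[~test_mask].sum(axis=0) == 0)
        for j in uncovered:
            carriers = np.flatnonzero(y[:, j])
            if carriers.size == 0:
                continue  # term with no carrier anywhere: nothing to repair
            test_mask[carriers[0]] = False
    if not test_mask.any():
        raise ValueError("coverage repair emptied the test split")
    train = cohort.take(np.flatnonzero(~test_mask))
    test = cohort.take(np.flatnonzero(test_mask))
    return train, test
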