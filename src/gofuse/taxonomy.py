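"""Taxonomy encoding: pool fused residue-level features to protein level
and mix in a species code via a learned label-encoding table.

X_mix = LE(species) · w_tax + X_pro, where X_pro is the arithmetic mean of
the fused features over all sequence and selected-text positions, LE is a
learnable (n_species + 1) × d embedding table (row 0 reserved for unknown
species) and w_tax a fixed scalar weight, 0.1 by default.  Only the leaf
rank of the taxonomy (the species itself) is encoded.  Setting w_tax = 0
reproduces the no-taxonomy ablation bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .alignment import FusedFeatures

__all__ = ["TaxonomyEncoder", "MixedFeature", "pool_protein", "mix"]


@dataclass
class TaxonomyEncoder:
    """Learned species-embedding table with a fixed mixing weight."""

    table: Tensor          # (n_species + 1) × d, row 0 = unknown
    w_tax: float = 0.1
    learnable_weight: Tensor | None = None   # optional learned scalar mode

    def __post_init__(self):
        if self.table.shape[0] < 1:
            raise ValueError("embedding table needs at least one row")
        if self.w_tax < 0:
            raise ValueError("w_tax must be non-negative")

    @classmethod
    def init(
        cls,
        n_species: int,
        d: int,
        rng: np.random.Generator,
        w_tax: float = 0.1,
        init_sd: float = 0.02,
        learnable_weight: bool = False,
    ) -> "TaxonomyEncoder":
        table = Tensor(
            rng.normal(scale=init_sd, size=(n_species + 1, d)), requires_grad=True
        )
        lw = Tensor(np.array(w_tax), requires_grad=True) if learnable_weight else None
        return cls(table=table, w_tax=w_tax, learnable_weight=lw)

    @property
    def n_species(self) -> int:
        return self.table.shape[0] - 1

    def parameters(self) -> list[Tensor]:
        ps = [self.table]
        if self.learnable_weight is not None:
            ps.append(self.learnable_weight)
        return ps

    def row_index(self, species_id: int) -> int:
        """Unknown or out-of-vocabulary species map to the reserved row 0."""
        if 0 <= species_id <= self.n_species:
            return int(species_id)
        return 0

    def contribution(self, species_id: int) -> Tensor:
        row = self.table.gather_rows(np.array([self.row_index(species_id)]))
        row = row.reshape(self.table.shape[1])
        if self.learnable_weight is not None:
            return row * self.learnable_weight
        return row * self.w_tax


@dataclass
class MixedFeature:
    """Protein-level mixed feature vector with provenance flags."""

    vector: np.ndarray
    text_used: bool = False
    taxonomy_known: bool = False

    def __post_init__(self):
        if not np.isfinite(self.vector).all():
            raise ValueError("non-finite mixed feature")


def pool_protein(fused: FusedFeatures | np.ndarray | Tensor) -> Tensor:
    """Mean over all positions (sequence and selected-text jointly),
    yielding the protein-level d-vector X_pro."""
    if isinstance(fused, FusedFeatures):
        tensor = fused.tensor            # L × d
    elif isinstance(fused, Tensor):
        tensor = fused
    else:
        tensor = Tensor(np.asarray(fused).T)   # accept d × L archive layout
    if tensor.shape[0] < 1:
        raise ValueError("cannot pool zero positions")
    return tensor.mean(axis=0)


def mix(
    x_pro: Tensor | np.ndarray,
    species_id: int,
    encoder: TaxonomyEncoder,
    text_used: bool = False,
) -> MixedFeature:
    """Species mixing: table[species] · w_tax + x_pro (numpy-facing)."""
    x = x_pro.data if isinstance(x_pro, Tensor) else np.asarray(x_pro, dtype=float)
    contrib = encoder.contribution(species_id).data
    return MixedFeature(
        vector=contrib + x,
        text_used=text_used,
        taxonomy_known=encoder.row_index(species_id) != 0,
    )


def mix_tensor(x_pro: Tensor, species_id: int, encoder: TaxonomyEncoder) -> Tensor:
    """Tape-connected version of :func:`mix` used during training."""
    return encoder.contribution(species_id) + x_pro
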