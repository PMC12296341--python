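"""Text–sequence alignment: relevance filtering and attention fusion.

A protein's per-residue embedding (d × l) is fused with the embeddings of
GO-term descriptions (d′ × l′ each) in two steps:

1. *Relevance selection.*  Each candidate text is projected to the
   sequence width d through a learnable linear map, then scored by the
   mean per-position cosine between projected text column k and sequence
   column k (k up to min(l, l′)).  Texts with positive relevance are kept,
   sorted by descending relevance (ties by GO id) and capped at
   ``top_k_texts``.

2. *Fusion.*  Sinusoidal positional encodings are added to the sequence
   and each selected text; the matrices are concatenated along positions,
   split into fragments of at most ``fragment_length`` positions, and each
   fragment passes through parameter-free multi-head dot-product
   attention — the input serves as query, key and value, heads are
   contiguous d/h row slices with per-head scale sqrt(d/h) — followed by a
   position-wise feed-forward network with a residual connection.

All learnable capacity lives in the text projection and the FFN; an
optional switch adds learned per-head query/key/value projections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, relu, softmax

__all__ = [
    "AlignmentParams",
    "FusedFeatures",
    "positional_encode",
    "positional_encoding_table",
    "relevance_select",
    "fuse",
]


def positional_encoding_table(d: int, length: int) -> np.ndarray:
    """Sinusoid table, shape (d, length): row 2i is sin(pos/10000^(2i/d)),
    row 2i+1 the matching cosine."""
    pos = np.arange(length)[None, :]
    i = np.arange(d)[:, None]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table


def positional_encode(matrix: np.ndarray) -> np.ndarray:
    """Add the standard sinusoidal positional encoding to a d × L matrix."""
    d, length = matrix.shape
    return matrix + positional_encoding_table(d, length)


@dataclass
class AlignmentParams:
    """Learnable pieces of the alignment module plus its hyperparameters."""

    text_projection: Tensor          # d × d′
    ffn_w1: Tensor                   # d × 2d
    ffn_b1: Tensor                   # 2d
    ffn_w2: Tensor                   # 2d × d
    ffn_b2: Tensor                   # d
    n_heads: int = 8
    fragment_length: int = 512
    top_k_texts: int = 5
    dropout: float = 0.3
    use_positional_encoding: bool = True
    qkv: tuple[Tensor, Tensor, Tensor] | None = None   # optional learned Q/K/V

    def __post_init__(self):
        d = self.text_projection.shape[0]
        if d % self.n_heads != 0:
            raise ValueError(f"d={d} not divisible by n_heads={self.n_heads}")
        if self.fragment_length < 1 or self.top_k_texts < 0:
            raise ValueError("fragment_length must be >= 1 and top_k_texts >= 0")

    @property
    def d(self) -> int:
        return self.text_projection.shape[0]

    @classmethod
    def init(
        cls,
        d: int,
        d_prime: int,
        rng: np.random.Generator,
        n_heads: int = 8,
        fragment_length: int = 512,
        top_k_texts: int = 5,
        dropout: float = 0.3,
        learned_qkv: bool = False,
        use_positional_encoding: bool = True,
    ) -> "AlignmentParams":
        def kaiming(fan_in, shape):
            return Tensor(
                rng.normal(size=shape) * np.sqrt(2.0 / fan_in), requires_grad=True
            )

        qkv = None
        if learned_qkv:
            qkv = tuple(kaiming(d, (d, d)) for _ in range(3))
        return cls(
            text_projection=kaiming(d_prime, (d, d_prime)),
            ffn_w1=kaiming(d, (d, 2 * d)),
            ffn_b1=Tensor(np.zeros(2 * d), requires_grad=True),
            ffn_w2=kaiming(2 * d, (2 * d, d)),
            ffn_b2=Tensor(np.zeros(d), requires_grad=True),
            n_heads=n_heads,
            fragment_length=fragment_length,
            top_k_texts=top_k_texts,
            dropout=dropout,
            use_positional_encoding=use_positional_encoding,
            qkv=qkv,
        )

    def parameters(self) -> list[Tensor]:
        ps = [self.text_projection, self.ffn_w1, self.ffn_b1, self.ffn_w2, self.ffn_b2]
        if self.qkv is not None:
            ps.extend(self.qkv)
        return ps


@dataclass
class FusedFeatures:
    """Attention output over the concatenated sequence+text positions.

    ``tensor`` is (L_total × d) with positions as rows (kept on the
    autodiff tape so pooling feeds gradients back into the projection and
    FFN); ``sequence_mask`` marks which positions came from the sequence;
    ``attention`` holds the per-fragment, per-head weight matrices.
    """

    tensor: Tensor
    sequence_mask: np.ndarray
    attention: list[np.ndarray] = field(default_factory=list)
    selected_terms: list[str] = field(default_factory=list)

    @property
    def matrix(self) -> np.ndarray:
        """d × (l + Σ l′) view, matching the archive orientation."""
        return self.tensor.data.T


def _cosine_relevance(projected: np.ndarray, seq: np.ndarray) -> float:
    """Mean per-position cosine between two d × L matrices: position k of
    the text is scored against position k of the sequence."""
    k = min(projected.shape[1], seq.shape[1])
    a, b = projected[:, :k], seq[:, :k]
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    denom = na * nb
    cos = np.zeros(k)
    ok = denom > 0
    cos[ok] = (a[:, ok] * b[:, ok]).sum(axis=0) / denom[ok]
    return float(cos.mean())


def relevance_select(
    seq: np.ndarray,
    texts: dict[str, np.ndarray],
    params: AlignmentParams,
) -> list[tuple[str, float]]:
    """Score every candidate term text against the sequence and keep those
    with positive relevance, best first (ties broken by term id), capped at
    ``params.top_k_texts``.  May return an empty list."""
    proj = params.text_projection.data
    scored = []
    for term_id, text in texts.items():
        relevance = _cosine_relevance(proj @ text, seq)
        if relevance > 0:
            scored.append((term_id, relevance))
    scored.sort(key=lambda item: (-item[1], item[0]))
    return scored[: params.top_k_texts]


def _fragment_runs(run_lengths: list[int], max_len: int) -> list[int]:
    """Pack position runs (sequence, then each text) into fragments of at
    most ``max_len`` positions.  A run is never split across fragments
    unless it alone exceeds ``max_len``; a text may share a fragment with
    preceding positions.  Returns fragment sizes."""
    sizes: list[int] = []
    current = 0
    for run in run_lengths:
        if current and current + run > max_len:
            sizes.append(current)
            current = 0
        while run > max_len:
            sizes.append(max_len)
            run -= max_len
        current += run
    if current:
        sizes.append(current)
    return sizes


def _attend(x: Tensor, params: AlignmentParams) -> tuple[Tensor, np.ndarray]:
    """Multi-head dot-product attention on one fragment (x: L × d)."""
    length, d = x.shape
    h = params.n_heads
    dh = d // h
    if params.qkv is not None:
        q, k, v = (x @ w for w in params.qkv)
    else:
        q = k = v = x
    # (L, d) -> (h, L, dh)
    qh = q.reshape(length, h, dh).transpose(1, 0, 2)
    kh = k.reshape(length, h, dh).transpose(1, 0, 2)
    vh = v.reshape(length, h, dh).transpose(1, 0, 2)
    scores = (qh @ kh.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))
    weights = softmax(scores, axis=-1)
    out = weights @ vh
    merged = out.transpose(1, 0, 2).reshape(length, d)
    return merged, weights.data


def fuse(
    seq: np.ndarray,
    selected: list[tuple[str, float]],
    texts: dict[str, np.ndarray],
    params: AlignmentParams,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> FusedFeatures:
    """Concatenate PE(sequence) with PE(projected selected texts), run
    fragment-wise multi-head attention and the residual FFN.

    With an empty selection the same operator runs on the sequence alone.
    """
    if not np.isfinite(seq).all():
        raise ValueError("non-finite values in sequence embedding")
    blocks: list[Tensor] = []
    runs: list[int] = [seq.shape[1]]
    seq_in = positional_encode(seq) if params.use_positional_encoding else seq
    blocks.append(Tensor(seq_in.T))  # positions as rows
    for term_id, _ in selected:
        text = texts[term_id]
        if not np.isfinite(text).all():
            raise ValueError(f"non-finite values in text embedding {term_id}")
        projected = params.text_projection @ Tensor(text)  # d × l′
        if params.use_positional_encoding:
            projected = projected + Tensor(
                positional_encoding_table(params.d, text.shape[1])
            )
        blocks.append(projected.T)
        runs.append(text.shape[1])
    x = concat(blocks, axis=0) if len(blocks) > 1 else blocks[0]

    frag_sizes = _fragment_runs(runs, params.fragment_length)
    outputs: list[Tensor] = []
    attn_maps: list[np.ndarray] = []
    start = 0
    for size in frag_sizes:
        if len(frag_sizes) == 1:
            frag = x
        else:
            frag = _slice_rows(x, start, size)
        attended, weights = _attend(frag, params)
        if training and params.dropout > 0:
            if rng is None:
                raise ValueError("training-mode fuse() needs an rng for dropout")
            mask = (rng.random(attended.shape) >= params.dropout) / (
                1.0 - params.dropout
            )
            attended = attended * Tensor(mask)
        hidden = relu(attended @ params.ffn_w1 + params.ffn_b1)
        out = attended + (hidden @ params.ffn_w2 + params.ffn_b2)
        outputs.append(out)
        attn_maps.append(weights)
        start += size
    fused = concat(outputs, axis=0) if len(outputs) > 1 else outputs[0]
    mask = np.zeros(sum(runs), dtype=bool)
    mask[: runs[0]] = True
    return FusedFeatures(
        tensor=fused,
        sequence_mask=mask,
        attention=attn_maps,
        selected_terms=[t for t, _ in selected],
    )


def _slice_rows(x: Tensor, start: int, size: int) -> Tensor:
    data = x.data[start : start + size]
    shape = x.shape

    def backward(g):
        out = np.zeros(shape)
        out[start : start + size] = g
        return (out,)

    return x._make(data, (x,), backward)
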