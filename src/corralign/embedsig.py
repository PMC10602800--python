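"""Fixed-size embedding signatures via 2D-DCT truncation, L1 distances, and
distance-based gating of alignment parameters.

A per-residue embedding matrix (length x dim) is reduced to a fixed shape by
taking its orthonormal 2D type-II DCT, keeping the top-left coefficient block,
inverse-transforming at the target size, and rescaling so constant inputs are
preserved.  Two blocks (5x44 and 3x85 by default) form a signature; the
distance between signatures is the elementwise sum of absolute differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dctn, idctn

BLOCK_A_SHAPE = (5, 44)
BLOCK_B_SHAPE = (3, 85)

#: Largest possible quantized distance over both default blocks.
MAX_QUANTIZED_DISTANCE = 255.0 * (
    BLOCK_A_SHAPE[0] * BLOCK_A_SHAPE[1] + BLOCK_B_SHAPE[0] * BLOCK_B_SHAPE[1]
)


class EmbedError(ValueError):
    pass


def compress_embedding(matrix: np.ndarray, target_rows: int, target_cols: int) -> np.ndarray:
    """Reduce an N x D matrix to target_rows x target_cols via DCT truncation.

    Orthonormal DCT-II, truncate to the top-left block, orthonormal inverse at
    the target size, then rescale by sqrt(target_size / input_size) so a
    constant matrix stays constant.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2:
        raise EmbedError(f"expected a 2-D matrix, got shape {matrix.shape}")
    n, d = matrix.shape
    if n < target_rows or d < target_cols:
        raise EmbedError(
            f"input {n}x{d} smaller than target {target_rows}x{target_cols}"
        )
    coeffs = dctn(matrix, norm="ortho")
    block = coeffs[:target_rows, :target_cols]
    out = idctn(block, norm="ortho")
    return out * np.sqrt((target_rows * target_cols) / (n * d))


def quantize(block: np.ndarray) -> np.ndarray:
    """Min-max map a block to integers in [0, 255], rounding half-up.

    A constant block maps to all-128 by convention.
    """
    block = np.asarray(block, dtype=float)
    if not np.all(np.isfinite(block)):
        raise EmbedError("non-finite entries")
    lo, hi = block.min(), block.max()
    if hi == lo:
        return np.full(block.shape, 128, dtype=np.int64)
    scaled = (block - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.int64)


@dataclass
class EmbeddingSignature:
    """Two fixed-shape compressed blocks; optionally uint8-quantized."""

    block_a: np.ndarray
    block_b: np.ndarray
    quantized: bool = True

    def __post_init__(self) -> None:
        self.block_a = np.asarray(self.block_a)
        self.block_b = np.asarray(self.block_b)
        if self.block_a.shape != BLOCK_A_SHAPE or self.block_b.shape != BLOCK_B_SHAPE:
            raise EmbedError(
                f"signature blocks must be {BLOCK_A_SHAPE} and {BLOCK_B_SHAPE}, "
                f"got {self.block_a.shape} and {self.block_b.shape}"
            )
        if self.quantized:
            for blk in (self.block_a, self.block_b):
                if np.any(blk != np.round(blk)) or blk.min() < 0 or blk.max() > 255:
                    raise EmbedError("quantized blocks must be integers in [0, 255]")


def make_signature(
    embedding_a: np.ndarray, embedding_b: np.ndarray, quantized: bool = True
) -> EmbeddingSignature:
    """Compress the two per-layer embedding matrices into one signature."""
    a = compress_embedding(embedding_a, *BLOCK_A_SHAPE)
    b = compress_embedding(embedding_b, *BLOCK_B_SHAPE)
    if quantized:
        a, b = quantize(a), quantize(b)
    return EmbeddingSignature(block_a=a, block_b=b, quantized=quantized)


def embedding_distance(sig1: EmbeddingSignature, sig2: EmbeddingSignature) -> float:
    """Sum of absolute differences over all signature cells."""
    if sig1.quantized != sig2.quantized:
        raise EmbedError("cannot compare quantized with unquantized signatures")
    return float(
        np.abs(sig1.block_a - sig2.block_a).sum() + np.abs(sig1.block_b - sig2.block_b).sum()
    )


@dataclass
class GateSchedule:
    """Distance-banded (corr_cutoff, w2) settings.

    Rows are (distance_upper_bound, corr_cutoff, w2), bounds strictly
    increasing; the terminal row applies beyond the last bound.  Closer
    homologs get a larger w2 and a smaller correlation cutoff.
    """

    rows: list[tuple[float, float, float]]
    terminal: tuple[float, float]

    def __post_init__(self) -> None:
        if not self.rows and self.terminal is None:
            raise EmbedError("empty gate schedule")
        bounds = [r[0] for r in self.rows]
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise EmbedError("schedule bounds must be strictly increasing")
        w2s = [r[2] for r in self.rows] + [self.terminal[1]]
        cuts = [r[1] for r in self.rows] + [self.terminal[0]]
        if any(not (0.0 <= w <= 0.9) for w in w2s):
            raise EmbedError("w2 values must lie in [0, 0.9]")
        if any(w2 < w1 - 1e-12 for w1, w2 in zip(cuts, cuts[1:])):
            raise EmbedError("corr_cutoff must be non-decreasing with distance")
        if any(b2 > b1 + 1e-12 for b1, b2 in zip(w2s, w2s[1:])):
            raise EmbedError("w2 must be non-increasing with distance")


def default_gate_schedule(max_distance: float = MAX_QUANTIZED_DISTANCE) -> GateSchedule:
    """Default gating bands, expressed as fractions of the maximum distance."""
    return GateSchedule(
        rows=[
            (0.20 * max_distance, 0.3, 0.1),
            (0.50 * max_distance, 0.5, 0.05),
        ],
        terminal=(1.1, 0.0),  # cutoff > 1 selects no pairs; single-residue only
    )


def gate_parameters(distance: float, schedule: GateSchedule) -> tuple[float, float]:
    """(corr_cutoff, w2) for a given embedding distance."""
    if distance < 0:
        raise EmbedError("distance must be nonnegative")
    for bound, cutoff, w2 in schedule.rows:
        if distance <= bound:
            return cutoff, w2
    return schedule.terminal


def read_embedding_file(path: str) -> np.ndarray:
    """Load a dense whitespace-separated numeric matrix."""
    mat = np.loadtxt(path, ndmin=2)
    if mat.size == 0:
        raise EmbedError(f"{path}: empty embedding file")
    return mat


def write_signature(sig: EmbeddingSignature, path: str) -> None:
    """Text container: one shape header per block, then row-major values."""
    with open(path, "w") as fh:
        for blk in (sig.block_a, sig.block_b):
            fh.write(f"{blk.shape[0]} {blk.shape[1]} {int(sig.quantized)}\n")
            for row in blk:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def read_signature(path: str) -> EmbeddingSignature:
    blocks = []
    quantized = True
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    pos = 0
    for _ in range(2):
        r, c, qflag = (int(t) for t in lines[pos].split())
        quantized = bool(qflag)
        rows = [[float(t) for t in lines[pos + 1 + k].split()] for k in range(r)]
        blocks.append(np.array(rows))
        pos += 1 + r
    a, b = blocks
    if quantized:
        a, b = a.astype(np.int64), b.astype(np.int64)
    return EmbeddingSignature(block_a=a, block_b=b, quantized=quantized)
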