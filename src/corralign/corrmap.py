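"""Position-by-position correlation / contact maps and pair selection."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

DEFAULT_CONTACT_CUTOFF = 8.0  # Angstrom, representative-atom distance
DEFAULT_CONTACT_MIN_SEP = 5
DEFAULT_SELECT_MIN_SEP = 3
DEFAULT_MAX_PARTNERS = 16
DEFAULT_CORR_CUTOFF = 0.5  # applied after min-max rescaling to [0, 1]


class CorrMapError(ValueError):
    pass


@dataclass
class CorrelationMap:
    """Symmetric n x n map of positional dependence (or binary contacts)."""

    values: np.ndarray
    kind: Literal["correlation", "contact"] = "correlation"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise CorrMapError(f"map must be square, got {v.shape}")
        v = (v + v.T) / 2.0  # symmetrize asymmetric (e.g. attention-derived) input
        np.fill_diagonal(v, 0.0)
        if self.kind == "contact":
            uniq = set(np.unique(v)) - {0.0, 1.0}
            if uniq:
                raise CorrMapError(f"contact map has non-binary values {sorted(uniq)[:3]}")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def rescaled(self) -> "CorrelationMap":
        """Min-max rescale off-diagonal values to [0, 1] (constant maps to 0)."""
        v = self.values.copy()
        mask = ~np.eye(self.n, dtype=bool)
        lo, hi = v[mask].min(), v[mask].max()
        if hi > lo:
            v[mask] = (v[mask] - lo) / (hi - lo)
        else:
            v[mask] = 0.0
        return CorrelationMap(values=v, kind=self.kind)


@dataclass
class SelectedPairs:
    """Correlated position pairs (i < j) with positive weights."""

    pairs: list[tuple[int, int, float]]
    source: str = "unknown"

    def __post_init__(self) -> None:
        seen = set()
        for i, j, w in self.pairs:
            if not (0 <= i < j):
                raise CorrMapError(f"bad pair ({i},{j})")
            if (i, j) in seen:
                raise CorrMapError(f"duplicate pair ({i},{j})")
            if w <= 0:
                raise CorrMapError(f"non-positive weight for pair ({i},{j})")
            seen.add((i, j))

    def partners_of(self, n: int) -> list[list[tuple[int, float]]]:
        """Per-position partner lists (both orientations), for n positions."""
        out: list[list[tuple[int, float]]] = [[] for _ in range(n)]
        for i, j, w in self.pairs:
            if j >= n:
                raise CorrMapError(f"pair ({i},{j}) out of range for length {n}")
            out[i].append((j, w))
            out[j].append((i, w))
        return out


def load_corrmap(path: str | Path, expected_n: int) -> CorrelationMap:
    """Load a dense whitespace matrix or 1-based sparse ``i j value`` triplets."""
    rows = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise CorrMapError(f"{path}: non-numeric entry: {exc}") from exc
    if not rows:
        raise CorrMapError(f"{path}: empty map file")
    widths = {len(r) for r in rows}
    if widths == {expected_n} and len(rows) == expected_n:
        return CorrelationMap(values=np.array(rows))
    if widths <= {3}:
        values = np.zeros((expected_n, expected_n))
        for i1, j1, v in rows:
            i, j = int(i1) - 1, int(j1) - 1
            if not (0 <= i < expected_n and 0 <= j < expected_n):
                raise CorrMapError(f"{path}: triplet ({int(i1)},{int(j1)}) out of range")
            values[i, j] = v
            values[j, i] = v
        return CorrelationMap(values=values)
    raise CorrMapError(
        f"{path}: neither a dense {expected_n}x{expected_n} matrix nor sparse triplets"
    )


def save_corrmap_sparse(cmap: CorrelationMap, path: str | Path) -> None:
    """Write non-zero upper-triangle entries as 1-based triplets."""
    with open(path, "w") as fh:
        fh.write(f"# sparse triplets, n={cmap.n}\n")
        for i in range(cmap.n):
            for j in range(i + 1, cmap.n):
                if cmap.values[i, j] != 0.0:
                    fh.write(f"{i + 1} {j + 1} {cmap.values[i, j]:.6g}\n")


def select_pairs(
    cmap: CorrelationMap,
    cutoff: float = DEFAULT_CORR_CUTOFF,
    min_separation: int = DEFAULT_SELECT_MIN_SEP,
    max_partners_per_position: int | None = DEFAULT_MAX_PARTNERS,
) -> SelectedPairs:
    """Pairs with value >= cutoff and |j-i| >= min_separation.

    When a position has more than ``max_partners_per_position`` qualifying
    partners, its highest-valued ones are kept (ties broken by smaller j);
    a pair survives only if kept by both endpoints.
    """
    if min_separation < 1:
        raise CorrMapError("min_separation must be >= 1")
    n = cmap.n
    candidates = [
        (i, j, float(cmap.values[i, j]))
        for i in range(n)
        for j in range(i + min_separation, n)
        if cmap.values[i, j] >= cutoff and cmap.values[i, j] > 0
    ]
    if max_partners_per_position is not None:
        kept_by: list[set[int]] = [set() for _ in range(n)]
        by_pos: list[list[tuple[float, int]]] = [[] for _ in range(n)]
        for i, j, w in candidates:
            by_pos[i].append((w, j))
            by_pos[j].append((w, i))
        for p in range(n):
            ranked = sorted(by_pos[p], key=lambda t: (-t[0], t[1]))
            kept_by[p] = {q for _, q in ranked[:max_partners_per_position]}
        candidates = [
            (i, j, w) for i, j, w in candidates if j in kept_by[i] and i in kept_by[j]
        ]
    return SelectedPairs(pairs=candidates, source=f"cutoff={cutoff}")


def contacts_from_coords(
    coords: np.ndarray,
    distance_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    min_separation: int = DEFAULT_CONTACT_MIN_SEP,
) -> CorrelationMap:
    """Binary contact map from per-residue representative-atom coordinates.

    ``coords`` is (n, 3); missing residues are rows of NaN and never contact.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise CorrMapError(f"coords must be (n, 3), got {coords.shape}")
    present = ~np.isnan(coords).any(axis=1)
    if present.sum() < 2:
        raise CorrMapError("fewer than 2 residues with coordinates")
    n = coords.shape[0]
    filled = np.where(present[:, None], coords, 0.0)
    diff = filled[:, None, :] - filled[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    idx = np.arange(n)
    sep_ok = np.abs(idx[:, None] - idx[None, :]) >= min_separation
    both = present[:, None] & present[None, :]
    values = ((dist <= distance_cutoff) & sep_ok & both).astype(float)
    return CorrelationMap(values=values, kind="contact")
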