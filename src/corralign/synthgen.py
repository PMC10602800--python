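"""Deterministic synthetic-fixture generators: covarying MSAs, toy structures,
random correlation maps and embedding matrices.  Every generator is a pure
function of its arguments plus an explicit seed."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corrmap import CorrelationMap
from .matrices import ALPHABET
from .seqio import MSA, ProteinSequence


class SynthError(ValueError):
    pass


@dataclass
class PlantedFamilySpec:
    """Recipe for an i.i.d.-row MSA with planted covarying column pairs.

    At each planted pair (i, j, permutation), with probability
    ``coupling_strength`` the letter in column j is the permutation image of
    the letter in column i; otherwise it is drawn independently.
    """

    depth: int
    width: int
    planted_pairs: list[tuple[int, int, dict[str, str]]] = field(default_factory=list)
    coupling_strength: float = 1.0
    background_composition: np.ndarray | None = None
    alphabet: str = ALPHABET
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2 or self.width < 1:
            raise SynthError("depth must be >= 2 and width >= 1")
        if not (0.0 <= self.coupling_strength <= 1.0):
            raise SynthError("coupling_strength must be in [0, 1]")
        used: set[int] = set()
        for i, j, perm in self.planted_pairs:
            if not (0 <= i < self.width and 0 <= j < self.width and i != j):
                raise SynthError(f"planted pair ({i},{j}) out of range")
            if i in used or j in used:
                raise SynthError(f"overlapping planted pair ({i},{j})")
            used.update((i, j))
            if sorted(perm) != sorted(set(perm.values())) or set(perm) - set(self.alphabet):
                raise SynthError(f"invalid pairing permutation at ({i},{j})")


def cyclic_permutation(alphabet: str = ALPHABET, shift: int = 1) -> dict[str, str]:
    """Convenience pairing permutation: each letter maps to the next one."""
    n = len(alphabet)
    return {alphabet[x]: alphabet[(x + shift) % n] for x in range(n)}


def make_covarying_msa(spec: PlantedFamilySpec) -> MSA:
    """Draw an MSA per the planted-family recipe; reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(spec.alphabet))
    comp = spec.background_composition
    if comp is None:
        comp = np.ones(len(letters)) / len(letters)
    else:
        comp = np.asarray(comp, dtype=float)
        comp = comp / comp.sum()
    grid = rng.choice(len(letters), size=(spec.depth, spec.width), p=comp)
    rows = [list(letters[r]) for r in grid]
    for i, j, perm in spec.planted_pairs:
        coupled = rng.random(spec.depth) < spec.coupling_strength
        for r in range(spec.depth):
            if coupled[r]:
                rows[r][j] = perm.get(rows[r][i], rows[r][i])
    ids = [f"synth{r}" for r in range(spec.depth)]
    return MSA(ids=ids, rows=["".join(r) for r in rows])


def make_random_sequence(length: int, seed: int = 0, alphabet: str = ALPHABET) -> ProteinSequence:
    rng = np.random.default_rng(seed)
    letters = np.array(list(alphabet))
    return ProteinSequence(
        id=f"rand{seed}", residues="".join(rng.choice(letters, size=length))
    )


def make_toy_structure(length: int, fold: str = "helix", seed: int = 0) -> np.ndarray:
    """Ideal-geometry C-alpha trace as an (n, 3) array.

    helix: 1.5 A rise and 100 degrees per residue (consecutive CA ~3.8 A).
    hairpin: two antiparallel strands 4.8 A apart, 3.8 A along-strand spacing.
    """
    if length < 2:
        raise SynthError("length must be >= 2")
    if fold == "helix":
        radius = np.sqrt(3.8**2 - 1.5**2) / (2.0 * np.sin(np.deg2rad(50.0)))
        idx = np.arange(length)
        theta = np.deg2rad(100.0) * idx
        return np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), 1.5 * idx]
        )
    if fold == "hairpin":
        half = length // 2
        coords = np.zeros((length, 3))
        for i in range(half):
            coords[i] = (3.8 * i, 0.0, 0.0)
        for offset, i in enumerate(range(half, length)):
            coords[i] = (3.8 * (half - 1 - offset), 4.8, 0.0)
        return coords
    raise SynthError(f"unknown fold {fold!r}")


def make_random_corrmap(n: int, density: float, seed: int = 0) -> CorrelationMap:
    """Symmetric map whose off-diagonal entries are nonzero with the given density."""
    if not (0.0 <= density <= 1.0):
        raise SynthError("density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                v = rng.uniform(0.05, 1.0)
                values[i, j] = values[j, i] = v
    return CorrelationMap(values=values)


def make_random_embeddings(n: int, dim: int, seed: int = 0) -> np.ndarray:
    """Reproducible standard-normal (n, dim) embedding matrix."""
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n, dim))


def write_pdb_ca(coords: np.ndarray, path: str, residues: str | None = None) -> None:
    """Write a minimal single-chain CA-only PDB file for toy structures."""
    three = {
        "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
        "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
        "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
        "Y": "TYR", "V": "VAL", "X": "UNK",
    }
    coords = np.asarray(coords, dtype=float)
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(coords):
            res = three.get(residues[i] if residues else "A", "UNK")
            fh.write(
                f"ATOM  {i + 1:>5}  CA  {res} A{i + 1:>4}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")
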