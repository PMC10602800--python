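"""Structure-based evaluation of sequence alignments: optimal superposition
and the per-residue-normalized RMSD over matched columns."""

from __future__ import annotations

import warnings

import numpy as np

from .seqio import AlignmentResult


class StructEvalError(ValueError):
    pass


def kabsch_superpose(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of Y onto X.

    Returns (rotation, translation, rmsd) with rotation a proper rotation
    (det = +1) such that ``Y @ rotation.T + translation`` best fits X.  For
    degenerate (e.g. collinear) point sets the rmsd is still optimal but the
    rotation may be non-unique.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise StructEvalError(f"point sets must both be (n, 3); got {X.shape}, {Y.shape}")
    if X.shape[0] < 3:
        raise StructEvalError("need at least 3 point pairs")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y))):
        raise StructEvalError("non-finite coordinates")
    cx, cy = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - cx, Y - cy
    H = Yc.T @ Xc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    Yr = Yc @ R.T
    rmsd = float(np.sqrt(((Xc - Yr) ** 2).sum() / X.shape[0]))
    t = cx - cy @ R.T
    return R, t, rmsd


def normalized_aligned_rmsd(
    result: AlignmentResult, coords_a: np.ndarray, coords_b: np.ndarray
) -> float:
    """Superposed RMSD over MATCH columns, divided by the number of such columns.

    Coordinates are (length, 3) with NaN rows for unresolved residues; MATCH
    columns lacking a coordinate on either side are skipped.
    """
    coords_a = np.asarray(coords_a, dtype=float)
    coords_b = np.asarray(coords_b, dtype=float)
    pairs = []
    for i, k in result.match_columns():
        if i >= len(coords_a) or k >= len(coords_b):
            raise StructEvalError(f"match column ({i},{k}) outside coordinate range")
        xa, xb = coords_a[i], coords_b[k]
        if np.isnan(xa).any() or np.isnan(xb).any():
            continue
        pairs.append((xa, xb))
    if len(pairs) < 3:
        raise StructEvalError(
            f"only {len(pairs)} usable matched columns; need at least 3"
        )
    X = np.array([p[0] for p in pairs])
    Y = np.array([p[1] for p in pairs])
    _, _, rmsd = kabsch_superpose(X, Y)
    return rmsd / len(pairs)


def read_pdb_ca(path: str, chain: str | None = None) -> tuple[str, np.ndarray]:
    """C-alpha trace of the first model (one chain) of a PDB file.

    Returns the one-letter sequence and an (n, 3) coordinate array ordered by
    residue number; unknown residue types become 'X'.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import protein_letters_3to1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", path)
    model = next(iter(structure))
    if chain is None:
        ch = next(iter(model))
    else:
        if chain not in model:
            raise StructEvalError(f"{path}: no chain {chain!r}")
        ch = model[chain]
    seq, coords = [], []
    for res in ch:
        if "CA" not in res:
            continue
        name = res.get_resname().capitalize()
        seq.append(protein_letters_3to1.get(name.upper(), "X"))
        coords.append(res["CA"].coord)
    if len(coords) < 2:
        raise StructEvalError(f"{path}: fewer than 2 CA atoms")
    return "".join(seq), np.array(coords, dtype=float)


def read_pdb_cb(path: str, chain: str | None = None) -> tuple[str, np.ndarray]:
    """Representative-atom trace: C-beta with C-alpha fallback (glycine)."""
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import protein_letters_3to1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", path)
    model = next(iter(structure))
    ch = model[chain] if chain is not None else next(iter(model))
    seq, coords = [], []
    for res in ch:
        atom = res["CB"] if "CB" in res else (res["CA"] if "CA" in res else None)
        if atom is None:
            continue
        seq.append(protein_letters_3to1.get(res.get_resname().upper(), "X"))
        coords.append(atom.coord)
    if len(coords) < 2:
        raise StructEvalError(f"{path}: fewer than 2 representative atoms")
    return "".join(seq), np.array(coords, dtype=float)
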