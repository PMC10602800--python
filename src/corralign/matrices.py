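"""Substitution score tables: single-residue (20x20) and residue-pair (400x400).

The 20x20 tables follow the NCBI/EMBOSS text dialect; the 400x400 tables use a
documented TSV of ``<XY> <ZW> <score>`` records where ``XY`` is the residue
pair in the first sequence and ``ZW`` the pair it aligns to in the second.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

#: Canonical amino-acid alphabet in NCBI matrix-file order.
ALPHABET = "ARNDCQEGHILKMFPSTWYV"
#: Symbol used for any residue outside the canonical alphabet after sanitization.
UNKNOWN = "X"

AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

_BUNDLED = {"blosum62": "BLOSUM62.txt", "pam250": "PAM250.txt"}


class MatrixError(ValueError):
    """Raised for malformed or inconsistent matrix files."""


def aa_index(residue: str) -> int:
    """Index of a canonical residue; raises KeyError for anything else."""
    return AA_INDEX[residue]


def pair_index(a: str, b: str) -> int:
    """Row/column index of an ordered residue pair in a 400x400 table."""
    return 20 * AA_INDEX[a] + AA_INDEX[b]


@dataclass
class SubstitutionMatrix20:
    """Symmetric 20x20 substitution score table over the canonical alphabet."""

    scores: np.ndarray
    name: str = "custom"
    alphabet: str = ALPHABET
    _unknown_score: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (20, 20):
            raise MatrixError(f"expected 20x20 scores, got {self.scores.shape}")
        if not np.all(np.isfinite(self.scores)):
            raise MatrixError("non-finite matrix entry")
        if not np.allclose(self.scores, self.scores.T):
            raise MatrixError("matrix is not symmetric")
        off = self.scores[~np.eye(20, dtype=bool)]
        self._unknown_score = float(off.min())

    def score(self, a: str, b: str) -> float:
        """Score of aligning residue ``a`` with ``b``.

        Unknown residues score the minimum off-diagonal value of the table.
        """
        ia = AA_INDEX.get(a)
        ib = AA_INDEX.get(b)
        if ia is None or ib is None:
            return self._unknown_score
        return float(self.scores[ia, ib])


@dataclass
class PairSubstitutionMatrix400:
    """Score table over ordered residue-pair substitutions.

    ``scores[pair_index(i,j), pair_index(k,l)]`` is the score of pair (i,j)
    in sequence A aligning to pair (k,l) in sequence B.  The table satisfies
    ``score(i,j,k,l) == score(j,i,l,k)`` (same event read in the other
    direction) but is allowed to be asymmetric between A and B.
    """

    scores: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (400, 400):
            raise MatrixError(f"expected 400x400 scores, got {self.scores.shape}")
        if not np.all(np.isfinite(self.scores)):
            raise MatrixError("non-finite matrix entry")

    def score(self, i: str, j: str, k: str, l: str) -> float:
        """Score for pair (i,j) in A aligned to (k,l) in B; 0 if any residue is unknown."""
        try:
            return float(self.scores[pair_index(i, j), pair_index(k, l)])
        except KeyError:
            return 0.0

    def check_swap_invariant(self, atol: float = 1e-9) -> bool:
        swapped = self.scores.reshape(20, 20, 20, 20).transpose(1, 0, 3, 2).reshape(400, 400)
        return bool(np.allclose(self.scores, swapped, atol=atol))


@dataclass
class DPParams:
    """Dynamic-programming parameters for the combined-score global aligner.

    ``gap_open`` (p) is charged once per gap on top of ``gap_extend`` (q);
    a gap of length g costs p + g*q.
    """

    w1: float = 1.0
    w2: float = 0.1
    gap_open: float = 10.0
    gap_extend: float = 0.5
    window: int = 10
    free_end_gaps: bool = False

    def __post_init__(self) -> None:
        if self.w1 < 0:
            raise ValueError("w1 must be >= 0")
        if not (0.0 <= self.w2 <= 0.9):
            raise ValueError("w2 must be within [0.0, 0.9]")
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")
        if self.window < 0:
            raise ValueError("window must be >= 0")


def parse_matrix20(text: str, name: str = "custom") -> SubstitutionMatrix20:
    """Parse an NCBI/EMBOSS-style text matrix into a 20x20 table.

    Extra columns (B, Z, X, ``*``) are parsed and dropped.  A missing
    canonical letter or an asymmetric entry pair is an error.
    """
    header: list[str] | None = None
    rows: dict[str, list[float]] = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if header is None:
            if any(len(f) != 1 for f in fields):
                raise MatrixError("malformed header row")
            header = fields
            continue
        label = fields[0]
        if len(label) != 1:
            raise MatrixError(f"malformed row label {label!r}")
        try:
            values = [float(v) for v in fields[1:]]
        except ValueError as exc:
            raise MatrixError(f"non-numeric entry in row {label}: {exc}") from exc
        if len(values) != len(header):
            raise MatrixError(f"row {label} has {len(values)} entries, expected {len(header)}")
        rows[label] = values
    if header is None:
        raise MatrixError("no header row found")
    for letter in ALPHABET:
        if letter not in header:
            raise MatrixError(f"missing canonical letter {letter} in header")
        if letter not in rows:
            raise MatrixError(f"missing canonical letter {letter} row")
    col = {a: header.index(a) for a in ALPHABET}
    scores = np.zeros((20, 20))
    for a in ALPHABET:
        for b in ALPHABET:
            scores[AA_INDEX[a], AA_INDEX[b]] = rows[a][col[b]]
    if not np.allclose(scores, scores.T):
        bad = np.argwhere(~np.isclose(scores, scores.T))[0]
        a, b = ALPHABET[bad[0]], ALPHABET[bad[1]]
        raise MatrixError(f"asymmetric entries for ({a},{b}) vs ({b},{a})")
    return SubstitutionMatrix20(scores=scores, name=name)


def write_matrix20(matrix: SubstitutionMatrix20) -> str:
    """Serialize a 20x20 table in the NCBI text dialect."""
    lines = [f"# {matrix.name}", "   " + "  ".join(ALPHABET)]
    for a in ALPHABET:
        vals = " ".join(f"{matrix.scores[AA_INDEX[a], AA_INDEX[b]]:6.2f}" for b in ALPHABET)
        lines.append(f"{a} {vals}")
    return "\n".join(lines) + "\n"


def load_named_matrix20(name: str) -> SubstitutionMatrix20:
    """Load a bundled matrix (``blosum62`` or ``pam250``) by name."""
    key = name.lower()
    if key not in _BUNDLED:
        raise MatrixError(f"no bundled matrix named {name!r}; choose from {sorted(_BUNDLED)}")
    text = (
        importlib.resources.files("corralign").joinpath("data", _BUNDLED[key]).read_text()
    )
    return parse_matrix20(text, name=key)


def _pair_token(token: str) -> int:
    if len(token) != 2 or token[0] not in AA_INDEX or token[1] not in AA_INDEX:
        raise MatrixError(f"malformed pair token {token!r}")
    return pair_index(token[0], token[1])


def parse_matrix400(text: str, name: str = "custom") -> PairSubstitutionMatrix400:
    """Parse the pair-substitution TSV format.

    Lines are ``<XY> <ZW> <score>``; ``#`` starts a comment; an optional
    ``default=<real>`` header fills unspecified tuples.  The
    (i,j,k,l) <-> (j,i,l,k) identity is enforced: conflicting orientations are
    an error, a single orientation fills its mirror.
    """
    default: float | None = None
    entries: dict[tuple[int, int], float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("default="):
            try:
                default = float(line.split("=", 1)[1])
            except ValueError as exc:
                raise MatrixError(f"line {lineno}: bad default value") from exc
            continue
        fields = line.split()
        if len(fields) != 3:
            raise MatrixError(f"line {lineno}: expected '<XY> <ZW> <score>'")
        r = _pair_token(fields[0])
        c = _pair_token(fields[1])
        try:
            value = float(fields[2])
        except ValueError as exc:
            raise MatrixError(f"line {lineno}: non-numeric score") from exc
        if (r, c) in entries and entries[(r, c)] != value:
            raise MatrixError(f"line {lineno}: conflicting duplicate for {fields[0]} {fields[1]}")
        entries[(r, c)] = value

    def mirror(rc: tuple[int, int]) -> tuple[int, int]:
        r, c = rc
        ri, rj = divmod(r, 20)
        ck, cl = divmod(c, 20)
        return 20 * rj + ri, 20 * cl + ck

    for rc, value in list(entries.items()):
        m = mirror(rc)
        if m in entries:
            if entries[m] != value:
                ri, rj = divmod(rc[0], 20)
                ck, cl = divmod(rc[1], 20)
                raise MatrixError(
                    "inconsistent mirrored entries for "
                    f"{ALPHABET[ri]}{ALPHABET[rj]} {ALPHABET[ck]}{ALPHABET[cl]}"
                )
        else:
            entries[m] = value
    if len(entries) < 160000:
        if default is None:
            raise MatrixError(
                f"only {len(entries)} of 160000 tuples specified and no default= header"
            )
        scores = np.full((400, 400), default, dtype=float)
    else:
        scores = np.empty((400, 400), dtype=float)
    for (r, c), value in entries.items():
        scores[r, c] = value
    return PairSubstitutionMatrix400(scores=scores, name=name)


def write_matrix400(matrix: PairSubstitutionMatrix400) -> str:
    """Serialize all 160,000 tuples, sorted lexicographically by pair tokens."""
    tokens = sorted(a + b for a in ALPHABET for b in ALPHABET)
    lines = [f"# {matrix.name}"]
    for ra in tokens:
        r = pair_index(ra[0], ra[1])
        for cb in tokens:
            c = pair_index(cb[0], cb[1])
            lines.append(f"{ra} {cb} {matrix.scores[r, c]:.6g}")
    return "\n".join(lines) + "\n"
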