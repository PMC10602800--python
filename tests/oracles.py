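"""Independent reference implementations used only to check the package.

Everything here is deliberately naive and written from the documented
definitions, not from the package's code paths.
"""

from __future__ import annotations

import numpy as np

GAP_OPEN_PLUS_EXT = "first gap residue costs p+q, each further residue q"


def naive_pair_bonus(i, k, seq_a, seq_b, pairs, m400_lookup, window, normalization, scale=1.0):
    """Windowed-max pair bonus, direct enumeration.

    ``pairs`` is a list of (i, j, weight) with i < j; ``m400_lookup(a,b,c,d)``
    returns the pair-substitution score.
    """
    partners = []
    for x, y, _w in pairs:
        if x == i:
            partners.append(y)
        elif y == i:
            partners.append(x)
    vals = []
    for j in partners:
        delta = j - i
        candidates = []
        for l in range(k + delta - window, k + delta + window + 1):
            if 0 <= l < len(seq_b):
                candidates.append(m400_lookup(seq_a[i], seq_a[j], seq_b[k], seq_b[l]))
        if candidates:
            vals.append(max(candidates))
    if not vals:
        return 0.0
    total = sum(vals)
    if normalization == "mean":
        total /= len(vals)
    return scale * total


def enumerate_alignments(n: int, m: int):
    """Yield every global alignment of n vs m residues as an op-kind string."""
    if n == 0 and m == 0:
        yield ""
        return
    if n > 0:
        for rest in enumerate_alignments(n - 1, m):
            yield "A" + rest
    if m > 0:
        for rest in enumerate_alignments(n, m - 1):
            yield "B" + rest
    if n > 0 and m > 0:
        for rest in enumerate_alignments(n - 1, m - 1):
            yield "M" + rest


def score_ops_naive(
    kinds: str,
    seq_a: str,
    seq_b: str,
    score_cell,
    gap_open: float,
    gap_extend: float,
    free_end_gaps: bool = False,
) -> float:
    """Score an op-kind string; ``score_cell(i, k)`` gives the match score."""
    total = 0.0
    i = k = 0
    prev = None
    ncols = len(kinds)
    for idx, kind in enumerate(kinds):
        if kind == "M":
            total += score_cell(i, k)
            i += 1
            k += 1
        else:
            cost = gap_extend if prev == kind else gap_open + gap_extend
            if free_end_gaps:
                leading = all(c == kind for c in kinds[: idx + 1])
                j = idx
                while j + 1 < ncols and kinds[j + 1] == kind:
                    j += 1
                if leading or j == ncols - 1:
                    cost = 0.0
            total -= cost
            if kind == "A":
                i += 1
            else:
                k += 1
        prev = kind
    return total


def best_alignment_bruteforce(
    seq_a: str,
    seq_b: str,
    score_cell,
    gap_open: float,
    gap_extend: float,
    free_end_gaps: bool = False,
):
    """(best score, one best op string) by exhaustive enumeration."""
    best, best_ops = -np.inf, None
    for kinds in enumerate_alignments(len(seq_a), len(seq_b)):
        s = score_ops_naive(
            kinds, seq_a, seq_b, score_cell, gap_open, gap_extend, free_end_gaps
        )
        if s > best:
            best, best_ops = s, kinds
    return best, best_ops


def gotoh_reference(seq_a: str, seq_b: str, score_cell, gap_open: float, gap_extend: float):
    """Independent plain affine-gap global aligner.

    Same conventions as the package: a gap of length g costs p + g*q; tie
    order diagonal > gap-in-B (consume A) > gap-in-A (consume B).  Returns
    (score, op-kind string).
    """
    n, m = len(seq_a), len(seq_b)
    NEG = -np.inf
    open_c, ext_c = gap_open + gap_extend, gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    PM = [[-1] * (m + 1) for _ in range(n + 1)]
    PX = [[-1] * (m + 1) for _ in range(n + 1)]
    PY = [[-1] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + i * gap_extend)
    for k in range(1, m + 1):
        Y[0][k] = -(gap_open + k * gap_extend)
    for i in range(1, n + 1):
        for k in range(1, m + 1):
            opts = [M[i - 1][k - 1], X[i - 1][k - 1], Y[i - 1][k - 1]]
            arg = int(np.argmax(opts))  # first max: M > X > Y
            M[i][k] = opts[arg] + score_cell(i - 1, k - 1)
            PM[i][k] = arg
            opts = [M[i - 1][k] - open_c, X[i - 1][k] - ext_c, Y[i - 1][k] - open_c]
            arg = int(np.argmax(opts))
            X[i][k] = opts[arg]
            PX[i][k] = arg
            opts = [M[i][k - 1] - open_c, X[i][k - 1] - open_c, Y[i][k - 1] - ext_c]
            arg = int(np.argmax(opts))
            Y[i][k] = opts[arg]
            PY[i][k] = arg
    finals = [M[n][m], X[n][m], Y[n][m]]
    s = int(np.argmax(finals))
    score = finals[s]
    ops = []
    i, k = n, m
    while i > 0 or k > 0:
        if i == 0:
            ops.append("B")
            k -= 1
            continue
        if k == 0:
            ops.append("A")
            i -= 1
            continue
        if s == 0:
            ops.append("M")
            s = PM[i][k]
            i, k = i - 1, k - 1
        elif s == 1:
            ops.append("A")
            s = PX[i][k]
            i -= 1
        else:
            ops.append("B")
            s = PY[i][k]
            k -= 1
    return score, "".join(reversed(ops))


def naive_dct_compress(matrix: np.ndarray, target_rows: int, target_cols: int) -> np.ndarray:
    """Explicit cosine-basis DCT -> truncate -> inverse DCT -> rescale."""
    matrix = np.asarray(matrix, dtype=float)
    n, d = matrix.shape

    def dct_basis(size: int) -> np.ndarray:
        B = np.zeros((size, size))
        for k in range(size):
            for x in range(size):
                B[k, x] = np.cos(np.pi * k * (2 * x + 1) / (2 * size))
            B[k] *= np.sqrt((1 if k == 0 else 2) / size)
        return B

    Bn, Bd = dct_basis(n), dct_basis(d)
    coeffs = Bn @ matrix @ Bd.T
    block = coeffs[:target_rows, :target_cols]
    Br, Bc = dct_basis(target_rows), dct_basis(target_cols)
    out = Br.T @ block @ Bc
    return out * np.sqrt((target_rows * target_cols) / (n * d))


def quaternion_superpose_rmsd(X: np.ndarray, Y: np.ndarray) -> float:
    """Optimal superposition RMSD via Horn's quaternion eigenvalue method."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    S = Yc.T @ Xc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    ssd = (Xc**2).sum() + (Yc**2).sum() - 2.0 * lam
    return float(np.sqrt(max(ssd, 0.0) / X.shape[0]))
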