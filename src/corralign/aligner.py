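"""Global pairwise alignment combining single-residue and correlated-pair scores.

The dynamic program is a three-state affine-gap (Gotoh) recursion whose match
score at cell (i, k) is

    S(i, k) = w1 * m20(A[i], B[k]) + w2 * pair_bonus(i, k)

where the pair bonus probes, for every correlated partner j of position i, a
window of candidate positions l around the diagonal projection l = k + (j - i)
and takes the best 400x400 pair-substitution score, combining partners by mean
(default) or sum.  A gap of length g costs gap_open + g * gap_extend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .corrmap import SelectedPairs
from .matrices import AA_INDEX, DPParams, PairSubstitutionMatrix400, SubstitutionMatrix20
from .seqio import AlignmentResult, Op, ProteinSequence, SequenceError

NEG_INF = float("-inf")


@dataclass
class PairBonusContext:
    """Everything needed to score correlated-pair bonuses for sequence A."""

    pairs: SelectedPairs
    matrix400: PairSubstitutionMatrix400
    window: int = 10
    normalization: Literal["sum", "mean"] = "mean"
    scale: float = 1.0  # set to 0.5 to halve the per-endpoint contribution

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.normalization not in ("sum", "mean"):
            raise ValueError("normalization must be 'sum' or 'mean'")


def _residue_indices(seq: ProteinSequence) -> np.ndarray:
    # unknown residues index a zero-scoring virtual row handled by masking
    return np.array([AA_INDEX.get(ch, -1) for ch in seq.residues], dtype=int)


def pair_bonus(
    i: int, k: int, seq_a: ProteinSequence, seq_b: ProteinSequence, ctx: PairBonusContext
) -> float:
    """Correlated-pair bonus for aligning A[i] with B[k].

    For each selected partner j of i (either orientation), the best 400x400
    score over l in [k+(j-i)-W, k+(j-i)+W] clipped to B's range; partners whose
    window is empty contribute nothing.  Combined by the configured
    normalization; no partners (or all windows empty) gives 0.
    """
    partners = ctx.pairs.partners_of(len(seq_a))[i]
    if not partners:
        return 0.0
    m = len(seq_b)
    scores = ctx.matrix400.scores
    vals = []
    for j, _w in partners:
        delta = j - i
        lo = max(0, k + delta - ctx.window)
        hi = min(m - 1, k + delta + ctx.window)
        if lo > hi:
            continue
        ai, aj, bk = seq_a.residues[i], seq_a.residues[j], seq_b.residues[k]
        if ai not in AA_INDEX or aj not in AA_INDEX or bk not in AA_INDEX:
            continue
        row = 20 * AA_INDEX[ai] + AA_INDEX[aj]
        best = NEG_INF
        for l in range(lo, hi + 1):
            bl = seq_b.residues[l]
            if bl not in AA_INDEX:
                continue
            best = max(best, scores[row, 20 * AA_INDEX[bk] + AA_INDEX[bl]])
        if best > NEG_INF:
            vals.append(best)
    if not vals:
        return 0.0
    total = sum(vals)
    if ctx.normalization == "mean":
        total /= len(vals)
    return ctx.scale * total


def _bonus_matrix(
    seq_a: ProteinSequence, seq_b: ProteinSequence, ctx: PairBonusContext
) -> np.ndarray:
    """Precompute pair_bonus(i, k) for all cells (vectorized over k and l)."""
    n, m = len(seq_a), len(seq_b)
    out_sum = np.zeros((n, m))
    out_cnt = np.zeros((n, m), dtype=int)
    aidx = _residue_indices(seq_a)
    bidx = _residue_indices(seq_b)
    scores4 = ctx.matrix400.scores.reshape(20, 20, 20, 20)
    W = ctx.window
    partner_lists = ctx.pairs.partners_of(n)
    ks = np.arange(m)
    for i in range(n):
        if aidx[i] < 0:
            continue
        for j, _w in partner_lists[i]:
            if aidx[j] < 0:
                continue
            # Q[k, l] = score of pair (A[i],A[j]) vs (B[k],B[l]); mask unknowns
            R = scores4[aidx[i], aidx[j]]
            valid = bidx >= 0
            bk = np.where(valid, bidx, 0)
            Q = R[np.ix_(bk, bk)]
            Q[~valid, :] = NEG_INF
            Q[:, ~valid] = NEG_INF
            delta = j - i
            lo = np.clip(ks + delta - W, 0, m)
            hi = np.clip(ks + delta + W + 1, 0, m)
            for k in range(m):
                if not valid[k] or lo[k] >= hi[k]:
                    continue
                best = Q[k, lo[k] : hi[k]].max()
                if best > NEG_INF:
                    out_sum[i, k] += best
                    out_cnt[i, k] += 1
    if ctx.normalization == "mean":
        with np.errstate(invalid="ignore"):
            out = np.where(out_cnt > 0, out_sum / np.maximum(out_cnt, 1), 0.0)
    else:
        out = out_sum
    return ctx.scale * out


def _score_grid(
    seq_a: ProteinSequence,
    seq_b: ProteinSequence,
    m20: SubstitutionMatrix20,
    params: DPParams,
    ctx: PairBonusContext | None,
) -> np.ndarray:
    n, m = len(seq_a), len(seq_b)
    grid = np.empty((n, m))
    for i, a in enumerate(seq_a.residues):
        for k, b in enumerate(seq_b.residues):
            grid[i, k] = params.w1 * m20.score(a, b)
    if ctx is not None and params.w2 != 0.0 and ctx.pairs.pairs:
        grid += params.w2 * _bonus_matrix(seq_a, seq_b, ctx)
    return grid


def align_global(
    seq_a: ProteinSequence,
    seq_b: ProteinSequence,
    m20: SubstitutionMatrix20,
    params: DPParams | None = None,
    ctx: PairBonusContext | None = None,
) -> AlignmentResult:
    """Optimal global alignment under the combined scoring model.

    Traceback is deterministic with tie order diagonal > gap-in-B > gap-in-A.
    With ``params.free_end_gaps`` leading and trailing gaps cost nothing.
    """
    if params is None:
        params = DPParams()
    if len(seq_a) == 0 or len(seq_b) == 0:
        raise SequenceError("cannot align empty sequences")
    if ctx is not None:
        for i, j, _ in ctx.pairs.pairs:
            if j >= len(seq_a):
                raise SequenceError(f"pair context ({i},{j}) out of range for A")
    S = _score_grid(seq_a, seq_b, m20, params, ctx)
    return _align_with_grid(seq_a, seq_b, S, params)


def _align_with_grid(
    seq_a: ProteinSequence, seq_b: ProteinSequence, S: np.ndarray, params: DPParams
) -> AlignmentResult:
    """Gotoh DP and traceback on a precomputed (n, m) cell-score grid."""
    n, m = len(seq_a), len(seq_b)
    p, q = params.gap_open, params.gap_extend
    open_cost, ext_cost = p + q, q

    # State 0 = M (match), 1 = X (gap in B, consumes A), 2 = Y (gap in A).
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0 if params.free_end_gaps else -(p + i * q)
    for k in range(1, m + 1):
        Y[0, k] = 0.0 if params.free_end_gaps else -(p + k * q)

    # ptr[state][i,k] = predecessor state (0/1/2); -1 for boundary
    ptrM = np.full((n + 1, m + 1), -1, dtype=np.int8)
    ptrX = np.full((n + 1, m + 1), -1, dtype=np.int8)
    ptrY = np.full((n + 1, m + 1), -1, dtype=np.int8)

    for i in range(1, n + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Si = S[i - 1]
        for k in range(1, m + 1):
            # M: tie order M > X > Y on the predecessor
            best, arg = Mi1[k - 1], 0
            if Xi1[k - 1] > best:
                best, arg = Xi1[k - 1], 1
            if Yi1[k - 1] > best:
                best, arg = Yi1[k - 1], 2
            Mi[k] = best + Si[k - 1]
            ptrM[i, k] = arg

            best, arg = Mi1[k] - open_cost, 0
            if Xi1[k] - ext_cost > best:
                best, arg = Xi1[k] - ext_cost, 1
            if Yi1[k] - open_cost > best:
                best, arg = Yi1[k] - open_cost, 2
            Xi[k] = best
            ptrX[i, k] = arg

            best, arg = Mi[k - 1] - open_cost, 0
            if Xi[k - 1] - open_cost > best:
                best, arg = Xi[k - 1] - open_cost, 1
            if Yi[k - 1] - ext_cost > best:
                best, arg = Yi[k - 1] - ext_cost, 2
            Yi[k] = best
            ptrY[i, k] = arg

    states = (M, X, Y)
    if params.free_end_gaps:
        # trailing gaps are free: best over the last row and column
        best_score, end = NEG_INF, (0, n, m)
        for s in range(3):
            v = states[s][n, m]
            if v > best_score:
                best_score, end = v, (s, n, m)
        for i in range(n + 1):
            for s in range(3):
                v = states[s][i, m]
                if v > best_score:
                    best_score, end = v, (s, i, m)
        for k in range(m + 1):
            for s in range(3):
                v = states[s][n, k]
                if v > best_score:
                    best_score, end = v, (s, n, k)
        s, ei, ek = end
        tail: list[Op] = []
        for i in range(n - 1, ei - 1, -1):
            tail.append(("A", i, None))
        for k in range(m - 1, ek - 1, -1):
            tail.append(("B", None, k))
        tail.reverse()
    else:
        best_score, s = states[0][n, m], 0
        if states[1][n, m] > best_score:
            best_score, s = states[1][n, m], 1
        if states[2][n, m] > best_score:
            best_score, s = states[2][n, m], 2
        ei, ek = n, m
        tail = []

    ops: list[Op] = []
    i, k = ei, ek
    ptrs = (ptrM, ptrX, ptrY)
    while i > 0 or k > 0:
        if s == 0:
            if i == 0 or k == 0:
                break
            prev = ptrs[0][i, k]
            ops.append(("M", i - 1, k - 1))
            i, k, s = i - 1, k - 1, prev
        elif s == 1:
            if i == 0:
                break
            prev = ptrs[1][i, k] if k > 0 else 1
            ops.append(("A", i - 1, None))
            i, s = i - 1, prev
        else:
            if k == 0:
                break
            prev = ptrs[2][i, k] if i > 0 else 2
            ops.append(("B", None, k - 1))
            k, s = k - 1, prev
        if i == 0 and k == 0:
            break
    # leading boundary gaps (free or charged, already in the score)
    while i > 0:
        ops.append(("A", i - 1, None))
        i -= 1
    while k > 0:
        ops.append(("B", None, k - 1))
        k -= 1
    ops.reverse()
    ops.extend(tail)

    result = AlignmentResult(
        ops=ops,
        score=float(best_score),
        seq_ids=(seq_a.id, seq_b.id),
        params=params,
    )
    result.validate(seq_a, seq_b)
    return result


def score_alignment(
    result: AlignmentResult,
    seq_a: ProteinSequence,
    seq_b: ProteinSequence,
    m20: SubstitutionMatrix20,
    params: DPParams | None = None,
    ctx: PairBonusContext | None = None,
) -> float:
    """Recompute the alignment objective on a fixed op list.

    Uses the same gap accounting (p + g*q per gap run, end runs free when
    ``free_end_gaps``) and the same pair bonus at each MATCH column.
    """
    if params is None:
        params = DPParams()
    result.validate(seq_a, seq_b)
    bonus = None
    if ctx is not None and params.w2 != 0.0 and ctx.pairs.pairs:
        bonus = _bonus_matrix(seq_a, seq_b, ctx)
    total = 0.0
    ops = result.ops
    ncols = len(ops)
    run_start = None  # index where the current gap run began, with its kind
    for idx, (kind, i, k) in enumerate(ops):
        if kind == "M":
            total += params.w1 * m20.score(seq_a.residues[i], seq_b.residues[k])
            if bonus is not None:
                total += params.w2 * bonus[i, k]
            run_start = None
        else:
            if run_start is not None and run_start[0] == kind:
                cost = params.gap_extend
            else:
                cost = params.gap_open + params.gap_extend
                run_start = (kind, idx)
            if params.free_end_gaps:
                # a gap column is free if its run touches either end of the alignment
                j = idx
                while j + 1 < ncols and ops[j + 1][0] == kind:
                    j += 1
                touches_start = all(op[0] == kind for op in ops[: idx + 1])
                touches_end = j == ncols - 1
                if touches_start or touches_end:
                    cost = 0.0
            total -= cost
    return total


def sequence_identity(
    result: AlignmentResult, seq_a: ProteinSequence, seq_b: ProteinSequence
) -> float:
    """Percent identical MATCH columns over all alignment columns (gaps included)."""
    result.validate(seq_a, seq_b)
    if not result.ops:
        return 0.0
    ident = sum(
        1
        for kind, i, k in result.ops
        if kind == "M" and seq_a.residues[i] == seq_b.residues[k]
    )
    return 100.0 * ident / len(result.ops)


def align_iterative(
    seq_a: ProteinSequence,
    seq_b: ProteinSequence,
    m20: SubstitutionMatrix20,
    params: DPParams | None = None,
    ctx: PairBonusContext | None = None,
    max_iter: int = 10,
) -> AlignmentResult:
    """Frozen-alignment variant: align, map partners through the previous
    alignment, rescore with the partner position fixed, repeat to convergence.
    """
    if params is None:
        params = DPParams()
    base = DPParams(
        w1=params.w1,
        w2=0.0,
        gap_open=params.gap_open,
        gap_extend=params.gap_extend,
        window=params.window,
        free_end_gaps=params.free_end_gaps,
    )
    current = align_global(seq_a, seq_b, m20, base, None)
    if ctx is None or params.w2 == 0.0 or not ctx.pairs.pairs:
        return current
    n, m = len(seq_a), len(seq_b)
    aidx = _residue_indices(seq_a)
    bidx = _residue_indices(seq_b)
    scores4 = ctx.matrix400.scores.reshape(20, 20, 20, 20)
    partner_lists = ctx.pairs.partners_of(n)
    for _ in range(max_iter):
        amap = {i: k for kind, i, k in current.ops if kind == "M"}
        bonus_sum = np.zeros((n, m))
        bonus_cnt = np.zeros((n, m), dtype=int)
        for i in range(n):
            if aidx[i] < 0:
                continue
            for j, _w in partner_lists[i]:
                l = amap.get(j)
                if l is None or aidx[j] < 0 or bidx[l] < 0:
                    continue
                row = scores4[aidx[i], aidx[j]]
                for k in range(m):
                    if bidx[k] < 0:
                        continue
                    bonus_sum[i, k] += row[bidx[k], bidx[l]]
                    bonus_cnt[i, k] += 1
        if ctx.normalization == "mean":
            bonus = np.where(bonus_cnt > 0, bonus_sum / np.maximum(bonus_cnt, 1), 0.0)
        else:
            bonus = bonus_sum
        bonus *= ctx.scale

        grid = _score_grid(seq_a, seq_b, m20, base, None) + params.w2 * bonus
        nxt = _align_with_grid(seq_a, seq_b, grid, params)
        if nxt.ops == current.ops:
            return nxt
        current = nxt
    return current
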