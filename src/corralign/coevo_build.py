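"""Build log-odds substitution tables from MSA coevolution statistics.

Two column-pair ranking statistics are provided: mutual information (MI) and
mean-field direct coupling analysis (DI).  The 400x400 pair table is a
log-odds ratio of 4-tuple substitution frequencies at highly ranked column
pairs (foreground) against all eligible column pairs (background); the 20x20
table does the same with the single-residue substitutions drawn from the
selected pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .corrmap import CorrelationMap
from .matrices import AA_INDEX, ALPHABET, PairSubstitutionMatrix400, SubstitutionMatrix20
from .seqio import GAP, MSA

GAP_STATE = 20  # index of the gap state in the 21-state alphabet
N_STATES = 21

MAX_COLUMN_GAP_FRACTION = 0.5
DEFAULT_TOP_FRACTION = 0.15
DEFAULT_IDENTITY_CLUSTERING = 0.8


class CoevoError(ValueError):
    pass


@dataclass
class PairRanking:
    """Statistic for every eligible column pair of one MSA, i < j."""

    scores: list[tuple[int, int, float]]
    method: Literal["MI", "mfDCA"]
    eligible_columns: list[int]

    def top_fraction(self, fraction: float) -> list[tuple[int, int]]:
        """The ceil(fraction * total) best-ranked pairs, deterministic order."""
        if not (0 < fraction <= 1):
            raise CoevoError("top fraction must be in (0, 1]")
        ranked = sorted(self.scores, key=lambda t: (-t[2], t[0], t[1]))
        keep = int(np.ceil(fraction * len(ranked)))
        return [(i, j) for i, j, _ in ranked[:keep]]


def _msa_state_matrix(msa: MSA) -> np.ndarray:
    """MSA as (depth, width) integer states; unknown residues count as gaps."""
    out = np.empty((msa.depth, msa.width), dtype=np.int8)
    for r, row in enumerate(msa.rows):
        for c, ch in enumerate(row):
            if ch == GAP:
                out[r, c] = GAP_STATE
            else:
                out[r, c] = AA_INDEX.get(ch, GAP_STATE)
    return out


def sequence_weights(msa: MSA, identity_threshold: float = DEFAULT_IDENTITY_CLUSTERING) -> np.ndarray:
    """Clustering weights: 1 / (number of rows within the identity threshold)."""
    X = _msa_state_matrix(msa)
    depth, width = X.shape
    sim = (X[:, None, :] == X[None, :, :]).mean(axis=2)
    counts = (sim >= identity_threshold).sum(axis=1)
    return 1.0 / counts


def eligible_columns(msa: MSA) -> list[int]:
    """Columns with gap fraction <= 0.5 (gap includes unknown residues)."""
    X = _msa_state_matrix(msa)
    frac = (X == GAP_STATE).mean(axis=0)
    return [c for c in range(msa.width) if frac[c] <= MAX_COLUMN_GAP_FRACTION]


def column_mi(
    msa: MSA, weights: np.ndarray | None = None, pseudocount: float = 0.0
) -> PairRanking:
    """Mutual information (bits) between every eligible column pair.

    Frequencies are sequence-weighted and pseudocounted (``pseudocount`` added
    to each of the 400 joint cells); gapped rows are excluded per pair.
    """
    if msa.depth < 2:
        raise CoevoError("MSA depth must be >= 2")
    cols = eligible_columns(msa)
    if len(cols) < 2:
        raise CoevoError("fewer than 2 eligible columns (all too gappy)")
    X = _msa_state_matrix(msa)
    w = np.ones(msa.depth) if weights is None else np.asarray(weights, dtype=float)
    scores = []
    for a_pos in range(len(cols)):
        for b_pos in range(a_pos + 1, len(cols)):
            i, j = cols[a_pos], cols[b_pos]
            ci, cj = X[:, i], X[:, j]
            ok = (ci != GAP_STATE) & (cj != GAP_STATE)
            joint = np.full((20, 20), pseudocount, dtype=float)
            np.add.at(joint, (ci[ok], cj[ok]), w[ok])
            total = joint.sum()
            if total <= 0:
                scores.append((i, j, 0.0))
                continue
            f = joint / total
            fi = f.sum(axis=1)
            fj = f.sum(axis=0)
            nz = f > 0
            outer = np.outer(fi, fj)
            mi = float((f[nz] * np.log2(f[nz] / outer[nz])).sum())
            scores.append((i, j, mi))
    return PairRanking(scores=scores, method="MI", eligible_columns=cols)


def mfdca_di(
    msa: MSA, weights: np.ndarray | None = None, pseudocount_fraction: float = 0.5
) -> PairRanking:
    """Mean-field DCA direct information for every eligible column pair.

    Standard recipe: identity-clustered sequence weights, pseudocounted 21-state
    frequencies, couplings as the negative inverse of the 20-state covariance
    matrix, and DI from the two-site model with self-consistent fields.
    """
    if msa.depth < 2:
        raise CoevoError("MSA depth must be >= 2")
    cols = eligible_columns(msa)
    L = len(cols)
    if L < 2:
        raise CoevoError("fewer than 2 eligible columns (all too gappy)")
    X = _msa_state_matrix(msa)[:, cols]
    w = sequence_weights(msa) if weights is None else np.asarray(weights, dtype=float)
    meff = w.sum()
    lam = pseudocount_fraction * meff
    q = N_STATES

    fi = np.full((L, q), lam / q, dtype=float)
    for pos in range(L):
        np.add.at(fi[pos], X[:, pos], w)
    fi /= lam + meff

    fij = np.full((L, L, q, q), lam / (q * q), dtype=float)
    for a in range(L):
        for b in range(a + 1, L):
            tab = np.zeros((q, q))
            np.add.at(tab, (X[:, a], X[:, b]), w)
            fij[a, b] += tab
            fij[b, a] += tab.T
    fij /= lam + meff
    # same-column convention: f_aa(x, y) = delta(x, y) * f_a(x)
    for a in range(L):
        fij[a, a] = np.diag(fi[a])

    # covariance over q-1 states per column (last state = gap is the reference)
    qm = q - 1
    C = np.empty((L * qm, L * qm))
    for a in range(L):
        for b in range(L):
            block = fij[a, b, :qm, :qm] - np.outer(fi[a, :qm], fi[b, :qm])
            C[a * qm : (a + 1) * qm, b * qm : (b + 1) * qm] = block
    try:
        invC = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise CoevoError(
            "singular covariance matrix; increase pseudocount_fraction"
        ) from exc
    J = -invC  # couplings in the mean-field approximation

    scores = []
    for a in range(L):
        for b in range(a + 1, L):
            eJ = np.ones((q, q))
            eJ[:qm, :qm] = np.exp(J[a * qm : (a + 1) * qm, b * qm : (b + 1) * qm])
            di = _direct_information(eJ, fi[a], fi[b])
            scores.append((cols[a], cols[b], di))
    return PairRanking(scores=scores, method="mfDCA", eligible_columns=cols)


def _direct_information(eJ: np.ndarray, fa: np.ndarray, fb: np.ndarray) -> float:
    """DI of the two-site model exp(J) with fields matched to the marginals."""
    mu_a = np.ones(N_STATES) / N_STATES
    mu_b = np.ones(N_STATES) / N_STATES
    for _ in range(200):
        new_a = fa / (eJ @ mu_b)
        new_a /= new_a.sum()
        new_b = fb / (eJ.T @ mu_a)
        new_b /= new_b.sum()
        if max(np.abs(new_a - mu_a).max(), np.abs(new_b - mu_b).max()) < 1e-12:
            mu_a, mu_b = new_a, new_b
            break
        mu_a, mu_b = new_a, new_b
    pdir = eJ * np.outer(mu_a, mu_b)
    pdir /= pdir.sum()
    outer = np.outer(fa, fb)
    nz = pdir > 0
    return float((pdir[nz] * np.log(pdir[nz] / outer[nz])).sum())


def rank_pairs(
    msa: MSA, method: Literal["MI", "mfDCA"], pseudocount: float = 0.5
) -> PairRanking:
    if method == "MI":
        return column_mi(msa, pseudocount=pseudocount)
    if method == "mfDCA":
        return mfdca_di(msa)
    raise CoevoError(f"unknown ranking method {method!r}")


def _tuple_counts(
    msa: MSA, column_pairs: Sequence[tuple[int, int]], weights: np.ndarray | None = None
) -> np.ndarray:
    """400x400 counts of pair->pair substitutions over all ordered row pairs.

    Each unordered column pair contributes in both orientations (i,j) and
    (j,i), and each row pair in both directions, so the result satisfies the
    swap identity by construction.  Tuples containing a gap are skipped.
    """
    X = _msa_state_matrix(msa)
    counts = np.zeros((400, 400))
    for i, j in column_pairs:
        for a, b in ((i, j), (j, i)):
            ca, cb = X[:, a], X[:, b]
            ok = (ca != GAP_STATE) & (cb != GAP_STATE)
            codes = 20 * ca[ok].astype(int) + cb[ok].astype(int)
            c = np.bincount(codes, minlength=400).astype(float)
            # ordered row pairs (s, t), s != t: outer product minus same-row diagonal
            counts += np.outer(c, c)
            counts[np.arange(400), np.arange(400)] -= c
    return counts


def build_ps400(
    msas: Sequence[MSA],
    ranking_method: Literal["MI", "mfDCA"] = "mfDCA",
    top_fraction: float = DEFAULT_TOP_FRACTION,
    pseudocount: float = 0.5,
) -> PairSubstitutionMatrix400:
    """Log-odds 400x400 pair-substitution table from one or more MSAs.

    Per MSA the top fraction of column pairs by the ranking statistic forms
    the foreground; all eligible column pairs form the background.  Entries
    are ln(P_fg / P_bg) with ``pseudocount`` added to every count cell.
    """
    if not msas:
        raise CoevoError("at least one MSA required")
    fg = np.zeros((400, 400))
    bg = np.zeros((400, 400))
    any_selected = False
    for msa in msas:
        ranking = rank_pairs(msa, ranking_method)
        all_pairs = [(i, j) for i, j, _ in ranking.scores]
        selected = ranking.top_fraction(top_fraction)
        if selected:
            any_selected = True
        fg += _tuple_counts(msa, selected)
        bg += _tuple_counts(msa, all_pairs)
    if not any_selected or fg.sum() == 0:
        raise CoevoError("no gap-free foreground observations")
    pfg = (fg + pseudocount) / (fg + pseudocount).sum()
    pbg = (bg + pseudocount) / (bg + pseudocount).sum()
    return PairSubstitutionMatrix400(scores=np.log(pfg / pbg), name="coevo400")


def build_protsub(
    msas: Sequence[MSA],
    ranking_method: Literal["MI", "mfDCA"] = "MI",
    top_fraction: float = DEFAULT_TOP_FRACTION,
    proximity_filters: Sequence[CorrelationMap | None] | None = None,
    pseudocount: float = 0.5,
) -> SubstitutionMatrix20:
    """Log-odds 20x20 table from single substitutions at correlated column pairs.

    ``proximity_filters`` optionally restricts each MSA's selected pairs to
    those in contact (maps are in MSA-column coordinates).  The background is
    the single-substitution frequency over all eligible columns.
    """
    if not msas:
        raise CoevoError("at least one MSA required")
    if proximity_filters is not None and len(proximity_filters) != len(msas):
        raise CoevoError("need one proximity filter (or None) per MSA")
    fg = np.zeros((20, 20))
    bg = np.zeros((20, 20))
    for idx, msa in enumerate(msas):
        ranking = rank_pairs(msa, ranking_method)
        selected = ranking.top_fraction(top_fraction)
        if proximity_filters is not None and proximity_filters[idx] is not None:
            contact = proximity_filters[idx]
            selected = [(i, j) for i, j in selected if contact.values[i, j] > 0]
        X = _msa_state_matrix(msa)
        fg_cols = sorted({c for pair in selected for c in pair})
        for c in fg_cols:
            fg += _single_counts(X[:, c])
        for c in ranking.eligible_columns:
            bg += _single_counts(X[:, c])
    if fg.sum() == 0:
        raise CoevoError("no foreground substitution observations")
    pfg = (fg + pseudocount) / (fg + pseudocount).sum()
    pbg = (bg + pseudocount) / (bg + pseudocount).sum()
    scores = np.log(pfg / pbg)
    scores = (scores + scores.T) / 2.0
    return SubstitutionMatrix20(scores=scores, name="coevo20")


def _single_counts(col: np.ndarray) -> np.ndarray:
    """20x20 counts of residue substitutions over ordered row pairs of one column."""
    ok = col != GAP_STATE
    c = np.bincount(col[ok].astype(int), minlength=20)[:20].astype(float)
    out = np.outer(c, c)
    out[np.arange(20), np.arange(20)] -= c
    return out


def to_half_bits(matrix: SubstitutionMatrix20) -> SubstitutionMatrix20:
    """Rescale a natural-log table to rounded half-bit units."""
    scaled = np.round(matrix.scores * (2.0 / np.log(2.0)))
    return SubstitutionMatrix20(scores=scaled, name=matrix.name + "_halfbits")
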