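"""Five-state pair-HMM local Viterbi alignment of two augmented profiles.

The alignment of profiles P(1..n) and Q(1..m) is modelled as a pair-HMM with
states MM, MI, IM, DG and GD describing which profile advances at each step
(match-match, match/insert, insert/match, delete/gap, gap/delete).  Five DP
matrices are filled; the MM recurrence adds the column match score M(i, j)
and takes a max with 0 so alignments can start anywhere (local alignment).
Gap penalties are the log transition probabilities of the underlying plan7
models, scaled by the gap weight Wg so that windowed column scores do not
swamp them.  Traceback starts at the global maximum of the MM matrix, which
is also the reported alignment score, and follows stored pointers back to a
local start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractViolation
from .hmm_io import (
    AlignHushProfile,
    T_DD,
    T_DM,
    T_II,
    T_IM,
    T_MD,
    T_MI,
    T_MM,
)
from .scoring import LOG_FLOOR, ScoringParams, match_score_matrix

# State codes (also the tie-break precedence after the local start)
MM, MI, IM, DG, GD = range(5)
STATE_NAMES = ("MM", "MI", "IM", "DG", "GD")
START = -1

NEG_INF = float("-inf")

# Move offsets (di, dj) consumed on entering each state
STATE_OFFSET = {MM: (1, 1), MI: (1, 0), IM: (0, 1), DG: (1, 0), GD: (0, 1)}


@dataclass
class PairAlignment:
    """A local profile-profile alignment.

    ``pairs`` lists the aligned match-state index pairs (1-based, MM steps
    only); ``path`` is the full state sequence, which begins and ends in MM.
    """

    query: str
    target: str
    pairs: list[tuple[int, int]]
    path: list[str]
    score: float
    start: tuple[int, int] = (0, 0)
    end: tuple[int, int] = (0, 0)
    evalue: float | None = None

    @property
    def is_empty(self) -> bool:
        return not self.pairs


def _wlog(trans: np.ndarray, wg: float) -> np.ndarray:
    """Wg-weighted log2 transition matrix with the -50 floor for zeros."""
    with np.errstate(divide="ignore"):
        lt = np.log2(trans)
    lt[~np.isfinite(lt)] = LOG_FLOOR
    np.maximum(lt, LOG_FLOOR, out=lt)
    return wg * lt


def viterbi_align(
    P: AlignHushProfile,
    Q: AlignHushProfile,
    params: ScoringParams | None = None,
    M: np.ndarray | None = None,
) -> PairAlignment:
    """Optimal local alignment of two profiles by the five-state Viterbi DP.

    ``M`` may carry a precomputed match-score matrix (as produced by
    :func:`alignhush.scoring.match_score_matrix`); otherwise it is computed
    from ``params``.
    """
    params = params or ScoringParams()
    n, m = len(P), len(Q)
    if M is None:
        M = match_score_matrix(P, Q, params)
    if M.shape != (n, m):
        raise ContractViolation("match-score matrix shape mismatch")

    lp = _wlog(P.trans_matrix, params.Wg)  # (n, 7)
    lq = _wlog(Q.trans_matrix, params.Wg)

    S = np.full((5, n + 1, m + 1), NEG_INF)
    ptr = np.full((5, n + 1, m + 1), START, dtype=np.int8)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # MM: local start (0) or continue from any state at (i-1, j-1),
            # paying the two models' transition terms out of nodes i-1/j-1.
            best, arg = 0.0, START
            if i >= 2 and j >= 2:
                pi, qj = i - 2, j - 2  # 0-based node i-1 / j-1
                cands = (
                    (S[MM, i - 1, j - 1] + lp[pi, T_MM] + lq[qj, T_MM], MM),
                    (S[MI, i - 1, j - 1] + lp[pi, T_MM] + lq[qj, T_IM], MI),
                    (S[IM, i - 1, j - 1] + lp[pi, T_IM] + lq[qj, T_MM], IM),
                    (S[DG, i - 1, j - 1] + lp[pi, T_DM] + lq[qj, T_MM], DG),
                    (S[GD, i - 1, j - 1] + lp[pi, T_MM] + lq[qj, T_DM], GD),
                )
                for v, a in cands:
                    if v > best:
                        best, arg = v, a
            S[MM, i, j] = M[i - 1, j - 1] + best
            ptr[MM, i, j] = arg

            if i >= 2:
                # MI: P advances by match, Q sits in insert after column j
                v_mm = S[MM, i - 1, j] + lp[i - 2, T_MM] + lq[j - 1, T_MI]
                v_mi = S[MI, i - 1, j] + lp[i - 2, T_MM] + lq[j - 1, T_II]
                if v_mm >= v_mi:
                    S[MI, i, j], ptr[MI, i, j] = v_mm, MM
                else:
                    S[MI, i, j], ptr[MI, i, j] = v_mi, MI
                # DG: P advances by delete
                v_mm = S[MM, i - 1, j] + lp[i - 2, T_MD]
                v_dg = S[DG, i - 1, j] + lp[i - 2, T_DD]
                if v_mm >= v_dg:
                    S[DG, i, j], ptr[DG, i, j] = v_mm, MM
                else:
                    S[DG, i, j], ptr[DG, i, j] = v_dg, DG
            if j >= 2:
                # IM: mirror of MI with the roles of P and Q exchanged
                v_mm = S[MM, i, j - 1] + lq[j - 2, T_MM] + lp[i - 1, T_MI]
                v_im = S[IM, i, j - 1] + lq[j - 2, T_MM] + lp[i - 1, T_II]
                if v_mm >= v_im:
                    S[IM, i, j], ptr[IM, i, j] = v_mm, MM
                else:
                    S[IM, i, j], ptr[IM, i, j] = v_im, IM
                # GD: mirror of DG on Q
                v_mm = S[MM, i, j - 1] + lq[j - 2, T_MD]
                v_gd = S[GD, i, j - 1] + lq[j - 2, T_DD]
                if v_mm >= v_gd:
                    S[GD, i, j], ptr[GD, i, j] = v_mm, MM
                else:
                    S[GD, i, j], ptr[GD, i, j] = v_gd, GD

    # Traceback from the MM-matrix maximum (ties: smallest i, then j).
    mm = S[MM, 1:, 1:]
    flat = int(np.argmax(mm))
    bi, bj = flat // m + 1, flat % m + 1
    best_score = float(S[MM, bi, bj])
    if best_score <= 0.0:
        return PairAlignment(
            query=P.name, target=Q.name, pairs=[], path=[], score=0.0
        )

    rev_states: list[int] = []
    rev_cells: list[tuple[int, int]] = []
    state, i, j = MM, bi, bj
    while True:
        rev_states.append(state)
        rev_cells.append((i, j))
        pred = int(ptr[state, i, j])
        if state == MM:
            if pred == START:
                break
            i, j = i - 1, j - 1
        elif state in (MI, DG):
            i -= 1
        else:  # IM, GD
            j -= 1
        state = pred

    states = rev_states[::-1]
    cells = rev_cells[::-1]
    pairs = [c for s, c in zip(states, cells) if s == MM]
    return PairAlignment(
        query=P.name,
        target=Q.name,
        pairs=pairs,
        path=[STATE_NAMES[s] for s in states],
        score=best_score,
        start=cells[0],
        end=cells[-1],
    )


def rescore_alignment(
    P: AlignHushProfile,
    Q: AlignHushProfile,
    aln: PairAlignment,
    params: ScoringParams | None = None,
    M: np.ndarray | None = None,
) -> float:
    """Recompute an alignment's score term by term along its path.

    Validates the path structurally (begins/ends in MM, legal state moves)
    and returns the sum of column match scores plus Wg-weighted transition
    log terms; for a Viterbi output this equals ``aln.score``.
    """
    params = params or ScoringParams()
    if aln.is_empty:
        return 0.0
    if M is None:
        M = match_score_matrix(P, Q, params)
    lp = _wlog(P.trans_matrix, params.Wg)
    lq = _wlog(Q.trans_matrix, params.Wg)

    codes = []
    for s in aln.path:
        if s not in STATE_NAMES:
            raise ContractViolation(f"unknown state {s!r} in path")
        codes.append(STATE_NAMES.index(s))
    if codes[0] != MM or codes[-1] != MM:
        raise ContractViolation("local alignment path must begin and end in MM")

    i, j = aln.start
    if not (1 <= i <= len(P) and 1 <= j <= len(Q)):
        raise ContractViolation(f"start cell {aln.start} out of range")
    score = M[i - 1, j - 1]
    mm_pairs = [(i, j)]
    for step, (a, b) in enumerate(zip(codes, codes[1:]), start=1):
        if a != MM and b != MM and b != a:
            raise ContractViolation(
                f"step {step}: illegal transition {STATE_NAMES[a]}->{STATE_NAMES[b]}"
            )
        di, dj = STATE_OFFSET[b]
        i0, j0 = i, j
        i, j = i + di, j + dj
        if i > len(P) or j > len(Q):
            raise ContractViolation(f"step {step}: path leaves the profiles")
        if b == MM:
            pi, qj = i - 2, j - 2
            term = {
                MM: lp[pi, T_MM] + lq[qj, T_MM],
                MI: lp[pi, T_MM] + lq[qj, T_IM],
                IM: lp[pi, T_IM] + lq[qj, T_MM],
                DG: lp[pi, T_DM] + lq[qj, T_MM],
                GD: lp[pi, T_MM] + lq[qj, T_DM],
            }[a]
            score += term + M[i - 1, j - 1]
            mm_pairs.append((i, j))
        elif b == MI:
            score += lp[i0 - 1, T_MM] + (lq[j - 1, T_MI] if a == MM else lq[j - 1, T_II])
        elif b == IM:
            score += lq[j0 - 1, T_MM] + (lp[i - 1, T_MI] if a == MM else lp[i - 1, T_II])
        elif b == DG:
            score += lp[i0 - 1, T_MD] if a == MM else lp[i0 - 1, T_DD]
        elif b == GD:
            score += lq[j0 - 1, T_MD] if a == MM else lq[j0 - 1, T_DD]
    if mm_pairs != aln.pairs:
        raise ContractViolation("MM pairs inconsistent with path")
    return float(score)


@dataclass
class Hit:
    """One ranked search result."""

    query: str
    target: str
    score: float
    evalue: float | None
    alignment: PairAlignment


def align_all(
    query: AlignHushProfile,
    database: list[AlignHushProfile],
    params: ScoringParams | None = None,
    fit=None,
) -> list[Hit]:
    """Align a query against every profile of a database and rank the hits.

    Ranking is by E-value when a calibration ``fit`` (an
    :class:`alignhush.stats.EvalueFit`) is given, else by score; ties break
    on target name so output order is deterministic.
    """
    params = params or ScoringParams()
    hits = []
    for target in database:
        aln = viterbi_align(query, target, params)
        ev = None
        if fit is not None:
            from .stats import evalue

            ev = evalue(aln.score, fit)
        hits.append(Hit(query.name, target.name, aln.score, ev, aln))
    if fit is not None:
        hits.sort(key=lambda h: (h.evalue, h.target))
    else:
        hits.sort(key=lambda h: (-h.score, h.target))
    return hits


def write_hits_tsv(hits: list[Hit], stream) -> None:
    stream.write("query\ttarget\tscore\tevalue\n")
    for h in hits:
        ev = "NA" if h.evalue is None else "%.4g" % h.evalue
        stream.write(f"{h.query}\t{h.target}\t{h.score:.4f}\t{ev}\n")


def write_alignment_report(
    aln: PairAlignment, stream, params: ScoringParams | None = None
) -> None:
    """Human-readable per-hit report plus the aligned-pair TSV block."""
    stream.write(f"# query  {aln.query}\n")
    stream.write(f"# target {aln.target}\n")
    stream.write(f"# score  {aln.score:.4f} bits\n")
    if aln.evalue is not None:
        stream.write(f"# evalue {aln.evalue:.4g}\n")
    if params is not None:
        for ln in params.describe().splitlines():
            stream.write(f"# param {ln}\n")
    if aln.is_empty:
        stream.write("# empty alignment\n")
        return
    stream.write(
        f"# range  query {aln.start[0]}-{aln.end[0]}, "
        f"target {aln.start[1]}-{aln.end[1]}\n"
    )
    stream.write("i\tj\tstate\n")
    i, j = aln.start
    it = iter(aln.pairs)
    for s in aln.path:
        if s == "MM":
            i, j = next(it)
            stream.write(f"{i}\t{j}\tMM\n")
        else:
            di, dj = STATE_OFFSET[STATE_NAMES.index(s)]
            i, j = i + di, j + dj
            stream.write(f"{i if s in ('MI', 'DG') else '-'}\t"
                         f"{j if s in ('IM', 'GD') else '-'}\t{s}\n")
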