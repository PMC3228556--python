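"""Independent oracle for the five-state local alignment score.

Explores every legal local path (start and end in an MM cell, moves and
transition terms exactly as the pair-HMM defines them) by plain recursive
enumeration, with no dynamic-programming tables, and returns the best path
score.  Exponential in profile length, so only usable for tiny profiles.
"""

from alignhush.align import _wlog
from alignhush.hmm_io import T_DD, T_DM, T_II, T_IM, T_MD, T_MI, T_MM
from alignhush.scoring import match_score_matrix

NEG_INF = float("-inf")


def brute_force_score(P, Q, params):
    M = match_score_matrix(P, Q, params)
    lp = _wlog(P.trans_matrix, params.Wg)
    lq = _wlog(Q.trans_matrix, params.Wg)
    n, m = len(P), len(Q)

    def cont(state, i, j):
        """Best score of any continuation after entering `state` at (i, j)."""
        best = 0.0 if state == "MM" else NEG_INF  # paths must end in MM
        if state == "MM":
            if i < n and j < m:
                best = max(best, lp[i - 1, T_MM] + lq[j - 1, T_MM]
                           + M[i, j] + cont("MM", i + 1, j + 1))
            if i < n:
                best = max(best, lp[i - 1, T_MM] + lq[j - 1, T_MI]
                           + cont("MI", i + 1, j))
                best = max(best, lp[i - 1, T_MD] + cont("DG", i + 1, j))
            if j < m:
                best = max(best, lq[j - 1, T_MM] + lp[i - 1, T_MI]
                           + cont("IM", i, j + 1))
                best = max(best, lq[j - 1, T_MD] + cont("GD", i, j + 1))
        elif state == "MI":
            if i < n and j < m:
                best = max(best, lp[i - 1, T_MM] + lq[j - 1, T_IM]
                           + M[i, j] + cont("MM", i + 1, j + 1))
            if i < n:
                best = max(best, lp[i - 1, T_MM] + lq[j - 1, T_II]
                           + cont("MI", i + 1, j))
        elif state == "IM":
            if i < n and j < m:
                best = max(best, lp[i - 1, T_IM] + lq[j - 1, T_MM]
                           + M[i, j] + cont("MM", i + 1, j + 1))
            if j < m:
                best = max(best, lq[j - 1, T_MM] + lp[i - 1, T_II]
                           + cont("IM", i, j + 1))
        elif state == "DG":
            if i < n and j < m:
                best = max(best, lp[i - 1, T_DM] + lq[j - 1, T_MM]
                           + M[i, j] + cont("MM", i + 1, j + 1))
            if i < n:
                best = max(best, lp[i - 1, T_DD] + cont("DG", i + 1, j))
        elif state == "GD":
            if i < n and j < m:
                best = max(best, lp[i - 1, T_MM] + lq[j - 1, T_DM]
                           + M[i, j] + cont("MM", i + 1, j + 1))
            if j < m:
                best = max(best, lq[j - 1, T_DD] + cont("GD", i, j + 1))
        return best

    best = NEG_INF
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            best = max(best, M[i - 1, j - 1] + cont("MM", i, j))
    return max(best, 0.0)
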