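"""Column-pair match scoring.

The score for aligning match state i of profile P with match state j of
profile Q combines three terms, each summed over a diagonal window of
neighbouring column pairs:

* conservation — the log-sum-of-odds co-emission score
  log2(sum_a P(ia) Q(ja) / b_a), computed as the log of the dot product of
  the stored sqrt-background-normalised odds vectors;
* hydrophobicity — similarity of column Kyte-Doolittle hydropathies,
  c0 - |Hx - Hy|;
* secondary structure — the bilinear form f(x)^T L f(y) over the 3-state
  substitution table.

Windowing exploits the fact that conservation in homologous proteins runs in
stretches: summing adjacent column-pair scores boosts genuinely homologous
patches while noise in unrelated patches averages out.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractViolation, FormatError
from .hmm_io import AlignHushProfile, MatchState
from .ss_subst import SSSubstitutionTable, default_ss_table

# Floor replacing log2(0) everywhere (bits).
LOG_FLOOR = -50.0


def log2_floor(x: float) -> float:
    """log2 with zero mapped to the -50 bit floor instead of -inf."""
    return math.log2(x) if x > 0 else LOG_FLOOR


@dataclass
class ScoringParams:
    """Weights, window widths and the SS table for column-pair scoring.

    Defaults: conservation dominates (Wc=1) with hydrophobicity and secondary
    structure as weaker auxiliary signals (Wh=Ws=0.3); all three windows are
    5 columns; gap-transition log terms carry weight Wg=1.  The hydro_offset
    (Kyte-Doolittle units) sets the hydropathy difference at which the
    hydrophobic term crosses zero.
    """

    Wc: float = 1.0
    Wh: float = 0.3
    Ws: float = 0.3
    Wg: float = 1.0
    win_c: int = 5
    win_h: int = 5
    win_s: int = 5
    hydro_offset: float = 1.5
    ss_table: SSSubstitutionTable = field(default_factory=default_ss_table)

    def __post_init__(self) -> None:
        for w in ("Wc", "Wh", "Ws", "Wg"):
            v = getattr(self, w)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{w} must be finite and non-negative")
        for w in ("win_c", "win_h", "win_s"):
            v = getattr(self, w)
            if v < 1 or v % 2 == 0:
                raise ValueError(f"{w} must be an odd positive window width")

    _NUMERIC = ("Wc", "Wh", "Ws", "Wg", "hydro_offset")
    _INTS = ("win_c", "win_h", "win_s")

    def to_config(self, stream) -> None:
        """Write the effective parameter set as key = value lines."""
        for k in self._NUMERIC:
            stream.write(f"{k} = {getattr(self, k):g}\n")
        for k in self._INTS:
            stream.write(f"{k} = {getattr(self, k)}\n")

    @classmethod
    def from_config(cls, stream, **overrides) -> "ScoringParams":
        """Read key = value lines; unknown keys are an error."""
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        kwargs: dict = {}
        for ln in stream:
            ln = ln.split("#", 1)[0].strip()
            if not ln:
                continue
            if "=" not in ln:
                raise FormatError(f"bad config line: {ln!r}")
            k, v = (t.strip() for t in ln.split("=", 1))
            if k in cls._NUMERIC:
                kwargs[k] = float(v)
            elif k in cls._INTS:
                kwargs[k] = int(v)
            else:
                raise FormatError(f"unknown scoring parameter {k!r}")
        kwargs.update(overrides)
        return cls(**kwargs)

    def describe(self) -> str:
        buf = io.StringIO()
        self.to_config(buf)
        return buf.getvalue()


# ---------------------------------------------------------------------------
# raw per-column-pair terms


def conservation_score(x: MatchState, y: MatchState) -> float:
    """log2 sum_a P(xa) Q(ya) / b_a, via the stored sqrt-odds vectors."""
    return log2_floor(float(x.odds @ y.odds))


def hydrophobic_score(hx: float, hy: float, hydro_offset: float) -> float:
    """hydro_offset - |Hx - Hy|: positive when hydropathies are similar."""
    return hydro_offset - abs(hx - hy)


def ss_score(fx: np.ndarray, fy: np.ndarray, table: SSSubstitutionTable) -> float:
    """Bilinear form fx^T L fy over the 3-state substitution table."""
    return float(np.asarray(fx) @ table.L @ np.asarray(fy))


def windowed_term(term_fn, P, Q, i: int, j: int, width: int) -> float:
    """Sum term_fn over the diagonal window of half-width (width-1)//2 around
    (i, j), truncated at profile ends (1-based indices)."""
    n, m = len(P), len(Q)
    if not (1 <= i <= n and 1 <= j <= m):
        raise ContractViolation(f"window centre ({i}, {j}) out of range")
    w = (width - 1) // 2
    total = 0.0
    for k in range(-w, w + 1):
        ii, jj = i + k, j + k
        if 1 <= ii <= n and 1 <= jj <= m:
            total += term_fn(P, Q, ii, jj)
    return total


def _cons_at(P: AlignHushProfile, Q: AlignHushProfile, i: int, j: int) -> float:
    return conservation_score(P.states[i - 1], Q.states[j - 1])


def _hydro_at(P, Q, i, j, hydro_offset):
    return hydrophobic_score(
        P.states[i - 1].hydrophobicity, Q.states[j - 1].hydrophobicity, hydro_offset
    )


def _ss_at(P, Q, i, j, table):
    sx, sy = P.states[i - 1], Q.states[j - 1]
    if not (sx.ss_annotated and sy.ss_annotated):
        return 0.0
    return ss_score(sx.ss_freq, sy.ss_freq, table)


def column_match_score(
    P: AlignHushProfile, Q: AlignHushProfile, i: int, j: int, params: ScoringParams
) -> float:
    """Weighted sum of the three windowed terms at column pair (i, j)."""
    total = 0.0
    if params.Wc:
        total += params.Wc * windowed_term(_cons_at, P, Q, i, j, params.win_c)
    if params.Wh:
        total += params.Wh * windowed_term(
            lambda P, Q, a, b: _hydro_at(P, Q, a, b, params.hydro_offset),
            P, Q, i, j, params.win_h,
        )
    if params.Ws:
        total += params.Ws * windowed_term(
            lambda P, Q, a, b: _ss_at(P, Q, a, b, params.ss_table),
            P, Q, i, j, params.win_s,
        )
    return total


# ---------------------------------------------------------------------------
# dense match-score matrix (vectorised; used by the aligner)


def _window_sum(raw: np.ndarray, width: int) -> np.ndarray:
    """Sum of diagonal shifts of a raw (n, m) term matrix, truncated at the
    edges: out[i, j] = sum_k raw[i+k, j+k] for offsets in range."""
    if width == 1:
        return raw
    w = (width - 1) // 2
    out = raw.copy()
    for k in range(1, w + 1):
        out[k:, k:] += raw[:-k, :-k]
        out[:-k, :-k] += raw[k:, k:]
    return out


def match_score_matrix(
    P: AlignHushProfile, Q: AlignHushProfile, params: ScoringParams
) -> np.ndarray:
    """(n, m) matrix of M(i, j) for all column pairs (0-based storage)."""
    n, m = len(P), len(Q)
    M = np.zeros((n, m))
    if params.Wc:
        dot = P.odds_matrix @ Q.odds_matrix.T
        cons = np.where(dot > 0, np.log2(np.where(dot > 0, dot, 1.0)), LOG_FLOOR)
        M += params.Wc * _window_sum(cons, params.win_c)
    if params.Wh:
        diff = np.abs(P.hydro_vector[:, None] - Q.hydro_vector[None, :])
        M += params.Wh * _window_sum(params.hydro_offset - diff, params.win_h)
    if params.Ws:
        ss = P.ss_matrix @ params.ss_table.L @ Q.ss_matrix.T
        mask = P.ss_annotated_mask[:, None] & Q.ss_annotated_mask[None, :]
        M += params.Ws * _window_sum(np.where(mask, ss, 0.0), params.win_s)
    return M
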