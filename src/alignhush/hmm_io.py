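"""Profile HMM input/output.

Reads HMMER2 plan7 ASCII files, converts their integer log-odds scores back to
probabilities, and re-encodes the result into the augmented profile form used
by the aligner: per match state, emission odds ratios ``e(a) = p(a)/sqrt(b_a)``
together with a column hydrophobicity value, a 3-state secondary-structure
frequency vector and the seven plan7 transition probabilities.  Storing
emissions divided by the square root of the background lets the column
co-emission score be computed as a plain dot product of two stored vectors.

A versioned plain-text interchange format (``.ah``) serialises the augmented
profile losslessly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AnnotationError,
    FormatError,
    TruncationError,
    VersionError,
)

# Amino-acid alphabet: alphabetical order of one-letter codes, the ordering
# used by HMMER2 plan7 files and by every 20-vector in this package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA = 20

# plan7 integer score scale (HMMER2 INTSCALE): prob = null * 2**(score/1000)
INTSCALE = 1000.0
# Integer sentinel for "impossible" (probability zero), written as "*" in text.
P7_SENTINEL = -987654321

# Transition vector ordering used everywhere: leaving-node transitions
# (M->M, M->I, M->D, I->M, I->I, D->M, D->D)
TRANS_NAMES = ("mm", "mi", "md", "im", "ii", "dm", "dd")
T_MM, T_MI, T_MD, T_IM, T_II, T_DM, T_DD = range(7)

_AH_MAGIC = "ALIGNHUSH"
_AH_VERSION = 1


@dataclass
class RawPlan7HMM:
    """A HMMER2 plan7 model as integer scores, before probability conversion."""

    name: str
    length: int
    match_scores: np.ndarray  # (n, 20) int
    insert_scores: np.ndarray  # (n, 20) int, parsed then unused downstream
    trans_scores: np.ndarray  # (n, 7) int
    null_scores: np.ndarray  # (20,) int, relative to uniform 1/20
    specials: list[str] = field(default_factory=list)  # begin/end lines, opaque


@dataclass
class Background:
    """Amino-acid background frequencies b_a (sum to 1)."""

    b: np.ndarray

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        if self.b.shape != (N_AA,):
            raise ValueError("background must have 20 entries")
        if np.any(self.b <= 0):
            raise ValueError("background entries must be positive")
        if abs(self.b.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")


def uniform_background() -> Background:
    return Background(np.full(N_AA, 1.0 / N_AA))


@dataclass
class MatchState:
    """One profile column: emission odds, hydrophobicity, SS frequencies,
    and the seven outgoing plan7 transition probabilities."""

    odds: np.ndarray  # (20,) p(a)/sqrt(b_a)
    hydrophobicity: float  # Kyte-Doolittle units
    ss_freq: np.ndarray  # (3,) helix, sheet, loop
    trans: np.ndarray  # (7,) probabilities
    ss_annotated: bool = True

    def emission_probs(self, background: Background) -> np.ndarray:
        """Recover p(a) = odds(a) * sqrt(b_a)."""
        return self.odds * np.sqrt(background.b)


@dataclass
class AlignHushProfile:
    """Ordered match states plus the shared background; columns are 1-based
    in all public coordinates."""

    name: str
    states: list[MatchState]
    background: Background
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.states) < 1:
            raise ValueError("profile needs at least one match state")
        self._cache: dict[str, np.ndarray] = {}

    def __len__(self) -> int:
        return len(self.states)

    # Dense views used by the scorer; built lazily, invalidated never
    # (profiles are treated as immutable after construction).
    def _dense(self, key: str) -> np.ndarray:
        if key not in self._cache:
            if key == "odds":
                m = np.stack([s.odds for s in self.states])
            elif key == "hydro":
                m = np.array([s.hydrophobicity for s in self.states])
            elif key == "ss":
                m = np.stack([s.ss_freq for s in self.states])
            elif key == "trans":
                m = np.stack([s.trans for s in self.states])
            elif key == "ss_mask":
                m = np.array([s.ss_annotated for s in self.states], dtype=bool)
            else:  # pragma: no cover
                raise KeyError(key)
            self._cache[key] = m
        return self._cache[key]

    @property
    def odds_matrix(self) -> np.ndarray:
        return self._dense("odds")

    @property
    def hydro_vector(self) -> np.ndarray:
        return self._dense("hydro")

    @property
    def ss_matrix(self) -> np.ndarray:
        return self._dense("ss")

    @property
    def trans_matrix(self) -> np.ndarray:
        return self._dense("trans")

    @property
    def ss_annotated_mask(self) -> np.ndarray:
        return self._dense("ss_mask")


# ---------------------------------------------------------------------------
# plan7 parsing


def _parse_score(tok: str) -> int:
    if tok == "*":
        return P7_SENTINEL
    try:
        return int(tok)
    except ValueError as e:
        raise FormatError(f"bad plan7 score token {tok!r}") from e


def _fmt_score(s: int) -> str:
    return "*" if s == P7_SENTINEL else str(int(s))


def parse_hmmer2(stream) -> RawPlan7HMM:
    """Parse a HMMER2 plan7 ASCII model from a text stream or string.

    Insert emission scores are parsed and kept on the raw record (they are
    discarded at re-encoding time, since only the probability of an insert
    opening matters to profile-profile alignment, not its composition).
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.rstrip("\n") for ln in stream]
    if not lines or not lines[0].startswith("HMMER2"):
        head = lines[0] if lines else "<empty>"
        raise FormatError(f"not a HMMER2 file: first line {head!r}")

    name = ""
    length = 0
    null_scores: np.ndarray | None = None
    i = 1
    while i < len(lines) and not lines[i].startswith("HMM "):
        ln = lines[i]
        if ln.startswith("NAME"):
            name = ln.split(None, 1)[1].strip() if len(ln.split()) > 1 else ""
        elif ln.startswith("LENG"):
            try:
                length = int(ln.split()[1])
            except (IndexError, ValueError) as e:
                raise FormatError(f"bad LENG line: {ln!r}") from e
        elif ln.startswith("NULE"):
            toks = ln.split()[1:]
            if len(toks) != N_AA:
                raise FormatError(f"NULE line has {len(toks)} entries, expected 20")
            null_scores = np.array([_parse_score(t) for t in toks])
        i += 1
    if i >= len(lines):
        raise FormatError("missing HMM section header")
    if length < 1:
        raise FormatError("missing or invalid LENG declaration")
    if null_scores is None:
        null_scores = np.zeros(N_AA, dtype=int)  # uniform null

    i += 1  # skip "HMM  A  C ..." column header
    if i < len(lines) and "m->m" in lines[i]:
        i += 1  # skip transition-name header

    # Opaque special lines (begin-state transitions etc.) precede node 1.
    specials: list[str] = []
    while i < len(lines):
        toks = lines[i].split()
        if toks and toks[0].isdigit():
            break
        if toks and toks[0] != "//":
            specials.append(lines[i])
        i += 1

    match_scores = np.zeros((length, N_AA), dtype=np.int64)
    insert_scores = np.zeros((length, N_AA), dtype=np.int64)
    trans_scores = np.zeros((length, 7), dtype=np.int64)
    node = 0
    while i < len(lines) and lines[i].split() and lines[i].split()[0] != "//":
        toks = lines[i].split()
        if not toks[0].isdigit():
            raise FormatError(f"expected node line, got: {lines[i]!r}")
        if int(toks[0]) != node + 1:
            raise FormatError(
                f"node number {toks[0]} out of order (expected {node + 1})"
            )
        if node >= length:
            raise TruncationError(
                f"more node blocks than declared length {length}"
            )
        if len(toks) < 1 + N_AA:
            raise FormatError(f"match line of node {node + 1} has too few scores")
        match_scores[node] = [_parse_score(t) for t in toks[1 : 1 + N_AA]]
        if i + 2 >= len(lines):
            raise TruncationError(f"node block {node + 1} incomplete")
        itoks = lines[i + 1].split()
        if len(itoks) < 1 + N_AA:
            raise FormatError(f"insert line of node {node + 1} has too few scores")
        insert_scores[node] = [_parse_score(t) for t in itoks[1 : 1 + N_AA]]
        ttoks = lines[i + 2].split()
        if len(ttoks) < 1 + 7:
            raise FormatError(
                f"transition line of node {node + 1} has too few scores"
            )
        trans_scores[node] = [_parse_score(t) for t in ttoks[1:8]]
        node += 1
        i += 3

    if node != length:
        raise TruncationError(
            f"declared length {length} but found {node} node block(s)"
        )
    return RawPlan7HMM(
        name=name,
        length=length,
        match_scores=match_scores,
        insert_scores=insert_scores,
        trans_scores=trans_scores,
        null_scores=null_scores,
        specials=specials,
    )


def write_hmmer2(raw: RawPlan7HMM, stream) -> None:
    """Serialise a raw plan7 model back to HMMER2 ASCII."""
    w = stream.write
    w("HMMER2.0  [alignhush]\n")
    w(f"NAME  {raw.name}\n")
    w(f"LENG  {raw.length}\n")
    w("ALPH  Amino\n")
    w("NULE  " + " ".join(_fmt_score(s) for s in raw.null_scores) + "\n")
    w("HMM        " + "      ".join(AMINO_ACIDS) + "\n")
    w("         m->m   m->i   m->d   i->m   i->i   d->m   d->d   b->m   m->e\n")
    for ln in raw.specials:
        w(ln + "\n")
    for k in range(raw.length):
        w(f"{k + 1:6d} " + " ".join(_fmt_score(s) for s in raw.match_scores[k]) + "\n")
        w("     - " + " ".join(_fmt_score(s) for s in raw.insert_scores[k]) + "\n")
        w(
            "     - "
            + " ".join(_fmt_score(s) for s in raw.trans_scores[k])
            + " * *\n"
        )
    w("//\n")


# ---------------------------------------------------------------------------
# score -> probability conversion


def _scores_to_prob(scores: np.ndarray, null: np.ndarray) -> np.ndarray:
    """prob = null * 2**(score/INTSCALE); sentinel -> 0."""
    scores = np.asarray(scores, dtype=float)
    out = null * np.exp2(scores / INTSCALE)
    out[np.asarray(scores) == P7_SENTINEL] = 0.0
    return out


def scores_to_probs(
    raw: RawPlan7HMM,
) -> tuple[np.ndarray, np.ndarray, Background]:
    """Convert integer plan7 scores to probabilities.

    Returns per-node match emission probabilities (n, 20), per-node transition
    probabilities (n, 7), and the background derived from the null line
    (``b_a = (1/20) * 2**(null_score/1000)``, renormalised).  Transition
    probabilities are clamped to [0, 1] and each outgoing group (M->, I->,
    D->) renormalised so that log-transition terms stay non-positive.
    """
    b = _scores_to_prob(raw.null_scores, np.full(N_AA, 1.0 / N_AA))
    if np.any(b <= 0):
        raise FormatError("null model yields non-positive background frequency")
    background = Background(b / b.sum())

    emissions = np.empty((raw.length, N_AA))
    for k in range(raw.length):
        emissions[k] = _scores_to_prob(raw.match_scores[k], background.b)

    transitions = np.empty((raw.length, 7))
    for k in range(raw.length):
        t = _scores_to_prob(raw.trans_scores[k], np.ones(7))
        t = np.clip(t, 0.0, 1.0)
        for group in ((T_MM, T_MI, T_MD), (T_IM, T_II), (T_DM, T_DD)):
            s = t[list(group)].sum()
            if s > 0:
                t[list(group)] /= s
        transitions[k] = t
    return emissions, transitions, background


def probs_to_scores(probs: np.ndarray, null: np.ndarray) -> np.ndarray:
    """Inverse conversion: score = round(1000 * log2(p/null)); 0 -> sentinel."""
    probs = np.asarray(probs, dtype=float)
    out = np.full(probs.shape, P7_SENTINEL, dtype=np.int64)
    pos = probs > 0
    out[pos] = np.rint(INTSCALE * np.log2(probs[pos] / null[pos])).astype(np.int64)
    return out


# ---------------------------------------------------------------------------
# re-encoding


def encode_alignhush(
    emissions: np.ndarray,
    transitions: np.ndarray,
    background: Background,
    hydro: np.ndarray | None = None,
    ss: np.ndarray | None = None,
    name: str = "",
    provenance: str = "",
) -> AlignHushProfile:
    """Build the augmented profile from probability-space inputs.

    Emissions are renormalised to sum to 1 per node (insert emissions having
    been stripped) and stored as ``p(a)/sqrt(b_a)``.  ``hydro`` is a per-node
    hydrophobicity vector and ``ss`` a per-node (n, 3) frequency matrix; when
    ``ss`` is None the states are flagged unannotated and carry a uniform
    placeholder vector that the scorer ignores.
    """
    emissions = np.asarray(emissions, dtype=float)
    transitions = np.asarray(transitions, dtype=float)
    n = emissions.shape[0]
    if hydro is not None and len(hydro) != n:
        raise AnnotationError(
            f"hydrophobicity vector length {len(hydro)} != profile length {n}"
        )
    if ss is not None and len(ss) != n:
        raise AnnotationError(
            f"SS frequency matrix length {len(ss)} != profile length {n}"
        )
    sqrt_b = np.sqrt(background.b)
    states = []
    for k in range(n):
        p = emissions[k]
        total = p.sum()
        if total <= 0:
            raise AnnotationError(f"node {k + 1} has no emission probability mass")
        p = p / total
        annotated = ss is not None
        f = np.asarray(ss[k], dtype=float) if annotated else np.full(3, 1.0 / 3.0)
        states.append(
            MatchState(
                odds=p / sqrt_b,
                hydrophobicity=float(hydro[k]) if hydro is not None else 0.0,
                ss_freq=f,
                trans=transitions[k].astype(float),
                ss_annotated=annotated,
            )
        )
    return AlignHushProfile(
        name=name, states=states, background=background, provenance=provenance
    )


def profile_from_hmmer2(
    stream,
    hydro: np.ndarray | None = None,
    ss: np.ndarray | None = None,
) -> AlignHushProfile:
    """Convenience: parse plan7, convert scores, encode the augmented profile."""
    raw = parse_hmmer2(stream)
    emissions, transitions, background = scores_to_probs(raw)
    return profile_from_raw(raw, emissions, transitions, background, hydro, ss)


def profile_from_raw(
    raw: RawPlan7HMM,
    emissions: np.ndarray,
    transitions: np.ndarray,
    background: Background,
    hydro: np.ndarray | None = None,
    ss: np.ndarray | None = None,
) -> AlignHushProfile:
    return encode_alignhush(
        emissions,
        transitions,
        background,
        hydro=hydro,
        ss=ss,
        name=raw.name,
        provenance="converted from plan7",
    )


# ---------------------------------------------------------------------------
# augmented-profile interchange format
#
# Plain text, versioned.  Numeric fields use scientific notation with 10
# significant digits so round trips are lossless to well below 1e-9.

_NUM = "%.9e"


def _fmt_vec(v) -> str:
    return " ".join(_NUM % x for x in v)


def write_profile(profile: AlignHushProfile, stream) -> None:
    w = stream.write
    w(f"{_AH_MAGIC} {_AH_VERSION}\n")
    w(f"NAME {profile.name}\n")
    w(f"LENG {len(profile)}\n")
    if profile.provenance:
        w(f"PROV {profile.provenance}\n")
    w("BKG " + _fmt_vec(profile.background.b) + "\n")
    for k, st in enumerate(profile.states, start=1):
        w(f"STATE {k}\n")
        w("  ODDS " + _fmt_vec(st.odds) + "\n")
        w("  HYD " + _NUM % st.hydrophobicity + "\n")
        if st.ss_annotated:
            w("  SS " + _fmt_vec(st.ss_freq) + "\n")
        else:
            w("  SS NA\n")
        w("  TRANS " + _fmt_vec(st.trans) + "\n")
    w("//\n")


def read_profile(stream) -> AlignHushProfile:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.strip() for ln in stream if ln.strip()]
    if not lines:
        raise FormatError("empty profile file")
    head = lines[0].split()
    if len(head) != 2 or head[0] != _AH_MAGIC:
        raise FormatError(f"not an AlignHUSH profile: header {lines[0]!r}")
    if int(head[1]) != _AH_VERSION:
        raise VersionError(f"unsupported profile format version {head[1]}")

    name, provenance, length = "", "", 0
    background: Background | None = None
    states: list[MatchState] = []
    i = 1

    def vec(tokens, n, what):
        if len(tokens) != n:
            raise FormatError(f"{what}: expected {n} fields, got {len(tokens)}")
        return np.array([float(t) for t in tokens])

    while i < len(lines) and lines[i] != "//":
        toks = lines[i].split()
        key = toks[0]
        if key == "NAME":
            name = lines[i][5:].strip()
        elif key == "LENG":
            length = int(toks[1])
        elif key == "PROV":
            provenance = lines[i][5:].strip()
        elif key == "BKG":
            background = Background(vec(toks[1:], N_AA, "BKG"))
        elif key == "STATE":
            if int(toks[1]) != len(states) + 1:
                raise FormatError(f"state index {toks[1]} out of order")
            if i + 4 >= len(lines):
                raise TruncationError(f"state block {toks[1]} incomplete")
            otoks = lines[i + 1].split()
            htoks = lines[i + 2].split()
            stoks = lines[i + 3].split()
            ttoks = lines[i + 4].split()
            if otoks[0] != "ODDS" or htoks[0] != "HYD" or stoks[0] != "SS" or ttoks[0] != "TRANS":
                raise FormatError(f"malformed state block {toks[1]}")
            annotated = stoks[1] != "NA"
            states.append(
                MatchState(
                    odds=vec(otoks[1:], N_AA, "ODDS"),
                    hydrophobicity=float(htoks[1]),
                    ss_freq=vec(stoks[1:], 3, "SS")
                    if annotated
                    else np.full(3, 1.0 / 3.0),
                    trans=vec(ttoks[1:], 7, "TRANS"),
                    ss_annotated=annotated,
                )
            )
            i += 4
        else:
            raise FormatError(f"unknown record {key!r}")
        i += 1

    if background is None:
        raise FormatError("missing BKG record")
    if length != len(states):
        raise TruncationError(
            f"declared length {length} but found {len(states)} state block(s)"
        )
    return AlignHushProfile(
        name=name, states=states, background=background, provenance=provenance
    )


def load_profile(path) -> AlignHushProfile:
    with open(path) as fh:
        return read_profile(fh)


def save_profile(profile: AlignHushProfile, path) -> None:
    with open(path, "w") as fh:
        write_profile(profile, fh)
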