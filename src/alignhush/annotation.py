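"""Column-level profile annotation.

Derives from an MSA the two extra per-column signals the aligner scores:
hydrophobicity (the emission-weighted mean Kyte-Doolittle hydropathy of the
column) and a 3-state secondary-structure frequency vector (counted over
per-sequence predicted SS strings, e.g. PSIPRED output).  Also assigns MSA
columns to match/insert states by gap fraction, mirroring the usual profile
HMM construction heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import AlignIO

from .errors import AnnotationError, EmptyProfileError
from .hmm_io import AA_INDEX

import numpy as np

# Kyte-Doolittle hydropathy scale, indexed by one-letter code.
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# (20,) vector aligned with the package amino-acid ordering
KD_VECTOR = np.array([KYTE_DOOLITTLE[a] for a in sorted(KYTE_DOOLITTLE)])

SS_STATES = "HEC"  # helix, sheet, loop/coil
SS_INDEX = {"H": 0, "E": 1, "C": 2}
GAP_CHARS = set("-.")

MATCH, INSERT = "match", "insert"


def map_ss_state(ch: str) -> int:
    """3-state mapping: H -> helix, E -> sheet, anything else -> loop."""
    return SS_INDEX.get(ch.upper(), 2)


@dataclass
class AnnotatedMSA:
    """An alignment plus optional per-sequence (unaligned) SS strings."""

    sequences: list[tuple[str, str]]  # (id, aligned residue string)
    ss_strings: dict[str, str] = field(default_factory=dict)
    column_assignment: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("MSA must contain at least one sequence")
        width = len(self.sequences[0][1])
        for sid, s in self.sequences:
            if len(s) != width:
                raise ValueError(f"sequence {sid} has inconsistent aligned length")
        for sid, ss in self.ss_strings.items():
            ungapped = self.ungapped_length(sid)
            if len(ss) != ungapped:
                raise AnnotationError(
                    f"SS string for {sid} has length {len(ss)}, "
                    f"ungapped sequence has {ungapped}"
                )

    @property
    def width(self) -> int:
        return len(self.sequences[0][1])

    def ungapped_length(self, seq_id: str) -> int:
        for sid, s in self.sequences:
            if sid == seq_id:
                return sum(c not in GAP_CHARS for c in s)
        raise KeyError(seq_id)


def read_aligned_fasta(path_or_handle) -> AnnotatedMSA:
    """Read an aligned-FASTA MSA via Biopython."""
    aln = AlignIO.read(path_or_handle, "fasta")
    return AnnotatedMSA(sequences=[(rec.id, str(rec.seq).upper()) for rec in aln])


def read_ss_tsv(path_or_handle) -> dict[str, str]:
    """Two-column TSV (sequence id, 3-state SS string)."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle) as fh:
            return read_ss_tsv(fh)
    out: dict[str, str] = {}
    for ln in path_or_handle:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) != 2:
            raise AnnotationError(f"bad SS TSV line: {ln!r}")
        out[parts[0]] = parts[1].upper()
    return out


def read_psipred_ss2(path_or_handle) -> str:
    """PSIPRED vertical (.ss2) file -> 3-state string (argmax column)."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle) as fh:
            return read_psipred_ss2(fh)
    states = []
    for ln in path_or_handle:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split()
        # position, residue, state, then three confidences (ignored)
        if len(parts) < 3:
            raise AnnotationError(f"bad .ss2 line: {ln!r}")
        states.append(parts[2])
    return "".join(states)


def read_psipred_horiz(path_or_handle) -> str:
    """PSIPRED horizontal (.horiz) file -> 3-state string from Pred: lines."""
    if isinstance(path_or_handle, str):
        with open(path_or_handle) as fh:
            return read_psipred_horiz(fh)
    chunks = []
    for ln in path_or_handle:
        if ln.startswith("Pred:"):
            chunks.append(ln[5:].strip())
    return "".join(chunks)


# ---------------------------------------------------------------------------


def assign_match_columns(
    msa: AnnotatedMSA, gap_fraction_threshold: float = 0.5
) -> list[str]:
    """Label each column match or insert by gap fraction.

    Columns where the fraction of gap characters is <= the threshold become
    match columns (one profile node each); the rest are insert columns.
    """
    n_seq = len(msa.sequences)
    assignment = []
    for c in range(msa.width):
        gaps = sum(1 for _, s in msa.sequences if s[c] in GAP_CHARS)
        assignment.append(MATCH if gaps / n_seq <= gap_fraction_threshold else INSERT)
    if all(a == INSERT for a in assignment):
        raise EmptyProfileError("no column passes the match-column threshold")
    msa.column_assignment = assignment
    return assignment


def column_hydrophobicity(p: np.ndarray, kd: np.ndarray = KD_VECTOR) -> float:
    """Emission-weighted mean hydropathy H = sum_a p(a) * kd(a)."""
    p = np.asarray(p, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("emission vector must sum to 1")
    return float(p @ kd)


def ss_column_frequencies(msa: AnnotatedMSA) -> np.ndarray:
    """Per-match-column (helix, sheet, loop) frequencies.

    Only sequences with an SS string contribute; a gap cell contributes
    nothing.  Frequencies are counts over the annotated non-gap residues of
    the column, so every returned row sums to exactly 1.
    """
    if msa.column_assignment is None:
        raise AnnotationError("column assignment must be computed first")
    if not msa.ss_strings:
        raise AnnotationError("no SS strings available")

    # per-sequence map: aligned column -> SS state index (annotated, non-gap)
    col_states: list[dict[int, int]] = []
    for sid, s in msa.sequences:
        ss = msa.ss_strings.get(sid)
        if ss is None:
            continue
        mapping: dict[int, int] = {}
        r = 0
        for c, ch in enumerate(s):
            if ch not in GAP_CHARS:
                mapping[c] = map_ss_state(ss[r])
                r += 1
        col_states.append(mapping)

    rows = []
    for c, label in enumerate(msa.column_assignment):
        if label != MATCH:
            continue
        counts = np.zeros(3)
        for mapping in col_states:
            if c in mapping:
                counts[mapping[c]] += 1
        total = counts.sum()
        if total == 0:
            # match column with no annotated residue: fall back to loop
            counts[2] = 1.0
            total = 1.0
        rows.append(counts / total)
    return np.array(rows)


def match_column_emissions(
    msa: AnnotatedMSA,
    background: np.ndarray,
    pseudocount: float = 1.0,
) -> np.ndarray:
    """Per-match-column emission probabilities from residue counts.

    counts + pseudocount * b_a, normalised by (N_nongap + pseudocount).
    """
    if msa.column_assignment is None:
        raise AnnotationError("column assignment must be computed first")
    rows = []
    for c, label in enumerate(msa.column_assignment):
        if label != MATCH:
            continue
        counts = np.zeros(len(background))
        n = 0
        for _, s in msa.sequences:
            ch = s[c]
            if ch in GAP_CHARS:
                continue
            idx = AA_INDEX.get(ch)
            if idx is None:
                continue  # ambiguous residue: excluded from counts
            counts[idx] += 1
            n += 1
        rows.append((counts + pseudocount * background) / (n + pseudocount))
    return np.array(rows)
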