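"""Secondary-structure substitution scoring table.

A symmetric 3x3 log-odds table L(s, s') over (helix, sheet, loop), estimated
from pairs of structurally aligned 3-state strings: joint substitution counts
are symmetrised, a pseudocount added, and each cell converted to
log2(P(s, s') / (P(s) P(s'))).  The bundled default table is estimated from
the package's synthetic SS-conserving alignment generator and is an
approximation; users with curated structural alignments should estimate and
supply their own.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .annotation import map_ss_state
from .errors import EstimationError, FormatError

_HEADER = ("H", "E", "C")


@dataclass
class SSSubstitutionTable:
    """Symmetric 3x3 log2-odds matrix, rows/cols ordered helix, sheet, loop."""

    L: np.ndarray
    meta: str = ""

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.shape != (3, 3):
            raise ValueError("SS substitution table must be 3x3")
        if not np.all(np.isfinite(self.L)):
            raise ValueError("SS substitution table entries must be finite")
        if np.max(np.abs(self.L - self.L.T)) > 1e-9:
            raise ValueError("SS substitution table must be symmetric")
        self.L = 0.5 * (self.L + self.L.T)  # exact symmetry


def estimate_ss_table(
    paired_ss_alignments: list[tuple[str, str]],
    pseudocount: float = 1.0,
) -> SSSubstitutionTable:
    """Estimate L from aligned 3-state string pairs.

    Counts are accumulated over all aligned positions, symmetrised
    (N(s,s') <- N(s,s') + N(s',s)), and a pseudocount added to every cell;
    marginals are taken from the symmetrised joint.
    """
    if not paired_ss_alignments:
        raise EstimationError("no aligned SS string pairs given")
    counts = np.zeros((3, 3))
    for a, b in paired_ss_alignments:
        if len(a) != len(b):
            raise EstimationError(
                f"aligned SS strings differ in length ({len(a)} vs {len(b)})"
            )
        for ca, cb in zip(a, b):
            counts[map_ss_state(ca), map_ss_state(cb)] += 1
    counts = counts + counts.T
    counts = counts + pseudocount
    total = counts.sum()
    if total <= 0:
        raise EstimationError("no substitution counts accumulated")
    joint = counts / total
    marginal = joint.sum(axis=1)
    with np.errstate(divide="ignore"):
        L = np.log2(joint / np.outer(marginal, marginal))
    L[~np.isfinite(L)] = -50.0  # zero-count cells: package-wide log floor
    return SSSubstitutionTable(L=L, meta=f"estimated, pseudocount={pseudocount}")


def write_ss_table(table: SSSubstitutionTable, stream) -> None:
    if table.meta:
        stream.write(f"# {table.meta}\n")
    stream.write("\t" + "\t".join(_HEADER) + "\n")
    for i, name in enumerate(_HEADER):
        stream.write(name + "\t" + "\t".join("%.6f" % x for x in table.L[i]) + "\n")


def read_ss_table(stream) -> SSSubstitutionTable:
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    meta = ""
    rows = []
    header_seen = False
    for ln in stream:
        ln = ln.rstrip("\n")
        if not ln.strip():
            continue
        if ln.startswith("#"):
            meta = ln.lstrip("# ").strip()
            continue
        toks = ln.split()
        if not header_seen:
            if tuple(toks) != _HEADER:
                raise FormatError(f"bad SS table header: {ln!r}")
            header_seen = True
            continue
        if len(toks) != 4 or toks[0] != _HEADER[len(rows)]:
            raise FormatError(f"bad SS table row: {ln!r}")
        rows.append([float(t) for t in toks[1:]])
    if len(rows) != 3:
        raise FormatError(f"SS table has {len(rows)} rows, expected 3")
    return SSSubstitutionTable(L=np.array(rows), meta=meta)


def default_ss_table() -> SSSubstitutionTable:
    """The bundled default table (synthetic-derived approximation)."""
    text = resources.files("alignhush.data").joinpath("ss_substitution.tsv").read_text()
    return read_ss_table(text)
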