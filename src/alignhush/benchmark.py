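"""Benchmark machinery: homology-label relation classes, sensitivity/error
curves, alignment-accuracy scores, transitive alignment composition, and a
grid-search parameter tuner.

Relations between two profiles follow the SCOP-style convention: profiles of
different families in the same superfamily are true relations; profiles in
different classes are false relations; same fold but different superfamily,
or same class but different fold, are ambiguous and ignored; pairs within
one family are not scored.  Sensitivity is TP/(TP+FN) and error rate
FP/(FP+TP), swept over a score threshold.
"""

from __future__ import annotations

import enum
import io
import itertools
from dataclasses import dataclass

import numpy as np

from .errors import (
    AlignHushError,
    BenchmarkError,
    ContractViolation,
    FormatError,
)
from .scoring import ScoringParams


@dataclass(frozen=True)
class HomologyLabel:
    """SCOP-style classification tuple for one profile."""

    family: str
    superfamily: str
    fold: str
    scop_class: str

    @classmethod
    def from_ccs(cls, code: str) -> "HomologyLabel":
        """Parse a dot-separated class.fold.superfamily.family identifier."""
        parts = code.split(".")
        if len(parts) != 4:
            raise FormatError(f"bad classification code {code!r}")
        cl, fo, sf, fa = parts
        return cls(
            family=f"{cl}.{fo}.{sf}.{fa}",
            superfamily=f"{cl}.{fo}.{sf}",
            fold=f"{cl}.{fo}",
            scop_class=cl,
        )


class RelationClass(enum.Enum):
    TRUE_POSITIVE_ELIGIBLE = "true"
    FALSE_POSITIVE_ELIGIBLE = "false"
    IGNORED = "ignored"


def classify_relation(a: HomologyLabel, b: HomologyLabel) -> RelationClass:
    """Classify a profile pair as true, false, or ignored.

    Same family pairs are not scored; same superfamily (different family) is
    a true relation; different class is a false relation; everything between
    (same fold/different superfamily, same class/different fold) is ignored.
    """
    if a is None or b is None:
        raise BenchmarkError("missing homology label")
    if a.family == b.family:
        return RelationClass.IGNORED
    if a.superfamily == b.superfamily:
        return RelationClass.TRUE_POSITIVE_ELIGIBLE
    if a.scop_class != b.scop_class:
        return RelationClass.FALSE_POSITIVE_ELIGIBLE
    return RelationClass.IGNORED


def read_labels_tsv(stream) -> dict[str, HomologyLabel]:
    """Two-column TSV: profile id, dot-separated classification code."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    out: dict[str, HomologyLabel] = {}
    for ln in stream:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split("\t") if "\t" in ln else ln.split()
        if len(parts) != 2:
            raise FormatError(f"bad label line: {ln!r}")
        out[parts[0]] = HomologyLabel.from_ccs(parts[1])
    return out


def count_true_relations(labels: dict[str, HomologyLabel]) -> int:
    """Number of unordered true (same-superfamily, different-family) pairs."""
    total = 0
    for a, b in itertools.combinations(labels.values(), 2):
        if classify_relation(a, b) is RelationClass.TRUE_POSITIVE_ELIGIBLE:
            total += 1
    return total


def dedupe_hits(scored_hits):
    """Keep the best-scoring hit per unordered profile pair, dropping
    self-hits; input is (query, target, score) triples."""
    best: dict[tuple[str, str], tuple[str, str, float]] = {}
    for q, t, s in scored_hits:
        if q == t:
            continue
        key = (min(q, t), max(q, t))
        if key not in best or s > best[key][2]:
            best[key] = (q, t, s)
    return sorted(best.values(), key=lambda h: (-h[2], h[0], h[1]))


def sensitivity_error_curve(
    classified_hits: list[tuple[float, RelationClass]],
    n_true_relations: int,
) -> list[tuple[float, float]]:
    """Sweep a score threshold from best to worst hit and emit
    (error_rate, sensitivity) at each distinct score.

    ``classified_hits`` are (score, relation) pairs; ignored relations are
    skipped without affecting the counts.  The positive count TP+FN comes
    from the label set, not from the hit list.
    """
    if n_true_relations <= 0:
        raise BenchmarkError("label set contains no true relations")
    ranked = sorted(classified_hits, key=lambda h: -h[0])
    points = []
    tp = fp = 0
    for idx, (score, rel) in enumerate(ranked):
        if rel is RelationClass.TRUE_POSITIVE_ELIGIBLE:
            tp += 1
        elif rel is RelationClass.FALSE_POSITIVE_ELIGIBLE:
            fp += 1
        else:
            continue
        last_of_score = idx + 1 == len(ranked) or ranked[idx + 1][0] != score
        if last_of_score and (tp + fp) > 0:
            points.append((fp / (fp + tp), tp / n_true_relations))
    return points


def sensitivity_at_error(
    curve: list[tuple[float, float]], max_error: float = 0.10
) -> float:
    """Best sensitivity among curve points with error rate <= max_error."""
    eligible = [sens for err, sens in curve if err <= max_error]
    return max(eligible) if eligible else 0.0


def roc_auc(pos_scores, neg_scores) -> float:
    """Rank-based AUC (probability a true pair outscores a false pair)."""
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if len(pos) == 0 or len(neg) == 0:
        raise BenchmarkError("need both true and false pair scores")
    greater = (pos[:, None] > neg[None, :]).sum()
    equal = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * equal) / (len(pos) * len(neg)))


# ---------------------------------------------------------------------------
# alignment accuracy


@dataclass
class ReferenceAlignment:
    """Gold-standard residue pairs between two sequences (1-based)."""

    pairs: list[tuple[int, int]]
    source: str = ""

    def __post_init__(self) -> None:
        for (a1, b1), (a2, b2) in zip(self.pairs, self.pairs[1:]):
            if a2 <= a1 or b2 <= b1:
                raise ContractViolation(
                    "reference alignment must be strictly increasing"
                )


def reference_from_aligned_pair(s1: str, s2: str, source: str = "") -> ReferenceAlignment:
    """Build a residue-pair list from two aligned (gapped) strings."""
    if len(s1) != len(s2):
        raise FormatError("aligned strings differ in length")
    pairs = []
    r1 = r2 = 0
    for c1, c2 in zip(s1, s2):
        g1, g2 = c1 in "-.", c2 in "-."
        if not g1:
            r1 += 1
        if not g2:
            r2 += 1
        if not g1 and not g2:
            pairs.append((r1, r2))
    return ReferenceAlignment(pairs=pairs, source=source)


def compose_alignments(
    seq_to_p: list[tuple[int, int]],
    pp_pairs: list[tuple[int, int]],
    q_to_seq: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Compose residue->profile-P, P->Q (MM pairs) and profile-Q->residue
    maps into a residue-residue alignment.

    A residue pair (r1, r2) is emitted iff r1 maps to P column i, (i, j) is
    an aligned MM pair, and Q column j maps to r2.  All three input maps
    must be strictly increasing in both coordinates.
    """
    for name, mapping in (
        ("seq_to_p", seq_to_p),
        ("p_to_q", pp_pairs),
        ("q_to_seq", q_to_seq),
    ):
        for (a1, b1), (a2, b2) in zip(mapping, mapping[1:]):
            if a2 <= a1 or b2 <= b1:
                raise ContractViolation(f"{name} mapping is not monotone")
    p_col_to_r1 = {i: r for r, i in seq_to_p}
    q_col_to_r2 = {j: r for j, r in q_to_seq}
    out = []
    for i, j in pp_pairs:
        r1 = p_col_to_r1.get(i)
        r2 = q_col_to_r2.get(j)
        if r1 is not None and r2 is not None:
            out.append((r1, r2))
    return out


def alignment_accuracy(
    test: list[tuple[int, int]], reference: ReferenceAlignment
) -> tuple[float, float]:
    """Developer and modeller accuracy of a test alignment.

    developer = correct pairs / test pairs inside the reference's residue
    span on both sequences (the region of overlap); modeller = correct
    pairs / reference length.  An empty test alignment scores (0, 0).
    """
    if not reference.pairs:
        raise BenchmarkError("empty reference alignment")
    ref_set = set(reference.pairs)
    lo1, lo2 = reference.pairs[0]
    hi1, hi2 = reference.pairs[-1]
    in_region = [
        p for p in test if lo1 <= p[0] <= hi1 and lo2 <= p[1] <= hi2
    ]
    correct = sum(1 for p in test if p in ref_set)
    developer = correct / len(in_region) if in_region else 0.0
    modeller = correct / len(reference.pairs)
    return developer, modeller


# ---------------------------------------------------------------------------
# all-vs-all benchmark pipeline


def benchmark_profiles(
    profiles: dict,
    labels: dict[str, HomologyLabel],
    params: ScoringParams | None = None,
    calibration_size: int = 0,
    seed: int = 0,
    censor_frac: float = 0.01,
) -> dict:
    """Search every profile against all others and summarise discrimination.

    With ``calibration_size`` > 0, each query is E-value calibrated against
    a shuffled random database drawn from the profile pool and hits are
    ranked by -E; otherwise raw Viterbi scores rank the hits.  Returns the
    deduplicated hit list, the classified (rank score, relation) pairs, the
    sensitivity/error curve and the true-vs-false ROC AUC.
    """
    from .align import align_all
    from .stats import calibrate, make_random_db

    params = params or ScoringParams()
    names = sorted(profiles)
    pool = [profiles[n] for n in names]
    raw_hits = []
    for qi, qname in enumerate(names):
        query = profiles[qname]
        fit = None
        if calibration_size > 0:
            random_db = make_random_db(
                pool, calibration_size, seed=seed + qi, shuffle=True
            )
            fit = calibrate(
                query, random_db, params,
                db_size=len(pool) - 1, censor_frac=censor_frac, seed=seed + qi,
            )
        targets = [profiles[t] for t in names if t != qname]
        for h in align_all(query, targets, params, fit=fit):
            key = -h.evalue if h.evalue is not None else h.score
            raw_hits.append((h.query, h.target, key))

    deduped = dedupe_hits(raw_hits)
    classified = [
        (s, classify_relation(labels[q], labels[t])) for q, t, s in deduped
    ]
    n_true = count_true_relations(labels)
    curve = sensitivity_error_curve(classified, n_true)
    pos = [s for s, rel in classified
           if rel is RelationClass.TRUE_POSITIVE_ELIGIBLE]
    neg = [s for s, rel in classified
           if rel is RelationClass.FALSE_POSITIVE_ELIGIBLE]
    return {
        "hits": deduped,
        "classified": classified,
        "n_true_relations": n_true,
        "curve": curve,
        "auc": roc_auc(pos, neg),
    }


# ---------------------------------------------------------------------------
# parameter tuning


def tune_parameters(
    score_fn,
    grid: list[ScoringParams],
    max_error: float = 0.10,
) -> tuple[ScoringParams, list[dict]]:
    """Grid search maximising sensitivity at a fixed error rate.

    ``score_fn(params)`` must return (classified_hits, n_true_relations) for
    one parameter point (typically by re-running a labelled benchmark).
    Ties break toward smaller windows, then smaller weights.  Returns the
    winning parameter set and the full grid table.
    """
    if not grid:
        raise AlignHushError("empty parameter grid")
    table = []
    seen: set[tuple] = set()
    for params in grid:
        key = (
            params.Wc, params.Wh, params.Ws, params.Wg,
            params.win_c, params.win_h, params.win_s, params.hydro_offset,
        )
        if key in seen:
            continue
        seen.add(key)
        hits, n_true = score_fn(params)
        sens = sensitivity_at_error(
            sensitivity_error_curve(hits, n_true), max_error
        )
        table.append({"params": params, "sensitivity": sens})
    best = max(
        table,
        key=lambda row: (
            row["sensitivity"],
            -(row["params"].win_c + row["params"].win_h + row["params"].win_s),
            -(row["params"].Wc + row["params"].Wh + row["params"].Ws),
        ),
    )
    return best["params"], table
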