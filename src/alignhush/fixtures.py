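"""Seeded synthetic test worlds.

Generates desk-scale stand-ins for a structurally classified profile
database: for each synthetic superfamily an ancestral sequence and 3-state
secondary-structure string are drawn, families diverge from the ancestor at
a between-family rate, and sequences within a family diverge further at a
within-family rate, with indels.  Substitutions are conditioned on the
site's secondary-structure state (each state has its own residue pool), so
hydrophobicity and secondary-structure signals survive sequence divergence
— the property the aligner exploits.  Each superfamily is placed in its own
class, so cross-superfamily pairs are unambiguous false relations while
same-superfamily pairs are true relations.

From a family MSA a profile is built by plain counting (emissions with
background pseudocounts, transitions from observed match/insert/delete
paths with Laplace smoothing) and can be serialised as a HMMER2 plan7 file
to exercise the full input path.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import yaml

from .annotation import (
    GAP_CHARS,
    MATCH,
    AnnotatedMSA,
    assign_match_columns,
    column_hydrophobicity,
    match_column_emissions,
    ss_column_frequencies,
)
from .benchmark import HomologyLabel
from .hmm_io import (
    AMINO_ACIDS,
    AlignHushProfile,
    Background,
    RawPlan7HMM,
    encode_alignhush,
    probs_to_scores,
    uniform_background,
    write_hmmer2,
)

# Residue pools preferred by each secondary-structure state.  Helix formers,
# beta-branched/aromatic sheet formers, and polar/turn residues for loops;
# the pools differ in mean hydropathy so both signals carry information.
SS_POOLS = {
    0: "AELMQKRH",  # helix
    1: "VIFYWTC",   # sheet
    2: "GPSNDQT",   # loop
}
SS_CHARS = "HEC"


@dataclass
class FixtureSpec:
    """Parameters of one synthetic world."""

    seed: int = 42
    n_superfamilies: int = 5
    families_per_superfamily: int = 2
    sequences_per_family: int = 8
    length_range: tuple[int, int] = (50, 70)
    within_family_rate: float = 0.15
    between_family_rate: float = 0.5
    indel_rate: float = 0.03
    ss_mean_runs: tuple[float, float, float] = (8.0, 5.0, 4.0)
    ss_conservation: float = 0.9
    pool_fidelity: float = 0.9  # chance a substitution stays in the SS pool

    def __post_init__(self) -> None:
        for r in ("within_family_rate", "between_family_rate", "indel_rate",
                  "ss_conservation", "pool_fidelity"):
            v = getattr(self, r)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{r} must be in [0, 1]")
        if min(self.length_range) < 10:
            raise ValueError("profile lengths must be >= 10")

    @classmethod
    def from_yaml(cls, stream) -> "FixtureSpec":
        data = yaml.safe_load(stream) or {}
        if "length_range" in data:
            data["length_range"] = tuple(data["length_range"])
        if "ss_mean_runs" in data:
            data["ss_mean_runs"] = tuple(data["ss_mean_runs"])
        return cls(**data)

    def describe(self) -> str:
        return (
            f"seed={self.seed} sf={self.n_superfamilies} "
            f"fam/sf={self.families_per_superfamily} "
            f"seq/fam={self.sequences_per_family} len={self.length_range} "
            f"within={self.within_family_rate} between={self.between_family_rate} "
            f"indel={self.indel_rate} ss_cons={self.ss_conservation}"
        )


@dataclass
class World:
    """Everything one synthetic benchmark needs."""

    spec: FixtureSpec
    msas: dict[str, AnnotatedMSA]  # family id -> annotated MSA
    labels: dict[str, HomologyLabel]


def _draw_ss_string(rng, length: int, mean_runs) -> str:
    """Alternating-state segments with geometric run lengths."""
    out = []
    state = int(rng.integers(3))
    while len(out) < length:
        run = int(rng.geometric(1.0 / mean_runs[state]))
        out.extend([state] * run)
        nxt = int(rng.integers(2))
        state = [s for s in range(3) if s != state][nxt]
    return "".join(SS_CHARS[s] for s in out[:length])


def _draw_residue(rng, ss_state: int, fidelity: float) -> str:
    if rng.random() < fidelity:
        pool = SS_POOLS[ss_state]
    else:
        pool = AMINO_ACIDS
    return pool[int(rng.integers(len(pool)))]


def _mutate(rng, seq: str, ss: str, rate: float, fidelity: float) -> str:
    out = []
    for ch, s in zip(seq, ss):
        if rng.random() < rate:
            out.append(_draw_residue(rng, SS_CHARS.index(s), fidelity))
        else:
            out.append(ch)
    return "".join(out)


def _flip_ss_segments(rng, ss: str, keep_prob: float) -> str:
    """Re-draw whole segments' states with probability 1 - keep_prob."""
    out = []
    i = 0
    while i < len(ss):
        j = i
        while j < len(ss) and ss[j] == ss[i]:
            j += 1
        state = SS_CHARS.index(ss[i])
        if rng.random() >= keep_prob:
            state = [s for s in range(3) if s != state][int(rng.integers(2))]
        out.extend(SS_CHARS[state] * (j - i))
        i = j
    return "".join(out)


def generate_world(spec: FixtureSpec) -> World:
    """Generate MSAs, per-sequence SS strings and homology labels."""
    rng = np.random.default_rng(spec.seed)
    msas: dict[str, AnnotatedMSA] = {}
    labels: dict[str, HomologyLabel] = {}
    for s in range(spec.n_superfamilies):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        anc_ss = _draw_ss_string(rng, length, spec.ss_mean_runs)
        anc_seq = "".join(
            _draw_residue(rng, SS_CHARS.index(c), spec.pool_fidelity)
            for c in anc_ss
        )
        for f in range(spec.families_per_superfamily):
            fam_ss = _flip_ss_segments(rng, anc_ss, spec.ss_conservation)
            fam_seq = _mutate(
                rng, anc_seq, fam_ss, spec.between_family_rate, spec.pool_fidelity
            )
            fam_id = f"sf{s + 1}_fam{f + 1}"
            msas[fam_id] = _family_msa(rng, fam_id, fam_seq, fam_ss, spec)
            labels[fam_id] = HomologyLabel.from_ccs(f"{s + 1}.1.1.{f + 1}")
    return World(spec=spec, msas=msas, labels=labels)


def _family_msa(
    rng, fam_id: str, master: str, master_ss: str, spec: FixtureSpec
) -> AnnotatedMSA:
    """Diverge sequences from the family master and lay out an alignment."""
    length = len(master)
    rows = []  # per sequence: (mutated residues, deleted flags, inserts)
    for _ in range(spec.sequences_per_family):
        seq = _mutate(rng, master, master_ss, spec.within_family_rate,
                      spec.pool_fidelity)
        deleted = [False] * length
        inserts: dict[int, str] = {}  # before-site position -> residues
        for p in range(length):
            if rng.random() < spec.indel_rate:
                if rng.random() < 0.5:
                    deleted[p] = True
                else:
                    n_ins = int(rng.geometric(0.5))
                    inserts[p] = "".join(
                        _draw_residue(rng, 2, spec.pool_fidelity)
                        for _ in range(n_ins)
                    )
        rows.append((seq, deleted, inserts))

    # merge into aligned strings: per site, first the insert columns (width =
    # longest insertion there), then the site column itself
    aligned = ["" for _ in rows]
    ss_per_seq = ["" for _ in rows]
    for p in range(length + 1):
        width = max((len(r[2].get(p, "")) for r in rows), default=0)
        if width:
            for k, (_, _, ins) in enumerate(rows):
                chunk = ins.get(p, "")
                aligned[k] += chunk + "-" * (width - len(chunk))
                ss_per_seq[k] += "C" * len(chunk)
        if p < length:
            for k, (seq, deleted, _) in enumerate(rows):
                if deleted[p]:
                    aligned[k] += "-"
                else:
                    aligned[k] += seq[p]
                    ss_per_seq[k] += master_ss[p]

    ids = [f"{fam_id}_s{k + 1}" for k in range(len(rows))]
    return AnnotatedMSA(
        sequences=list(zip(ids, aligned)),
        ss_strings=dict(zip(ids, ss_per_seq)),
    )


# ---------------------------------------------------------------------------
# profile construction from an MSA


def build_profile_from_msa(
    msa: AnnotatedMSA,
    name: str = "",
    pseudocount: float = 1.0,
    background: Background | None = None,
    trans_pseudocount: float = 0.5,
    gap_fraction_threshold: float = 0.5,
) -> AlignHushProfile:
    """Count-based profile construction.

    Match columns are assigned by gap fraction; emissions are
    (counts + pseudocount * b_a)/(N + pseudocount); transitions come from
    each sequence's observed match/insert/delete path through the columns,
    Laplace-smoothed with ``trans_pseudocount``.
    """
    background = background or uniform_background()
    if msa.column_assignment is None:
        assign_match_columns(msa, gap_fraction_threshold)
    emissions = match_column_emissions(msa, background.b, pseudocount)
    n = len(emissions)
    hydro = np.array([column_hydrophobicity(p) for p in emissions])
    ss = ss_column_frequencies(msa) if msa.ss_strings else None

    match_cols = [
        c for c, lab in enumerate(msa.column_assignment) if lab == MATCH
    ]
    # transition counts per node: mm, mi, md, im, ii, dm, dd
    counts = np.zeros((n, 7))
    for _, s in msa.sequences:
        node_state = ["M" if s[c] not in GAP_CHARS else "D" for c in match_cols]
        for k in range(n):
            nxt_col = match_cols[k + 1] if k + 1 < n else len(s)
            n_ins = sum(
                1
                for c in range(match_cols[k] + 1, nxt_col)
                if msa.column_assignment[c] == "insert" and s[c] not in GAP_CHARS
            )
            cur = node_state[k]
            nxt = node_state[k + 1] if k + 1 < n else "M"  # end counts as M
            if cur == "M":
                if n_ins > 0:
                    counts[k, 1] += 1  # M->I
                    counts[k, 4] += n_ins - 1  # I->I
                    counts[k, 3] += 1  # I->M (plan7 has no I->D)
                elif nxt == "M":
                    counts[k, 0] += 1
                else:
                    counts[k, 2] += 1
            else:  # delete state; plan7 has no D->I, inserts are ignored here
                if nxt == "M":
                    counts[k, 5] += 1
                else:
                    counts[k, 6] += 1
    trans = np.zeros((n, 7))
    for k in range(n):
        for group in ((0, 1, 2), (3, 4), (5, 6)):
            g = counts[k, list(group)] + trans_pseudocount
            trans[k, list(group)] = g / g.sum()

    return encode_alignhush(
        emissions,
        trans,
        background,
        hydro=hydro,
        ss=ss,
        name=name or "profile",
        provenance="built from synthetic MSA",
    )


def profile_to_plan7(
    profile: AlignHushProfile, insert_emissions: np.ndarray | None = None
) -> RawPlan7HMM:
    """Quantise a profile back to integer plan7 scores (for serialisation)."""
    b = profile.background.b
    n = len(profile)
    emissions = np.stack(
        [st.emission_probs(profile.background) for st in profile.states]
    )
    if insert_emissions is None:
        insert_emissions = np.tile(b, (n, 1))
    return RawPlan7HMM(
        name=profile.name,
        length=n,
        match_scores=probs_to_scores(emissions, np.tile(b, (n, 1))),
        insert_scores=probs_to_scores(insert_emissions, np.tile(b, (n, 1))),
        trans_scores=probs_to_scores(profile.trans_matrix, np.ones((n, 7))),
        null_scores=probs_to_scores(b, np.full(len(b), 1.0 / 20.0)),
        specials=[],
    )


def world_profiles(
    world: World, pseudocount: float = 1.0
) -> dict[str, AlignHushProfile]:
    """Build one profile per family of a world."""
    return {
        fam_id: build_profile_from_msa(msa, name=fam_id, pseudocount=pseudocount)
        for fam_id, msa in world.msas.items()
    }


def ss_conserving_pairs(
    spec: FixtureSpec, n_pairs: int = 200
) -> list[tuple[str, str]]:
    """Aligned 3-state string pairs emulating structural alignments of
    related families; used to estimate the default SS substitution table."""
    rng = np.random.default_rng(spec.seed)
    pairs = []
    for _ in range(n_pairs):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        a = _draw_ss_string(rng, length, spec.ss_mean_runs)
        b = _flip_ss_segments(rng, a, spec.ss_conservation)
        pairs.append((a, b))
    return pairs


def write_world(world: World, out_dir: str, pseudocount: float = 1.0) -> None:
    """Write aligned FASTA, SS TSV, plan7 HMMs, profiles and labels TSV."""
    from .hmm_io import save_profile

    os.makedirs(out_dir, exist_ok=True)
    header = f"# fixture spec: {world.spec.describe()}\n"
    with open(os.path.join(out_dir, "labels.tsv"), "w") as fh:
        fh.write(header)
        for fam_id, lab in world.labels.items():
            fh.write(f"{fam_id}\t{lab.family}\n")
    for fam_id, msa in world.msas.items():
        with open(os.path.join(out_dir, f"{fam_id}.afa"), "w") as fh:
            for sid, s in msa.sequences:
                fh.write(f">{sid}\n{s}\n")
        with open(os.path.join(out_dir, f"{fam_id}.ss.tsv"), "w") as fh:
            fh.write(header)
            for sid, ss in msa.ss_strings.items():
                fh.write(f"{sid}\t{ss}\n")
        profile = build_profile_from_msa(msa, name=fam_id, pseudocount=pseudocount)
        save_profile(profile, os.path.join(out_dir, f"{fam_id}.ah"))
        with open(os.path.join(out_dir, f"{fam_id}.hmm"), "w") as fh:
            write_hmmer2(profile_to_plan7(profile), fh)
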