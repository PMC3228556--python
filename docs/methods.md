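# Methods

## Profile representation

A profile is an ordered list of match states derived from one family MSA
(or parsed from a HMMER2 plan7 file).  Each state stores:

- **Emission odds** `e(a) = p(a)/√b_a`.  Emissions are renormalised to sum
  to 1 after insert-state content is discarded — only the *probability* of
  an insert opening matters to profile-profile alignment, not what the
  inserts emit — and divided by the square root of the background so that
  the co-emission score of two columns is `log2(e_x · e_y)`, a dot product
  of stored vectors.  The renormalisation after stripping inserts is an
  assumption of this implementation.
- **Hydrophobicity** `H = Σ_a p(a)·kd(a)` in Kyte–Doolittle units, the
  emission-weighted mean hydropathy of the column.  Hydrophobicity acts as
  a sequence-computable proxy for core packing: two homologous columns
  buried in the core stay hydrophobic even when residue identity is lost.
- **Secondary-structure frequencies** `(f_H, f_E, f_C)`, counted over the
  per-sequence 3-state predictions (PSIPRED-style; only the argmax state is
  consumed, confidences are ignored) of the non-gap residues in the column.
  Sequences without predictions contribute to emissions but not to SS
  counts.  Profiles without predictions carry an "unannotated" flag and the
  SS term is skipped for them.
- **Seven plan7 transition probabilities** (M→M/I/D, I→M/I, D→M/D),
  giving position-specific gap penalties.

plan7 integer scores convert as `p = null·2^(score/1000)` (the HMMER2
integer scale), with the `*` sentinel mapping to probability zero.  The
background comes from the file's null-emission line relative to 1/20,
renormalised; a built-in uniform background is used when absent.
Transition probabilities above 1 after conversion (integer rounding) are
clamped and each outgoing group renormalised so log-transition terms stay
non-positive.  Begin/end special transitions are parsed but unused: local
start/stop is handled by the max-with-zero rule, not by begin/end states.
Amino acids are ordered alphabetically by one-letter code everywhere.

## Column match score

```
M(i,j) = Wc·Σ_w cons + Wh·Σ_w hyd + Ws·Σ_w ss
```

- `cons(x,y) = log2 Σ_a P(xa)Q(ya)/b_a`; equals 0 for two
  background-shaped columns and `log2(1/b_a)` for a shared point mass.
- `hyd(x,y) = c0 − |Hx − Hy|`.  The functional form is this package's
  choice: symmetric, monotone-decreasing in hydropathy mismatch, with a
  controllable zero crossing.  `c0 = 1.5` KD units makes the mean score
  over randomly paired synthetic columns roughly zero, so the term rewards
  genuine hydropathy agreement rather than inflating every alignment.  The
  form is isolated behind one function so alternatives (e.g. a product
  `Hx·Hy`) can be swapped.
- `ss(x,y) = f(x)ᵀ L f(y)` with `L` a symmetric 3×3 log2-odds table over
  helix/sheet/loop.  The bundled default table is estimated from the
  package's own SS-conserving synthetic alignment generator (500 pairs,
  pseudocount 1) and is labelled a synthetic approximation in its header;
  users with curated structural alignments should estimate their own via
  `estimate_ss_table` (counts symmetrised, pseudocount 1 per cell by
  default, zero-count cells floored at −50).

Each term is summed over a diagonal window (default width 5 for all three
terms; only the conservation window has an empirically established width,
the other two defaults mirror it and are exposed in config), truncated at
profile ends — truncation is the only edge policy that never invents
columns.  The window sum is raw, not averaged, and uniform within the
window.  Weights default to `Wc=1.0, Wh=0.3, Ws=0.3`: conservation is the
primary signal, the structure-flavoured terms are auxiliary.  No weight
values are canonical; `tune_parameters` grid-searches them on any labelled
benchmark, maximising sensitivity at a fixed error rate (default 10%) with
ties broken toward smaller windows then smaller weights.

Logs are base 2 throughout and a floor of −50 bits replaces −∞ (zero dot
products, zero transition probabilities), keeping the DP finite while
still making "impossible" events decisively unfavourable.

## Alignment

Five pair-HMM states (MM, MI, IM, DG, GD) suffice for profile-profile
alignment.  The Viterbi recurrence for MM takes a max with 0 (local start)
and adds `M(i,j)`; transition terms are `Wg·log2` of the product of the two
models' transition probabilities out of the previous nodes, with `Wg`
(default 1.0) applied to *all* transition log terms, keeping windowed
column scores from swamping gap penalties.  Local alignments begin and end
in MM: boundary cells of the gap matrices are −∞, so a path cannot open in
a gap state, and traceback starts at the global MM maximum (ties broken
toward the smallest (i, j)) and stops at a cell whose best predecessor is
the local start.  Max ties break in the fixed order local-start, MM, MI,
IM, DG, GD, making tracebacks deterministic.  Only the single best
alignment is reported.

The implementation computes the dense `M` matrix vectorised (diagonal
shift-and-add for windows) and fills the five DP matrices cell by cell;
`rescore_alignment` re-walks any path term by term and is used as a
self-consistency check.  An independent exhaustive path-enumeration oracle
(tests) explores every legal local path recursively with no DP tables and
must agree exactly for profiles up to 6×6.

## E-value statistics

Viterbi scores of a query against unrelated profiles are modelled as
Gumbel; calibration is per query (avoiding length/composition bias from
database-wide parameters).  The fit is maximum likelihood with
moment-based initialisation (Nelder-Mead on (log λ, μ)); by default the
top 1% of calibration scores are type-2 censored — they enter the
likelihood only through the survival term — guarding against true
homologs contaminating a randomly selected calibration database.  With
censoring disabled the fit agrees with scipy's `gumbel_r.fit` to ~0.1%.
Calibration requires ≥ 50 random profiles (default database size 200);
the random database is drawn seeded from a profile pool, optionally
column-shuffling each sampled profile (permuting match-state order) to
destroy residual homology, which also permits oversampling small pools.
`E = N·(1 − exp(−exp(−λ(S−μ))))` with `N` the searched database size (not
the calibration size), clamped to `[0, N]`.

## Benchmarking

Relations between labelled profiles: same superfamily but different family
→ true; different class → false; same fold/different superfamily and same
class/different fold → ignored (ambiguous homology); same family → not
scored, since the benchmark counts relationships *between* families.
Sensitivity/error curves sweep a threshold over deduplicated hits (best
score per unordered pair), skipping ignored relations; the positive total
(TP+FN) counts unordered true pairs in the label set.

Alignment accuracy composes sequence→profile, profile→profile and
profile→sequence maps into a residue-residue alignment and compares it to
a reference: `developer = correct / test pairs inside the reference's
residue span on both sequences` (the "region of overlap" reading of the
alignment region), `modeller = correct / reference length`.  An empty test
alignment reports (0, 0) by convention.

## Synthetic worlds

The generator emulates a structurally classified profile database at desk
scale.  Per superfamily: an ancestral 3-state SS string (geometric segment
lengths, mean runs 8/5/4 for H/E/C) and an ancestral sequence drawn from
SS-state-specific residue pools (helix formers, sheet formers, polar loop
residues; pools differ in mean hydropathy).  Families diverge from the
ancestor at a between-family substitution rate (default 0.5) with
replacements drawn from the site's SS pool (fidelity 0.9), and whole SS
segments re-drawn with probability 1 − SS-conservation (default 0.9);
sequences within a family diverge further (rate 0.15) with indels (rate
0.03).  Each superfamily sits in its own class, so cross-superfamily pairs
are unambiguous false relations.  Defaults (5 superfamilies × 2 families ×
8 sequences, lengths 50–70) were chosen as the smallest world on which
related and unrelated pairs separate clearly while the full pipeline runs
in seconds; profile construction is plain counting with background
pseudocounts (no Dirichlet mixture priors), and the same models serialise
to plan7 text to exercise the parser end to end.

What the generator does **not** emulate: phylogenetic tree structure and
rate heterogeneity, realistic amino-acid substitution matrices, predicted
SS errors correlated along the sequence, domain architecture, and the
extreme family-size skew of real databases.  Passing tests therefore
demonstrate internal correctness and the expected *direction* of effects
(e.g. neighbour windows and SS terms help discrimination on
structure-conserving, sequence-divergent families), not sensitivity levels
transferable to real SCOP-scale benchmarks, which additionally require
curated profile databases and reference alignments.

## Known limitations

- Only Viterbi (best-path) alignment; no forward-score statistics or
  posterior-decoded alignments.
- HMMER2 plan7 ASCII is the only HMM input dialect (no HMMER3/SAM/binary).
- The default SS substitution table is synthetic-derived; absolute SS-term
  magnitudes should not be over-interpreted without a user-supplied table.
- The hydrophobic-score functional form and the hydro/SS window widths and
  weights are package defaults, not empirically established constants;
  re-tune on labelled data for production use.
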