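# alignhush

Profile-HMM versus profile-HMM local alignment for remote homology
detection, augmented with hydrophobicity and predicted secondary-structure
information.

In the "midnight zone" of sequence similarity, residue conservation alone
is often too weak to recognise that two protein families are related, even
though their structures still superpose.  This package aligns two profile
HMMs (each summarising a multiple sequence alignment of one family) with a
column score that adds two structure-flavoured signals to the usual
conservation term — the column's Kyte–Doolittle hydrophobicity and its
3-state predicted secondary-structure composition — and sums every term
over a diagonal window of neighbouring columns, exploiting the fact that
homologous conservation runs in stretches.  It is aimed at people building
remote-homology search and annotation pipelines over family profile
collections.

## Method

Profiles `P(1..n)` and `Q(1..m)` hold, per match state, emission
probabilities re-encoded as odds `e(a) = p(a)/√b_a` (so co-emission scores
become dot products), a hydrophobicity `H`, secondary-structure frequencies
`f = (f_H, f_E, f_C)`, and the seven plan7 transition probabilities.  The
column match score is

```
M(i,j) = Wc·Σ_w cons(i+k, j+k) + Wh·Σ_w hyd(i+k, j+k) + Ws·Σ_w ss(i+k, j+k)

cons(x,y) = log2 Σ_a P(xa)·Q(ya)/b_a        (log-sum-of-odds)
hyd(x,y)  = c0 − |Hx − Hy|                  (c0 = 1.5 KD units)
ss(x,y)   = Σ_s Σ_s' f(x)_s · f(y)_s' · L(s,s')
```

with each `Σ_w` a sum over a 5-column diagonal window truncated at profile
ends, and `L` a symmetric 3×3 helix/sheet/loop log-odds substitution table.
The optimal local alignment is found by a five-state pair-HMM Viterbi
dynamic programme over states MM, MI, IM, DG, GD, in which gap penalties
are the models' own log transition probabilities weighted by `Wg`, and
traceback starts at the maximum of the MM matrix (that maximum is the
alignment score, in bits).  Statistical significance is per-query: scores
against a random profile database are fitted with a Gumbel distribution by
(optionally top-censored) maximum likelihood, giving
`E = N·(1 − exp(−exp(−λ(S−μ))))`.

Benchmark utilities score search output against SCOP-style labels
(sensitivity `TP/(TP+FN)` at error rate `FP/(FP+TP)`, with same-fold /
different-superfamily and same-class / different-fold pairs ignored), and
score alignment accuracy against gold-standard reference alignments
(developer and modeller scores) via transitive composition of
sequence–profile and profile–profile alignments.  A seeded synthetic world
generator produces labelled families of diverged MSAs with matching
secondary-structure strings, so everything is testable without external
databases.

## Worked example

```python
from alignhush import (FixtureSpec, ScoringParams, align_all, calibrate,
                       generate_world, make_random_db, viterbi_align,
                       world_profiles)

world = generate_world(FixtureSpec(seed=42))   # 5 superfamilies x 2 families
profiles = world_profiles(world)

aln = viterbi_align(profiles["sf1_fam1"], profiles["sf1_fam2"], ScoringParams())
print(aln.score, len(aln.pairs), aln.start, aln.end)
# 59.64 bits over 7 aligned column pairs, columns 45-51 in both profiles

pool = list(profiles.values())
fit = calibrate(profiles["sf1_fam1"],
                make_random_db(pool, 60, seed=0, shuffle=True), db_size=9)
print(fit.lam, fit.mu)          # lambda=0.131  mu=18.72
hits = align_all(profiles["sf1_fam1"],
                 [p for n, p in profiles.items() if n != "sf1_fam1"], fit=fit)
for h in hits[:3]:
    print(h.target, round(h.score, 2), round(h.evalue, 3))
# sf1_fam2  59.64  0.042   <- the true same-superfamily relative, ranked first
# sf5_fam1  48.56  0.177
# sf2_fam1  38.27  0.664
```

The only same-superfamily relative of `sf1_fam1` ranks first with the
smallest E-value; all cross-class decoys trail it.

The same functionality is exposed on the command line:

```sh
alignhush fixtures --out world/ --seed 42
alignhush align world/sf1_fam1.ah world/sf1_fam2.ah
alignhush calibrate world/sf1_fam1.ah world/ --size 60 --shuffle --out q.evd
alignhush search world/sf1_fam1.ah world/ --evd q.evd
```

## Layout

- `src/alignhush/hmm_io.py` — HMMER2 plan7 parsing, score→probability
  conversion, the augmented-profile interchange format
- `src/alignhush/annotation.py` — match-column assignment, hydrophobicity
  and SS column frequencies from MSAs and PSIPRED-style predictions
- `src/alignhush/ss_subst.py` — the 3×3 SS substitution table (estimator +
  bundled default)
- `src/alignhush/scoring.py` — windowed, weighted column-pair match score
- `src/alignhush/align.py` — five-state pair-HMM Viterbi alignment,
  traceback, rescoring, database search
- `src/alignhush/stats.py` — per-query Gumbel E-value calibration
- `src/alignhush/benchmark.py` — relation classes, sensitivity/error
  curves, alignment accuracy, parameter tuning
- `src/alignhush/fixtures.py` — synthetic world generator
- `docs/methods.md` — modelling assumptions, parameter defaults, numerical
  choices and limitations
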