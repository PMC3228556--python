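"""Hand-written miniature plan7 text fixtures."""


def minimal_plan7(length=2, match_score=0, sentinel_at=None):
    """A tiny HMMER2 plan7 file with uniform scores.

    ``sentinel_at`` marks one (node, amino) match entry as impossible ("*").
    """
    lines = [
        "HMMER2.0  [test]",
        "NAME  toy",
        f"LENG  {length}",
        "ALPH  Amino",
        "NULE  " + " ".join(["0"] * 20),
        "HMM        " + "      ".join("ACDEFGHIKLMNPQRSTVWY"),
        "         m->m   m->i   m->d   i->m   i->i   d->m   d->d   b->m   m->e",
    ]
    for k in range(length):
        match = [str(match_score)] * 20
        if sentinel_at is not None and sentinel_at[0] == k:
            match[sentinel_at[1]] = "*"
        lines.append(f"{k + 1:6d} " + " ".join(match))
        lines.append("     - " + " ".join(["0"] * 20))
        # near-deterministic match-match, mild insert/delete continuation
        lines.append("     -   -50  -5000  -5000  -1000  -1000  -1000  -1000  * *")
    lines.append("//")
    return "\n".join(lines) + "\n"
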