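"""Independent brute-force oracles used by several test modules."""

COMP = {"A": "U", "U": "A", "C": "G", "G": "C"}

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")


def brute_patterns(mirna):
    """Independent pattern construction by explicit base pairing."""
    m = mirna.upper().replace("T", "U")
    rc = lambda s: "".join(COMP[c] for c in reversed(s))
    return {"8mer": rc(m[1:8]) + "A", "7mer-m8": rc(m[1:8]),
            "7mer-A1": rc(m[1:7]) + "A"}


def brute_scan(utr, mirna):
    """Naive scanner: test every window against every pattern with the
    same precedence and 8mer-window suppression."""
    utr = utr.upper().replace("T", "U")
    pats = brute_patterns(mirna)
    raw = []
    for p in range(len(utr)):
        for stype in SITE_TYPES:
            w = utr[p:p + len(pats[stype])]
            if w == pats[stype]:
                raw.append((p, stype))
                break
    eights = [p for p, t in raw if t == "8mer"]
    return [(p, t) for p, t in raw
            if t == "8mer" or not any(q <= p and p + 7 <= q + 8
                                      for q in eights)]
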