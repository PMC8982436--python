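"""Canonical miRNA seed-site scanner for 3'UTR sequences.

Only the three canonical site types are considered. Numbering the miRNA
5'->3' from nt 1, the target-site patterns on the UTR (read 5'->3') are:

    8mer     reverse complement of miRNA nt 2-8, followed by A
    7mer-m8  reverse complement of miRNA nt 2-8
    7mer-A1  reverse complement of miRNA nt 2-7, followed by A

The A opposite miRNA nt 1 is a sequence requirement on the target, not a
pairing requirement. Positions are 0-based indices of the site's first
nucleotide on the UTR (1-based available via flag). Overlapping calls are
resolved strongest-first: 8mer > 7mer-m8 > 7mer-A1, and a 7mer whose window
lies inside a reported 8mer window is suppressed. N never matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
ALIASES = {"8mer": "8mer", "7mer-m8": "7_m8", "7mer-A1": "7_A1"}
_RNA = set("ACGU")
_UTR_OK = set("ACGUN")


@dataclass(frozen=True)
class SiteHit:
    utr_id: str
    mirna_id: str
    position: int          # 0-based index of the site's first nucleotide
    site_type: str         # one of SITE_TYPES
    site_sequence: str

    def type_alias(self) -> str:
        return ALIASES[self.site_type]


def _canon_rna(seq: str, allow_n: bool = False, what: str = "sequence") -> str:
    s = str(seq).upper().replace("T", "U")
    ok = _UTR_OK if allow_n else _RNA
    bad = set(s) - ok
    if bad:
        raise ValueError(f"invalid characters in {what}: {sorted(bad)}")
    return s


def _revcomp_rna(seq: str) -> str:
    dna = seq.replace("U", "T")
    return str(Seq(dna).reverse_complement()).replace("T", "U")


def seed_match_patterns(mirna_seq: str, alphabet: str = "rna") -> dict[str, str]:
    """Target-site patterns for one miRNA; only nt 1-8 of the miRNA matter."""
    s = _canon_rna(mirna_seq, what="miRNA")
    if len(s) < 8:
        raise ValueError("miRNA must be at least 8 nt")
    pats = {
        "8mer": _revcomp_rna(s[1:8]) + "A",
        "7mer-m8": _revcomp_rna(s[1:8]),
        "7mer-A1": _revcomp_rna(s[1:7]) + "A",
    }
    if alphabet == "dna":
        pats = {k: v.replace("U", "T") for k, v in pats.items()}
    elif alphabet != "rna":
        raise ValueError("alphabet must be 'rna' or 'dna'")
    return pats


def scan_utr(utr_seq: str, mirna_seq: str, utr_id: str = "",
             mirna_id: str = "", one_based: bool = False) -> list[SiteHit]:
    """All canonical sites of one miRNA on one UTR, sorted by position.

    At each start position at most one site is reported (8mer > 7mer-m8 >
    7mer-A1), and 7mers contained in a reported 8mer window are suppressed.
    A UTR shorter than 7 nt yields no hits.
    """
    utr = _canon_rna(utr_seq, allow_n=True, what="UTR")
    if len(utr) < 7:
        return []
    pats = seed_match_patterns(mirna_seq)
    eightmer_windows: list[int] = []
    hits: list[SiteHit] = []
    offset = 1 if one_based else 0
    for p in range(len(utr)):
        for stype in SITE_TYPES:
            pat = pats[stype]
            if utr[p:p + len(pat)] == pat:
                if stype == "8mer":
                    eightmer_windows.append(p)
                hits.append(SiteHit(utr_id, mirna_id, p + offset, stype, pat))
                break  # precedence: one hit per start position
    kept = []
    for h in hits:
        p = h.position - offset
        if h.site_type != "8mer" and any(
                q <= p and p + 7 <= q + 8 for q in eightmer_windows):
            continue
        kept.append(h)
    return kept


def hits_to_frame(hits: list[SiteHit], alias: bool = False) -> pd.DataFrame:
    rows = [
        (h.utr_id, h.mirna_id, h.position,
         h.type_alias() if alias else h.site_type, h.site_sequence)
        for h in hits
    ]
    return pd.DataFrame(
        rows, columns=["utr_id", "mirna_id", "position", "site_type",
                       "site_sequence"])


def _read_fasta(path: str | Path, what: str) -> dict[str, str]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty FASTA: {path}")
    seqs: dict[str, str] = {}
    for rec in records:
        if rec.id in seqs:
            raise ValueError(f"duplicate id {rec.id!r} in {what} FASTA")
        seqs[rec.id] = str(rec.seq)
    return seqs


def batch_scan(utr_fasta: str | Path, mirna_fasta: str | Path,
               one_based: bool = False, alias: bool = False) -> pd.DataFrame:
    """Scan every miRNA against every UTR; returns the hit table."""
    utrs = _read_fasta(utr_fasta, "UTR")
    mirnas = _read_fasta(mirna_fasta, "miRNA")
    frames = []
    for uid, useq in utrs.items():
        for mid, mseq in mirnas.items():
            hits = scan_utr(useq, mseq, utr_id=uid, mirna_id=mid,
                            one_based=one_based)
            if hits:
                frames.append(hits_to_frame(hits, alias=alias))
    if not frames:
        return hits_to_frame([], alias=alias)
    return pd.concat(frames, ignore_index=True)
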