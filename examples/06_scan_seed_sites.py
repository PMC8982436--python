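"""Scan a 3'UTR for canonical miRNA seed sites (8mer, 7mer-m8, 7mer-A1).

The site patterns derive from miRNA nucleotides 1-8: the UTR must carry the
reverse complement of the seed, optionally with an A opposite nt 1.
"""

from embryoquant.sites import hits_to_frame, scan_utr, seed_match_patterns

mirna = "UCUUUGGUUAUCUAGCUGUAUGA"  # 22-nt miRNA, 5'->3'
pats = seed_match_patterns(mirna)
print("target-site patterns:", pats)

utr = ("ACGGAU" + pats["8mer"] + "CCGUAAGGUCAUCG" + pats["7mer-A1"]
       + "GGAUUCGNNNACGU")
hits = scan_utr(utr, mirna, utr_id="toy_utr", mirna_id="toy_mir")
print(hits_to_frame(hits, alias=True).to_string(index=False))
# Positions are 0-based indices of the site's first UTR nucleotide; the
# 7mers embedded inside the reported 8mer window are suppressed, so each
# physical site appears exactly once at its strongest type.
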