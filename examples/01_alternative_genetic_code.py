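"""Translate and classify substitutions under genetic code 25 (UGA -> Gly).

Gracilibacteria read the canonical UGA stop codon as glycine. The same
nucleotide change can therefore be a stop gain under the bacterial code 11
but an ordinary amino-acid change under code 25 — which is why every
downstream synonymous/nonsynonymous count depends on the right table.
"""

from gracilib import classify_substitution, get_code, translate_cds

code25 = get_code(25)
code11 = get_code(11)

cds = "CCAACTGAT"  # one 9-bp repeat unit
print(f"{cds} under code 25 -> {translate_cds(cds, code25)}  (the repeat tripeptide)")
print(f"TGA under code 25 -> {translate_cds('TGA', code25)}, under code 11 -> "
      f"{translate_cds('TGA', code11)!r}")

for table, code in ((25, code25), (11, code11)):
    eff = classify_substitution("TGG", 2, "A", code)
    print(f"TGG -> TGA under code {table}: {eff.category} ({eff.ref_aa} -> {eff.alt_aa})")

# Output meaning: the identical Trp-codon mutation is nonsynonymous (W->G)
# for this organism but would be miscounted as a nonsense mutation under the
# standard bacterial table.
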