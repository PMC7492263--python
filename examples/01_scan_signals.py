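"""Scan classic localization signals in a few well-known peptide contexts.

Builds three small proteins — one carrying the SV40-style monopartite NLS,
one a nucleoplasmin-style bipartite NLS, one a leucine-rich export signal —
and prints each one's signal profile.
"""

from nucloc import profile_sequence

PROTEINS = {
    "sv40_nls_like": "MEA" + "PKKKRKV" + "GSTAAADEQ" * 4,
    "bipartite_nls_like": "MAS" + "KRPAATKKAGQAKKKK" + "LDEQSTNAG" * 4,
    "nes_like": "MDA" + "LAALAALAL" + "GSDEQTNAG" * 4,
}

for name, seq in PROTEINS.items():
    p = profile_sequence(name, seq)
    print(f"{name}  (length {len(seq)})")
    print(f"  PAT4/PAT7/bipartite matches: {p.n_pat4}/{p.n_pat7}/{p.n_bipartite}")
    print(f"  basic residues: {p.basic_percent:.2f}%")
    print(f"  NLS score {p.nls_score:+.0f} -> NLS {'present' if p.nls_positive else 'absent'}")
    print(f"  NES score {p.nes_score:.0f} -> NES {'present' if p.nes_positive else 'absent'}")
    print(f"  classification: {p.loc_class.value}")
    print()

print("A positive NLS score alone marks a nuclear-resident protein; NLS plus a")
print("windowed NES (>=3 contributing residues within 15 positions) marks a")
print("nucleocytoplasmic shuttler; NES alone, an export-signal-only protein.")
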