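"""Splice-variant localization concordance.

Classifies multi-variant genes by whether the designated tool predicts all,
some, or none of their protein isoforms nuclear.
"""

from nucloc import NuclearCall
from nucloc.splicing import build_groups, summarize_splicing

# WoLF-PSORT calls for the variants of four genes
calls = {
    "g1.1": [NuclearCall("g1.1", "wolfpsort", True)],
    "g1.2": [NuclearCall("g1.2", "wolfpsort", True)],
    "g2.1": [NuclearCall("g2.1", "wolfpsort", True)],
    "g2.2": [NuclearCall("g2.2", "wolfpsort", False)],   # splicing changes localization
    "g2.3": [NuclearCall("g2.3", "wolfpsort", False)],
    "g3.1": [NuclearCall("g3.1", "wolfpsort", False)],
    "g3.2": [NuclearCall("g3.2", "wolfpsort", False)],
    "g4.1": [NuclearCall("g4.1", "wolfpsort", False)],
    "g4.2": [NuclearCall("g4.2", "wolfpsort", True)],
}
gene_variants = {
    "g1": ["g1.1", "g1.2"],
    "g2": ["g2.1", "g2.2", "g2.3"],
    "g3": ["g3.1", "g3.2"],
    "g4": ["g4.1", "g4.2"],
}

groups = build_groups(gene_variants, calls, tool="wolfpsort")
for g in groups:
    flags = "".join("N" if f else "-" for f in g.variant_nuclear)
    print(f"{g.gene_id}: variants [{flags}] -> {g.concordance}")

print("\nsummary:", summarize_splicing(groups))
print("'mixed' genes are those where alternative splicing switches the")
print("predicted compartment between isoforms; any_nuclear = all + mixed.")
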