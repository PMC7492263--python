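"""Splice-variant localization concordance.

A gene with two or more annotated protein-coding splice variants is
classified by whether its variants' predicted nuclear calls agree:
all nuclear, none nuclear, or mixed (splicing changes the localization).
Variant calls come from a single designated tool (default WoLF-PSORT).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .records import NuclearCall


@dataclass
class SpliceGroup:
    gene_id: str
    variant_ids: list[str]
    variant_nuclear: list[bool]
    concordance: str  # all_nuclear | mixed | none_nuclear


def classify_gene(variant_nuclear: Sequence[bool]) -> str:
    if len(variant_nuclear) < 2:
        raise ValueError("a splice group needs at least two variants")
    if all(variant_nuclear):
        return "all_nuclear"
    if not any(variant_nuclear):
        return "none_nuclear"
    return "mixed"


def build_groups(
    gene_variants: Mapping[str, Sequence[str]],
    calls_by_protein: Mapping[str, Iterable[NuclearCall]],
    tool: str = "wolfpsort",
) -> list[SpliceGroup]:
    """Splice groups from a gene->variants map and the designated tool's calls.

    Genes with fewer than two variants carrying a call from the tool are
    skipped — they are not splice groups under that tool's view.
    """
    groups = []
    for gene_id in sorted(gene_variants):
        variants, flags = [], []
        for vid in gene_variants[gene_id]:
            call = next((c for c in calls_by_protein.get(vid, ()) if c.tool == tool), None)
            if call is not None:
                variants.append(vid)
                flags.append(call.nuclear)
        if len(variants) >= 2:
            groups.append(SpliceGroup(gene_id, variants, flags, classify_gene(flags)))
    return groups


def summarize_splicing(groups: Iterable[SpliceGroup]) -> dict[str, int]:
    """Counts: total groups, any-nuclear, all-nuclear, mixed, none-nuclear.

    any_nuclear = all_nuclear + mixed (at least one variant nuclear).
    """
    groups = list(groups)
    n_all = sum(1 for g in groups if g.concordance == "all_nuclear")
    n_mixed = sum(1 for g in groups if g.concordance == "mixed")
    n_none = sum(1 for g in groups if g.concordance == "none_nuclear")
    return {
        "n_groups": len(groups),
        "n_any_nuclear": n_all + n_mixed,
        "n_all_nuclear": n_all,
        "n_mixed": n_mixed,
        "n_none_nuclear": n_none,
    }
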