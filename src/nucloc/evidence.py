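"""Benchmarking consensus categories and individual tools against
experimentally observed localizations.

Evidence rows (one per publication or experiment) are merged per protein by
set union of observed compartments: a protein is nuclear-evidenced if any
source ever saw it in the nucleus (conditional nuclear movers count), and
nucleus-only if the merged compartment set contains nothing but the nucleus.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .records import CATEGORY_ORDER, Category, ConsensusResult, EvidenceRecord, NuclearCall
from .reporting import percent


@dataclass
class MergedEvidence:
    locus_id: str
    compartments: set[str]
    sources: set[str]

    @property
    def nuclear(self) -> bool:
        from .records import NUCLEUS_TOKENS

        return bool(self.compartments & NUCLEUS_TOKENS)

    @property
    def nucleus_only(self) -> bool:
        from .records import NUCLEUS_TOKENS

        return self.nuclear and self.compartments <= NUCLEUS_TOKENS


def merge_evidence(records: Iterable[EvidenceRecord]) -> dict[str, MergedEvidence]:
    """One merged record per protein: union of compartments across sources."""
    merged: dict[str, MergedEvidence] = {}
    for r in records:
        m = merged.get(r.locus_id)
        if m is None:
            merged[r.locus_id] = MergedEvidence(
                r.locus_id, set(r.compartments), {r.source}
            )
        else:
            m.compartments |= r.compartments
            m.sources.add(r.source)
    return merged


@dataclass
class CategoryAgreement:
    category: str
    n_evidenced: int
    n_nuclear_evidenced: int
    percent_nuclear: Optional[float]
    n_nucleus_only: int
    percent_nucleus_only: Optional[float]  # among nuclear-evidenced


def agreement_by_category(
    consensus: Mapping[str, ConsensusResult],
    evidence: Mapping[str, MergedEvidence],
    ndigits: int = 2,
) -> tuple[list[CategoryAgreement], Optional[float]]:
    """Per-category evidence agreement plus the pooled >=cat3 accuracy.

    For each category: the fraction of evidenced proteins whose merged
    evidence includes the nucleus. Categories without evidence report missing
    percentages, never 0.
    """
    rows = []
    pooled_n = pooled_k = 0
    for cat in CATEGORY_ORDER:
        members = [
            evidence[pid]
            for pid, r in consensus.items()
            if r.category is cat and pid in evidence
        ]
        n = len(members)
        k = sum(1 for m in members if m.nuclear)
        only = sum(1 for m in members if m.nucleus_only)
        rows.append(
            CategoryAgreement(
                category=cat.value,
                n_evidenced=n,
                n_nuclear_evidenced=k,
                percent_nuclear=percent(k, n, ndigits),
                n_nucleus_only=only,
                percent_nucleus_only=percent(only, k, ndigits),
            )
        )
        if cat in (Category.CAT3, Category.CAT4):
            pooled_n += n
            pooled_k += k
    return rows, percent(pooled_k, pooled_n, ndigits)


def tool_accuracy(
    evidence_nuclear_ids: set[str],
    calls_by_protein: Mapping[str, Iterable[NuclearCall]],
    ndigits: int = 2,
) -> dict[str, Optional[float]]:
    """Per-tool sensitivity on the evidenced-nuclear set.

    100 x (evidenced-nuclear proteins the tool called nuclear) /
    (evidenced-nuclear proteins the tool scored). The denominator is the
    evidenced-nuclear set only, so adding evidenced non-nuclear proteins
    never changes the result.
    """
    if not evidence_nuclear_ids:
        raise ValueError("empty evidenced-nuclear set")
    hit: dict[str, int] = defaultdict(int)
    tot: dict[str, int] = defaultdict(int)
    for pid in evidence_nuclear_ids:
        for call in calls_by_protein.get(pid, ()):
            tot[call.tool] += 1
            if call.nuclear:
                hit[call.tool] += 1
    return {tool: percent(hit[tool], tot[tool], ndigits) for tool in tot}


def exclusive_nuclear_fraction(
    evidence: Mapping[str, MergedEvidence],
    consensus: Mapping[str, ConsensusResult],
    category: Category,
    ndigits: int = 2,
) -> Optional[float]:
    """Among nuclear-evidenced proteins of a category, percent nucleus-only."""
    members = [
        evidence[pid]
        for pid, r in consensus.items()
        if r.category is category and pid in evidence and evidence[pid].nuclear
    ]
    only = sum(1 for m in members if m.nucleus_only)
    return percent(only, len(members), ndigits)
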