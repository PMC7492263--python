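"""Consensus nuclear categorization from four predictor outputs.

Each predictor's output is first normalized to a binary nuclear call:

* NucPred emits a single nuclear propensity score in [0, 1]; the call is
  nuclear iff the score is strictly above the threshold (default 0.8).
* WoLF-PSORT, CELLO and YLoc rank compartments; the call is nuclear iff the
  nucleus compartment's score is strictly greater than every other
  compartment's score (argmax ties involving the nucleus are conservatively
  not nuclear).

The consensus category of a protein is simply the number of tools calling it
nuclear: 0 (non-nuclear) through 4.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from typing import Iterable, Mapping, Optional, Sequence

from .records import (
    CATEGORY_ORDER,
    NUCLEUS_TOKENS,
    TOOLS,
    Category,
    ConsensusResult,
    NuclearCall,
    PipelineConfig,
    ToolPrediction,
)

logger = logging.getLogger(__name__)


def normalize_call(
    locus_id: str,
    tool: str,
    compartment_scores: Optional[Mapping[str, float]] = None,
    nucpred_score: Optional[float] = None,
    config: PipelineConfig | None = None,
    confidence: Optional[float] = None,
) -> NuclearCall:
    cfg = config or PipelineConfig()
    if tool not in TOOLS:
        raise ValueError(f"unknown tool {tool!r}")
    if tool == "nucpred":
        if nucpred_score is None:
            raise ValueError("nucpred requires a score")
        if not 0.0 <= nucpred_score <= 1.0:
            raise ValueError(f"nucpred score out of [0,1]: {nucpred_score}")
        return NuclearCall(
            locus_id=locus_id,
            tool=tool,
            nuclear=nucpred_score > cfg.nucpred_threshold,
            top_compartment="nuclear",
            top_score=nucpred_score,
        )
    if not compartment_scores:
        raise ValueError(f"{tool}: empty compartment score map")
    if tool == "yloc" and any(v < 0 for v in compartment_scores.values()):
        raise ValueError("yloc probabilities must be non-negative")
    scores = {c.strip().lower(): float(s) for c, s in compartment_scores.items()}
    top = max(scores, key=lambda c: scores[c])
    nuc_score = max(
        (s for c, s in scores.items() if c in NUCLEUS_TOKENS), default=None
    )
    others = [s for c, s in scores.items() if c not in NUCLEUS_TOKENS]
    nuclear = nuc_score is not None and (not others or nuc_score > max(others))
    return NuclearCall(
        locus_id=locus_id,
        tool=tool,
        nuclear=nuclear,
        top_compartment=top,
        top_score=scores[top],
        confidence=confidence,
    )


def normalize_predictions(
    predictions: Iterable[ToolPrediction], config: PipelineConfig | None = None
) -> dict[str, list[NuclearCall]]:
    """Group long-format prediction rows per (protein, tool) and normalize."""
    grouped: dict[tuple[str, str], dict[str, float]] = defaultdict(dict)
    for p in predictions:
        grouped[(p.protein_id, p.tool)][p.compartment] = p.score
    calls: dict[str, list[NuclearCall]] = defaultdict(list)
    for (pid, tool), scores in grouped.items():
        if tool == "nucpred":
            call = normalize_call(pid, tool, nucpred_score=max(scores.values()), config=config)
        else:
            call = normalize_call(pid, tool, compartment_scores=scores, config=config)
        calls[pid].append(call)
    return dict(calls)


def assign_category(calls: Sequence[NuclearCall]) -> ConsensusResult:
    """Vote count and category for one protein from its per-tool calls.

    Tools absent from ``calls`` count as non-nuclear votes (with a warning);
    two calls from the same tool are an error.
    """
    if not calls:
        raise ValueError("at least one tool call required")
    seen = Counter(c.tool for c in calls)
    dup = [t for t, n in seen.items() if n > 1]
    if dup:
        raise ValueError(f"duplicate calls for tool(s) {dup}")
    locus = calls[0].locus_id
    missing = set(TOOLS) - set(seen)
    if missing:
        logger.warning("%s: missing tool(s) %s counted as non-nuclear", locus, sorted(missing))
    tools_called = frozenset(c.tool for c in calls if c.nuclear)
    votes = len(tools_called)
    return ConsensusResult(
        locus_id=locus,
        votes=votes,
        category=Category.from_votes(votes),
        tools_called=tools_called,
    )


def categorize_dataset(
    calls_by_protein: Mapping[str, Sequence[NuclearCall]]
) -> tuple[dict[str, ConsensusResult], dict[str, int]]:
    """Consensus per protein plus the five-category count table.

    The count table also carries the "cat2_and_above" aggregate — the
    higher-assertion nuclear set of proteins called by at least two tools.
    """
    results = {pid: assign_category(calls) for pid, calls in calls_by_protein.items()}
    counts = {cat.value: 0 for cat in CATEGORY_ORDER}
    for r in results.values():
        counts[r.category.value] += 1
    counts["cat2_and_above"] = aggregate_high_confidence(counts)
    return results, counts


def aggregate_high_confidence(counts: Mapping[str, int]) -> int:
    """Number of proteins called nuclear by at least two tools."""
    return sum(counts.get(c, 0) for c in ("cat2", "cat3", "cat4"))
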