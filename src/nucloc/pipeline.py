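"""End-to-end orchestration: from input files to the per-protein report and
the summary tables (category distribution, signal fractions, evidence
agreement, tool accuracies, splicing concordance).

Outputs are deterministic given the config and inputs: rows are sorted by
locus ID and JSON keys are emitted in stable order, so repeated runs are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import consensus as cns
from . import evidence as ev
from . import io as nio
from . import splicing as spl
from .records import CATEGORY_ORDER, Category, PipelineConfig, ProteinRecord
from .reporting import percent, round_half_up
from .signals import profile_sequence

logger = logging.getLogger(__name__)

REPORT_COLUMNS = [
    "locus_id", "votes", "category", "n_pat4", "n_pat7", "n_bipartite",
    "basic_percent", "nls_score", "nls_call", "nes_score", "nes_call",
    "loc_class", "evidence_nuclear", "evidence_agrees",
]


@dataclass
class PipelineInputs:
    fasta: str | Path
    predictions: str | Path
    residue_scores: Optional[str | Path] = None
    evidence: Optional[str | Path] = None
    go: Optional[str | Path] = None
    tf: Optional[str | Path] = None
    splice: Optional[str | Path] = None


@dataclass
class PipelineResult:
    report: pd.DataFrame
    summary: dict
    warnings: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig, inputs: PipelineInputs) -> PipelineResult:
    """Run every stage the supplied inputs allow.

    Proteins present in the prediction table but absent from the FASTA are
    logged and excluded; the report holds one row per protein present in
    both inputs.
    """
    warnings: list[str] = []
    proteins = {p.locus_id: p for p in nio.read_fasta(inputs.fasta)}
    preds = nio.read_prediction_table(inputs.predictions)

    unknown = sorted({p.protein_id for p in preds} - set(proteins))
    if unknown:
        msg = f"{len(unknown)} protein(s) in prediction table absent from FASTA: {unknown[:5]}"
        logger.warning(msg)
        warnings.append(msg)
        preds = [p for p in preds if p.protein_id in proteins]

    calls = cns.normalize_predictions(preds, config)
    results, counts = cns.categorize_dataset(calls)

    tracks: Mapping[str, np.ndarray] = {}
    if inputs.residue_scores is not None:
        tracks = nio.read_residue_scores(
            inputs.residue_scores, {pid: p.sequence for pid, p in proteins.items()}
        )

    merged = {}
    if inputs.evidence is not None:
        merged = ev.merge_evidence(nio.read_evidence_table(inputs.evidence))

    rows = []
    for pid in sorted(results):
        r = results[pid]
        prof = profile_sequence(pid, proteins[pid].sequence, config, tracks.get(pid))
        m = merged.get(pid)
        rows.append({
            "locus_id": pid,
            "votes": r.votes,
            "category": r.category.value,
            "n_pat4": prof.n_pat4,
            "n_pat7": prof.n_pat7,
            "n_bipartite": prof.n_bipartite,
            "basic_percent": round_half_up(prof.basic_percent, config.rounding),
            "nls_score": prof.nls_score,
            "nls_call": prof.nls_positive,
            "nes_score": round_half_up(prof.nes_score, config.rounding),
            "nes_call": prof.nes_positive,
            "loc_class": prof.loc_class.value,
            "evidence_nuclear": "" if m is None else m.nuclear,
            "evidence_agrees": "" if m is None else (r.votes >= 1) == m.nuclear,
        })
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)

    summary: dict = {
        "n_proteins": len(report),
        "category_counts": counts,
        "signal_fractions": _signal_fractions(report, config.rounding),
    }
    if merged:
        agree, pooled = ev.agreement_by_category(results, merged, config.rounding)
        nuclear_ids = {pid for pid, m in merged.items() if m.nuclear}
        summary["evidence"] = {
            "n_evidenced": len([pid for pid in merged if pid in results]),
            "by_category": [vars(a) for a in agree],
            "pooled_cat3_cat4_percent_nuclear": pooled,
            "tool_accuracy_percent": ev.tool_accuracy(nuclear_ids, calls, config.rounding)
            if nuclear_ids else {},
        }
    if inputs.splice is not None:
        gene_variants = nio.read_splice_table(inputs.splice)
        groups = spl.build_groups(gene_variants, calls)
        summary["splicing"] = spl.summarize_splicing(groups)
    if inputs.tf is not None:
        from . import enrichment as enr

        _, tf_map = nio.read_annotation_tables(tf_path=inputs.tf)
        comp_rows, tf_dist = enr.tf_composition(results, tf_map, config.rounding)
        summary["tf_composition"] = {
            "by_category": [vars(c) for c in comp_rows],
            "tf_distribution_percent": tf_dist,
        }
    if inputs.go is not None:
        from . import enrichment as enr

        go_map, _ = nio.read_annotation_tables(go_path=inputs.go)
        summary["go_enrichment"] = [
            vars(e) for e in enr.go_enrichment(results, go_map, sorted(results))
        ]
    return PipelineResult(report=report, summary=summary, warnings=warnings)


def _signal_fractions(report: pd.DataFrame, ndigits: int) -> dict:
    """Per-category percent of NLS-carrying, NES-carrying and dual-signal proteins."""
    out = {}
    for cat in CATEGORY_ORDER:
        sub = report[report["category"] == cat.value]
        n = len(sub)
        out[cat.value] = {
            "n": n,
            "percent_nls": percent(int(sub["nls_call"].sum()), n, ndigits),
            "percent_nes": percent(int(sub["nes_call"].sum()), n, ndigits),
            "percent_both": percent(int((sub["nls_call"] & sub["nes_call"]).sum()), n, ndigits),
        }
    n_all = len(report)
    out["overall"] = {
        "n": n_all,
        "percent_nls": percent(int(report["nls_call"].sum()), n_all, ndigits),
        "percent_nes": percent(int(report["nes_call"].sum()), n_all, ndigits),
        "percent_both": percent(int((report["nls_call"] & report["nes_call"]).sum()), n_all, ndigits),
    }
    return out


def write_outputs(result: PipelineResult, report_path: str | Path, summary_path: str | Path) -> None:
    result.report.to_csv(report_path, sep="\t", index=False)
    nio.write_json(result.summary, summary_path)
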