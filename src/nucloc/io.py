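"""Readers and writers for every file the pipeline touches.

Formats: FASTA (Biopython, 60-column wrap on write); tab-delimited tables
with header rows, UTF-8, "." decimals; RFC-4180 evidence CSV; summary JSON
with stable key order. All tables are long-format — one observation per row.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import EvidenceRecord, ProteinRecord, ToolPrediction

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA; the header's first token is the locus ID.

    Sequences are uppercased and alphabet-checked; duplicate locus IDs are an
    error, as is sequence data before any header.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(f"{path}:{lineno}: sequence data before any FASTA header")
                break
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        locus = rec.id
        if locus in seen:
            raise ParseError(f"{path}: duplicate locus_id {locus!r}")
        seen.add(locus)
        records.append(ProteinRecord(locus_id=locus, sequence=str(rec.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as FASTA, 60 columns per sequence line."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.locus_id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqs)


def read_prediction_table(path: str | Path) -> list[ToolPrediction]:
    """Normalized long-format predictor TSV: protein_id, tool, compartment, score."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "tool", "compartment", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    preds = []
    for row in df.itertuples(index=False):
        try:
            score = float(row.score)
        except (TypeError, ValueError):
            raise ParseError(f"{path}: non-numeric score {row.score!r} for {row.protein_id}")
        preds.append(ToolPrediction(row.protein_id, row.tool, row.compartment, score))
    return preds


def write_prediction_table(preds: Iterable[ToolPrediction], path: str | Path) -> None:
    pd.DataFrame(
        [(p.protein_id, p.tool, p.compartment, p.score) for p in preds],
        columns=["protein_id", "tool", "compartment", "score"],
    ).to_csv(path, sep="\t", index=False)


def read_residue_scores(
    path: str | Path, sequences: Mapping[str, str] | None = None
) -> dict[str, np.ndarray]:
    """Per-residue NES score tracks from a TSV: protein_id, position, residue, score.

    Positions are 1-based; missing positions default to 0 and the track length
    is the maximum reported position. When sequences are supplied, residue
    letters are cross-checked; on mismatch the sequence wins and a warning is
    logged.
    """
    df = pd.read_csv(path, sep="\t")
    tracks: dict[str, np.ndarray] = {}
    if df.empty:
        return tracks
    if (df["position"] < 1).any():
        bad = df[df["position"] < 1].iloc[0]
        raise ParseError(f"{path}: position {bad['position']} < 1 for {bad['protein_id']}")
    for pid, grp in df.groupby("protein_id", sort=False):
        length = int(grp["position"].max())
        if sequences and pid in sequences:
            length = max(length, len(sequences[pid]))
        track = np.zeros(length, dtype=float)
        for row in grp.itertuples(index=False):
            pos = int(row.position)
            track[pos - 1] = float(row.score)
            if sequences and pid in sequences:
                seq = sequences[pid]
                if pos <= len(seq) and str(row.residue).upper() != seq[pos - 1]:
                    logger.warning(
                        "%s position %d: track residue %s != sequence residue %s; sequence wins",
                        pid, pos, row.residue, seq[pos - 1],
                    )
        tracks[str(pid)] = track
    return tracks


def read_evidence_table(path: str | Path) -> list[EvidenceRecord]:
    """Evidence CSV: protein_id, source, cell_system, compartments.

    Compartments are semicolon-separated lowercase tokens; rows with an empty
    compartment set are rejected with a logged reason.
    """
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            comps = {
                tok.strip().lower()
                for tok in (row.get("compartments") or "").split(";")
                if tok.strip()
            }
            if not comps:
                logger.warning(
                    "evidence row for %s rejected: empty compartment set", row.get("protein_id")
                )
                continue
            records.append(
                EvidenceRecord(
                    locus_id=row["protein_id"],
                    source=row.get("source", ""),
                    cell_system=row.get("cell_system", ""),
                    compartments=comps,
                )
            )
    return records


def write_evidence_table(records: Iterable[EvidenceRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["protein_id", "source", "cell_system", "compartments"])
        for r in records:
            w.writerow([r.locus_id, r.source, r.cell_system, ";".join(sorted(r.compartments))])


def read_annotation_tables(
    go_path: str | Path | None = None, tf_path: str | Path | None = None
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GO TSV (locus_id, go_term — one pair per row) and TF TSV (locus_id, family)."""
    go_map: dict[str, set[str]] = {}
    tf_map: dict[str, str] = {}
    if go_path is not None:
        df = pd.read_csv(go_path, sep="\t", dtype=str)
        for row in df.itertuples(index=False):
            go_map.setdefault(row.locus_id, set()).add(row.go_term)
    if tf_path is not None:
        df = pd.read_csv(tf_path, sep="\t", dtype=str)
        for row in df.itertuples(index=False):
            tf_map[row.locus_id] = row.family
    return go_map, tf_map


def read_splice_table(path: str | Path) -> dict[str, list[str]]:
    """Splice TSV (gene_id, variant_id) -> ordered gene->variants map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_variants: dict[str, list[str]] = {}
    for row in df.itertuples(index=False):
        gene_variants.setdefault(row.gene_id, []).append(row.variant_id)
    return gene_variants


def read_locus_list(path: str | Path) -> list[str]:
    """One locus ID per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_json(obj, path: str | Path) -> None:
    """JSON with stable key order and a trailing newline."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
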