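"""Synthetic proteome generator with known ground truth.

Emulates the statistical structure of a seed-expressed proteome analysis:
roughly half the proteins are truly nuclear; nuclear proteins are enriched
for planted NLS motifs, nuclear export signals, transcription-factor labels
and the nucleus GO term; four localization predictors call each protein
nuclear with tool-specific sensitivity/specificity; a subset of proteins
carries (noisy) localization evidence; some genes have multiple splice
variants.

Two background-composition modes:

* ``clean`` (default) — background residues exclude K/R (so un-planted
  sequences can never satisfy an NLS predicate) and the hydrophobic NES
  anchors L/I/V/F/M (so they can never satisfy the export-signal consensus).
  Planted-motif recall is then an exact, not statistical, test.
* ``uniform`` — uniform over the 20-letter alphabet, for statistical tests
  where realistic composition matters.

A single seeded generator governs all draws in a fixed stage order
(sequences, predictions, evidence, annotations), so outputs are reproducible
byte-for-byte for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np

from .records import ProteinRecord, ToolPrediction, EvidenceRecord

CLEAN_ALPHABET = "ACDEGHNPQSTWY"  # no K/R (basic) and no L/I/V/F/M (NES anchors)
FULL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

MOTIF_LITERALS = {
    "pat4": "KKKR",
    "pat7": "PKKKRKV",
    "bipartite": "KR" + "AAQAAPAAGA" + "KKKKK",
    "nes": "LAALAALAL",
}

TF_FAMILIES = ("bZIP", "WRKY", "MYB", "NAC", "AP2", "bHLH", "C2H2", "HB")
NUCLEUS_GO_TERM = "GO:0005634"
DECOY_GO_TERMS = ("GO:0005737", "GO:0016020", "GO:0009507", "GO:0005739")


@dataclass
class SimConfig:
    """Study conditions for the synthetic proteome.

    Defaults echo the structure of a rice seed-expressed dataset: ~50%
    nuclear-predicted proteins; tool sensitivities ranked 0.79 / 0.72 /
    0.60 / 0.16 (CELLO > YLoc > WoLF-PSORT > NucPred); evidence for ~7% of
    proteins; TFs ~20% of nuclear vs ~1% of non-nuclear proteins.
    """

    n_proteins: int = 5000
    length_min: int = 80
    length_max: int = 400
    fraction_nuclear: float = 0.5
    # per-class motif planting probabilities
    motif_p_nuclear: dict[str, float] = field(
        default_factory=lambda: {"pat4": 0.60, "pat7": 0.35, "bipartite": 0.45, "nes": 0.19}
    )
    motif_p_non_nuclear: dict[str, float] = field(
        default_factory=lambda: {"pat4": 0.0, "pat7": 0.0, "bipartite": 0.0, "nes": 0.075}
    )
    # per-tool (sensitivity, specificity)
    tool_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "cello": (0.79, 0.88),
            "yloc": (0.72, 0.86),
            "wolfpsort": (0.60, 0.82),
            "nucpred": (0.16, 0.98),
        }
    )
    evidence_coverage: float = 0.07
    evidence_error: float = 0.02
    nucleus_only_prob: float = 0.7
    tf_fraction_nuclear: float = 0.20
    tf_fraction_non_nuclear: float = 0.01
    go_p_nuclear: float = 0.45
    go_p_non_nuclear: float = 0.15
    go_p_decoy: float = 0.10
    splice_fraction: float = 0.20  # fraction of genes carrying 2-3 variants
    background: str = "clean"  # clean | uniform
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        probs = (
            [self.fraction_nuclear, self.evidence_coverage, self.evidence_error,
             self.nucleus_only_prob, self.tf_fraction_nuclear, self.tf_fraction_non_nuclear,
             self.go_p_nuclear, self.go_p_non_nuclear, self.go_p_decoy, self.splice_fraction]
            + list(self.motif_p_nuclear.values())
            + list(self.motif_p_non_nuclear.values())
            + [x for pair in self.tool_params.values() for x in pair]
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.background not in ("clean", "uniform"):
            raise ValueError("background must be 'clean' or 'uniform'")


@dataclass
class TruthRecord:
    locus_id: str
    true_nuclear: bool
    planted_motifs: list[tuple[str, int]]  # (kind, 1-based start)
    is_tf: bool
    go_terms: set[str]
    gene_id: str


def _plant(
    seq: list[str], motifs: list[str], rng: np.random.Generator
) -> list[tuple[str, int]]:
    """Overwrite non-overlapping slices with motif literals; 1-based starts."""
    placed: list[tuple[int, int]] = []
    out = []
    for motif in motifs:
        m = len(motif)
        if m > len(seq):
            raise ValueError(f"motif of length {m} cannot fit a sequence of length {len(seq)}")
        for _ in range(200):
            start = int(rng.integers(0, len(seq) - m + 1))
            if all(start + m <= s or start >= e for s, e in placed):
                break
        else:
            raise ValueError("could not place motif without overlap")
        seq[start : start + m] = list(motif)
        placed.append((start, start + m))
        out.append((motif, start + 1))
    return out


def generate_proteome(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[ProteinRecord], list[TruthRecord]]:
    """Sequences plus ground truth, deterministic for a fixed seed.

    Gene structure: each gene holds one variant, or 2-3 variants with
    probability ``splice_fraction``; variants of a gene share its nuclear
    truth class and differ only in background/planting draws.
    """
    cfg = config
    rng = rng or np.random.default_rng(cfg.rng_seed)
    alphabet = np.array(list(CLEAN_ALPHABET if cfg.background == "clean" else FULL_ALPHABET))
    proteins: list[ProteinRecord] = []
    truths: list[TruthRecord] = []
    motif_order = ("pat4", "pat7", "bipartite", "nes")

    i = 0
    gene_no = 0
    while i < cfg.n_proteins:
        gene_no += 1
        chrom = (gene_no - 1) % 12 + 1
        gene_id = f"LOC_Os{chrom:02d}g{gene_no * 10:05d}"
        if rng.random() < cfg.splice_fraction:
            n_var = int(rng.integers(2, 4))
        else:
            n_var = 1
        n_var = min(n_var, cfg.n_proteins - i)
        nuclear = bool(rng.random() < cfg.fraction_nuclear)
        plant_p = cfg.motif_p_nuclear if nuclear else cfg.motif_p_non_nuclear
        for v in range(1, n_var + 1):
            locus_id = gene_id if n_var == 1 else f"{gene_id}.{v}"
            length = int(rng.integers(cfg.length_min, cfg.length_max + 1))
            seq = list(rng.choice(alphabet, size=length))
            kinds = [k for k in motif_order if rng.random() < plant_p.get(k, 0.0)]
            placed = _plant(seq, [MOTIF_LITERALS[k] for k in kinds], rng)
            planted = [(k, pos) for k, (_, pos) in zip(kinds, placed)]
            proteins.append(
                ProteinRecord(locus_id=locus_id, sequence="".join(seq), gene_id=gene_id)
            )
            truths.append(
                TruthRecord(
                    locus_id=locus_id,
                    true_nuclear=nuclear,
                    planted_motifs=planted,
                    is_tf=False,  # assigned by simulate_annotations
                    go_terms=set(),
                    gene_id=gene_id,
                )
            )
            i += 1
    return proteins, truths


def simulate_tool_predictions(
    truths: Iterable[TruthRecord],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[ToolPrediction]:
    """Predictor tables with controlled per-tool error rates.

    A true-nuclear protein is called nuclear with probability = sensitivity;
    a non-nuclear one with probability = 1 - specificity, independently per
    tool. Emitted compartment scores are consistent with the normalization
    rules: for argmax tools the nucleus strictly tops the ranking iff the
    call is nuclear; for NucPred the score is strictly above / at-or-below
    the 0.8 threshold.
    """
    cfg = config
    rng = rng or np.random.default_rng(cfg.rng_seed + 1)
    preds: list[ToolPrediction] = []
    for t in truths:
        for tool, (sens, spec) in cfg.tool_params.items():
            p_call = sens if t.true_nuclear else 1.0 - spec
            call = bool(rng.random() < p_call)
            if tool == "nucpred":
                score = rng.uniform(0.801, 0.999) if call else rng.uniform(0.0, 0.799)
                preds.append(ToolPrediction(t.locus_id, tool, "nuclear", round(score, 3)))
            else:
                hi = round(rng.uniform(1.5, 3.0), 3)
                lo = round(rng.uniform(0.1, 1.0), 3)
                nuc, cyt = (hi, lo) if call else (lo, hi)
                preds.append(ToolPrediction(t.locus_id, tool, "nucleus", nuc))
                preds.append(ToolPrediction(t.locus_id, tool, "cytoplasm", cyt))
    return preds


def simulate_evidence(
    truths: Iterable[TruthRecord],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[EvidenceRecord]:
    """Localization evidence for a random subset of proteins.

    Observed compartments match the truth class with probability
    1 - evidence_error; nuclear observations are nucleus-only with
    probability ``nucleus_only_prob``, otherwise nucleus + cytoplasm.
    """
    cfg = config
    rng = rng or np.random.default_rng(cfg.rng_seed + 2)
    records = []
    for t in truths:
        if rng.random() >= cfg.evidence_coverage:
            continue
        observed_nuclear = t.true_nuclear
        if rng.random() < cfg.evidence_error:
            observed_nuclear = not observed_nuclear
        if observed_nuclear:
            comps = {"nucleus"} if rng.random() < cfg.nucleus_only_prob else {"nucleus", "cytoplasm"}
        else:
            comps = {"cytoplasm"} if rng.random() < 0.7 else {"cytoplasm", "membrane"}
        records.append(
            EvidenceRecord(
                locus_id=t.locus_id,
                source=f"SIM{1000000 + int(rng.integers(0, 999999))}",
                cell_system="onion epidermis",
                compartments=comps,
            )
        )
    return records


def simulate_annotations(
    truths: list[TruthRecord],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GO and TF annotation maps; mutates truth records in place.

    The nucleus GO term and a TF family label are assigned with higher
    probability to nuclear-truth proteins; decoy GO terms are class-neutral.
    Ribosomal-protein annotation text is attached to a class-neutral 1.5%
    of proteins for keyword-screen exercises.
    """
    cfg = config
    rng = rng or np.random.default_rng(cfg.rng_seed + 3)
    go_map: dict[str, set[str]] = {}
    tf_map: dict[str, str] = {}
    for t in truths:
        terms = set()
        p_nuc_term = cfg.go_p_nuclear if t.true_nuclear else cfg.go_p_non_nuclear
        if rng.random() < p_nuc_term:
            terms.add(NUCLEUS_GO_TERM)
        for decoy in DECOY_GO_TERMS:
            if rng.random() < cfg.go_p_decoy:
                terms.add(decoy)
        if terms:
            go_map[t.locus_id] = terms
        t.go_terms = terms
        p_tf = cfg.tf_fraction_nuclear if t.true_nuclear else cfg.tf_fraction_non_nuclear
        if rng.random() < p_tf:
            fam = TF_FAMILIES[int(rng.integers(0, len(TF_FAMILIES)))]
            tf_map[t.locus_id] = fam
            t.is_tf = True
    return go_map, tf_map


def splice_table_from_truth(truths: Iterable[TruthRecord]) -> dict[str, list[str]]:
    """Gene -> variant list for genes with at least two variants."""
    genes: dict[str, list[str]] = {}
    for t in truths:
        genes.setdefault(t.gene_id, []).append(t.locus_id)
    return {g: vs for g, vs in genes.items() if len(vs) >= 2}


def expected_category_probs(config: SimConfig) -> dict[int, float]:
    """Closed-form category distribution under independent tool errors.

    Poisson-binomial over the four tools' call probabilities, mixed over the
    nuclear / non-nuclear classes: P(votes = c) for c = 0..4.
    """
    def poisson_binomial(ps: list[float]) -> np.ndarray:
        pmf = np.array([1.0])
        for p in ps:
            pmf = np.convolve(pmf, [1.0 - p, p])
        return pmf

    f = config.fraction_nuclear
    nuc = poisson_binomial([s for s, _ in config.tool_params.values()])
    non = poisson_binomial([1.0 - sp for _, sp in config.tool_params.values()])
    mix = f * nuc + (1.0 - f) * non
    return {c: float(mix[c]) for c in range(5)}


def write_dataset(outdir: str | Path, config: SimConfig) -> dict[str, Path]:
    """Generate a full dataset and write every pipeline input file.

    Emits proteins.fasta, predictions.tsv, evidence.csv, go.tsv, tf.tsv,
    splice.tsv and truth.tsv under ``outdir``; returns the path map.
    """
    import pandas as pd

    from . import io as nio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)
    proteins, truths = generate_proteome(config, rng)
    preds = simulate_tool_predictions(truths, config, rng)
    evid = simulate_evidence(truths, config, rng)
    go_map, tf_map = simulate_annotations(truths, config, rng)

    paths = {k: outdir / v for k, v in {
        "fasta": "proteins.fasta", "predictions": "predictions.tsv",
        "evidence": "evidence.csv", "go": "go.tsv", "tf": "tf.tsv",
        "splice": "splice.tsv", "truth": "truth.tsv",
    }.items()}
    nio.write_fasta(proteins, paths["fasta"])
    nio.write_prediction_table(preds, paths["predictions"])
    nio.write_evidence_table(evid, paths["evidence"])
    pd.DataFrame(
        [(pid, term) for pid, terms in sorted(go_map.items()) for term in sorted(terms)],
        columns=["locus_id", "go_term"],
    ).to_csv(paths["go"], sep="\t", index=False)
    pd.DataFrame(sorted(tf_map.items()), columns=["locus_id", "family"]).to_csv(
        paths["tf"], sep="\t", index=False
    )
    splice = splice_table_from_truth(truths)
    pd.DataFrame(
        [(g, v) for g, vs in sorted(splice.items()) for v in vs],
        columns=["gene_id", "variant_id"],
    ).to_csv(paths["splice"], sep="\t", index=False)
    pd.DataFrame(
        [
            (t.locus_id, t.gene_id, int(t.true_nuclear), int(t.is_tf),
             ";".join(f"{k}@{p}" for k, p in t.planted_motifs))
            for t in truths
        ],
        columns=["locus_id", "gene_id", "true_nuclear", "is_tf", "planted_motifs"],
    ).to_csv(paths["truth"], sep="\t", index=False)
    return paths
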