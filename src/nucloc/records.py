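"""Core domain types shared across the pipeline.

A protein is identified by its RGAP-style locus ID (``LOC_OsXXgYYYYY``).
Sequences are uppercase strings over the 20 standard amino acids plus ``X``
(unknown residue). Everything downstream — signal scanning, consensus voting,
evidence evaluation — keys on the locus ID.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
VALID_ALPHABET = AMINO_ACIDS | {"X"}

TOOLS = ("wolfpsort", "yloc", "cello", "nucpred")

#: Compartment tokens interpreted as the nucleus (case-folded).
NUCLEUS_TOKENS = frozenset({"nucleus", "nuclear", "nucl"})


class LocClass(str, Enum):
    """Joint NLS/NES classification of a protein's trafficking signals."""

    NUCLEAR_RESIDENT = "nuclear_resident"  # NLS only
    SHUTTLING = "shuttling"                # NLS and NES
    EXPORT_SIGNAL_ONLY = "export_signal_only"  # NES only
    NO_SIGNAL = "no_signal"


class Category(str, Enum):
    """Consensus category: number of predictors (0-4) calling a protein nuclear."""

    NON_NUCLEAR = "non_nuclear"
    CAT1 = "cat1"
    CAT2 = "cat2"
    CAT3 = "cat3"
    CAT4 = "cat4"

    @classmethod
    def from_votes(cls, votes: int) -> "Category":
        if not 0 <= votes <= 4:
            raise ValueError(f"votes must be in 0..4, got {votes}")
        return cls.NON_NUCLEAR if votes == 0 else cls(f"cat{votes}")

    @property
    def votes(self) -> int:
        return 0 if self is Category.NON_NUCLEAR else int(self.value[-1])


CATEGORY_ORDER = (
    Category.NON_NUCLEAR,
    Category.CAT1,
    Category.CAT2,
    Category.CAT3,
    Category.CAT4,
)


@dataclass
class ProteinRecord:
    locus_id: str
    sequence: str
    is_tf: bool = False
    tf_family: Optional[str] = None
    go_terms: set[str] = field(default_factory=set)
    annotation_text: str = ""
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.locus_id}: empty sequence")
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"{self.locus_id}: invalid residue letter(s) {sorted(bad)}; "
                "only the 20 amino acids plus X are accepted"
            )
        if not self.gene_id:
            # RGAP convention: splice variants share the locus stem before '.'
            self.gene_id = self.locus_id.split(".")[0]


@dataclass
class ToolPrediction:
    """One predictor's score for one (protein, compartment)."""

    protein_id: str
    tool: str
    compartment: str
    score: float

    def __post_init__(self) -> None:
        if self.tool not in TOOLS:
            raise ValueError(f"unknown tool {self.tool!r}; expected one of {TOOLS}")
        self.compartment = self.compartment.strip().lower()


@dataclass
class NuclearCall:
    locus_id: str
    tool: str
    nuclear: bool
    top_compartment: str = ""
    top_score: float = float("nan")
    confidence: Optional[float] = None


@dataclass
class ConsensusResult:
    locus_id: str
    votes: int
    category: Category
    tools_called: frozenset[str]

    def __post_init__(self) -> None:
        if self.votes != len(self.tools_called):
            raise ValueError("votes must equal the number of tools calling nuclear")


@dataclass
class EvidenceRecord:
    locus_id: str
    source: str
    cell_system: str
    compartments: set[str]

    @property
    def nuclear(self) -> bool:
        return bool(self.compartments & NUCLEUS_TOKENS)

    @property
    def nucleus_only(self) -> bool:
        return self.nuclear and self.compartments <= NUCLEUS_TOKENS


@dataclass
class PipelineConfig:
    """Tunables for the whole pipeline.

    nucpred_threshold
        NucPred score above which (strictly) a protein is called nuclear.
    nes_window, nes_min_residues
        The windowed NES rule: a protein is NES-positive when at least
        ``nes_min_residues`` contributing residues fall within any stretch of
        ``nes_window`` consecutive positions.
    nes_residue_threshold
        A residue contributes when its per-residue NES score is strictly above
        this value (0.5 matches NetNES's own decision threshold; the built-in
        surrogate scorer uses 0.0 since its scores are binary).
    nls_weights
        (w_pat4, w_pat7, w_bipartite, base) for the cumulative NLS score.
    rounding
        Decimal places for reported percentages (half-up).
    """

    nucpred_threshold: float = 0.8
    nes_window: int = 15
    nes_min_residues: int = 3
    nes_residue_threshold: float = 0.5
    nls_weights: tuple[float, float, float, float] = (1.0, 1.0, 2.0, -1.0)
    rng_seed: int = 0
    rounding: int = 2

    def __post_init__(self) -> None:
        if self.nes_window < 1:
            raise ValueError("nes_window must be >= 1")
        if self.nes_min_residues < 1:
            raise ValueError("nes_min_residues must be >= 1")
        if not 0.0 <= self.nucpred_threshold <= 1.0:
            raise ValueError("nucpred_threshold must lie in [0, 1]")
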