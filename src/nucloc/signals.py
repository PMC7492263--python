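"""Nuclear localization and export signal scanning.

Implements the classical PSORT II-style NLS predicates and a windowed NES
call over per-residue export-signal scores.

* PAT4 — a 4-residue cluster that is either all basic (K/R) or exactly three
  basic residues with the fourth being H or P.
* PAT7 — a proline-anchored 7-mer: starts with P and contains a 4-mer
  beginning at offset 1, 2 or 3 with at least three basic residues.
* Bipartite — the Robbins-Dingwall consensus over 17 residues: two basic
  residues, a 10-residue unconstrained spacer, then at least 3 basic residues
  among the final 5 positions.

All positions are 1-based and windows are closed intervals. Overlapping
matches are each reported at their own start. ``X`` never counts as basic
(or as H/P), so unknown residues cannot create a match.

The cumulative NLS score is a weighted count of pattern matches plus a base
offset; a strictly positive score marks the protein NLS-containing. The NES
score of a protein is the plain sum of its per-residue NES track; the protein
is NES-containing when at least ``min_residues`` contributing residues (track
score strictly above a threshold) fall within any window of ``window``
consecutive positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .records import LocClass, PipelineConfig

BASIC = frozenset("KR")
HELIX_BREAKERS = frozenset("HP")  # the tolerated fourth residue of PAT4
NES_ANCHORS = "LIVFM"  # hydrophobic anchor set of the leucine-rich NES consensus

PAT4_LEN = 4
PAT7_LEN = 7
BIPARTITE_LEN = 17


@dataclass(frozen=True)
class PatternMatch:
    kind: str  # pat4 | pat7 | bipartite
    start: int  # 1-based
    length: int
    matched_subsequence: str


def _window_sums(mask: np.ndarray, w: int) -> np.ndarray:
    """Sliding sums of a 0/1 vector over all windows of width w."""
    if mask.size < w:
        return np.empty(0, dtype=int)
    c = np.concatenate(([0], np.cumsum(mask)))
    return c[w:] - c[:-w]


def _masks(sequence: str) -> tuple[np.ndarray, np.ndarray]:
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    basic = (arr == ord("K")) | (arr == ord("R"))
    hp = (arr == ord("H")) | (arr == ord("P"))
    return basic.astype(np.int64), hp.astype(np.int64)


def scan_pat4(sequence: str) -> list[PatternMatch]:
    """All PAT4 matches: 4-mers with 4 basic residues, or 3 basic + one H/P."""
    if len(sequence) < PAT4_LEN:
        return []
    basic, hp = _masks(sequence)
    b4 = _window_sums(basic, PAT4_LEN)
    h4 = _window_sums(hp, PAT4_LEN)
    hits = np.flatnonzero((b4 == 4) | ((b4 == 3) & (h4 == 1)))
    return [
        PatternMatch("pat4", int(i) + 1, PAT4_LEN, sequence[i : i + PAT4_LEN])
        for i in hits
    ]


def scan_pat7(sequence: str) -> list[PatternMatch]:
    """All PAT7 matches: P-anchored 7-mers holding a basic-rich internal 4-mer.

    A window qualifies when some 4-mer starting at offset 1, 2 or 3 inside it
    carries at least three K/R residues; each qualifying window is reported
    once, at the window start.
    """
    n = len(sequence)
    if n < PAT7_LEN:
        return []
    basic, _ = _masks(sequence)
    b4 = _window_sums(basic, 4)  # b4[i] = basic count of sequence[i:i+4]
    starts = []
    for i in range(n - PAT7_LEN + 1):
        if sequence[i] != "P":
            continue
        if any(b4[i + off] >= 3 for off in (1, 2, 3)):
            starts.append(i)
    return [
        PatternMatch("pat7", i + 1, PAT7_LEN, sequence[i : i + PAT7_LEN])
        for i in starts
    ]


def scan_bipartite(sequence: str) -> list[PatternMatch]:
    """All bipartite matches: KR-KR, 10-residue spacer, >=3 of 5 basic."""
    n = len(sequence)
    if n < BIPARTITE_LEN:
        return []
    basic, _ = _masks(sequence)
    b5 = _window_sums(basic, 5)  # b5[i] = basic count of sequence[i:i+5]
    hits = []
    for i in range(n - BIPARTITE_LEN + 1):
        if basic[i] and basic[i + 1] and b5[i + 12] >= 3:
            hits.append(i)
    return [
        PatternMatch("bipartite", i + 1, BIPARTITE_LEN, sequence[i : i + BIPARTITE_LEN])
        for i in hits
    ]


def basic_fraction(sequence: str) -> float:
    """Percentage of K+R residues (H excluded)."""
    if not sequence:
        raise ValueError("empty sequence")
    k = sum(1 for c in sequence if c in BASIC)
    return 100.0 * k / len(sequence)


def nls_score(
    n_pat4: int,
    n_pat7: int,
    n_bipartite: int,
    weights: tuple[float, float, float, float] = (1.0, 1.0, 2.0, -1.0),
) -> float:
    """Cumulative NLS score: weighted pattern counts plus a base offset.

    Default weights (1, 1, 2, -1) make any single bipartite match, or any
    monopartite pair — or indeed any single monopartite match — push the score
    positive; a strictly positive score marks the protein NLS-containing.
    """
    if min(n_pat4, n_pat7, n_bipartite) < 0:
        raise ValueError("pattern counts must be non-negative")
    w4, w7, wb, base = weights
    return w4 * n_pat4 + w7 * n_pat7 + wb * n_bipartite + base


def surrogate_nes_track(sequence: str) -> np.ndarray:
    """Per-residue NES scores from the leucine-rich consensus.

    Scans Phi-x(2,3)-Phi-x(2,3)-Phi-x-Phi with Phi in {L,I,V,F,M}. A residue
    occupying a Phi anchor position of any match (any start, any gap
    combination) scores 1; all other residues score 0. This is a deliberately
    transparent stand-in for a trained per-residue export-signal predictor,
    adequate for exercising the windowed NES call.
    """
    n = len(sequence)
    track = np.zeros(n, dtype=float)
    is_phi = [c in NES_ANCHORS for c in sequence]
    for i in range(n):
        if not is_phi[i]:
            continue
        for g1 in (2, 3):
            p2 = i + 1 + g1
            if p2 >= n or not is_phi[p2]:
                continue
            for g2 in (2, 3):
                p3 = p2 + 1 + g2
                p4 = p3 + 2
                if p4 < n and is_phi[p3] and is_phi[p4]:
                    track[[i, p2, p3, p4]] = 1.0
    return track


def nes_call(
    track: Sequence[float] | np.ndarray,
    window: int = 15,
    min_residues: int = 3,
    residue_threshold: float = 0.5,
) -> tuple[float, bool]:
    """Total NES score and the windowed presence call.

    The score is the sum over all residues. The call is positive when some
    window of ``window`` consecutive positions contains at least
    ``min_residues`` residues whose score is strictly above
    ``residue_threshold``.
    """
    arr = np.asarray(track, dtype=float)
    total = float(arr.sum())
    if arr.size == 0:
        return total, False
    contributing = (arr > residue_threshold).astype(np.int64)
    w = min(window, arr.size)
    positive = bool((_window_sums(contributing, w) >= min_residues).any())
    return total, positive


def classify_localization(nls_positive: bool, nes_positive: bool) -> LocClass:
    if nls_positive and not nes_positive:
        return LocClass.NUCLEAR_RESIDENT
    if nls_positive and nes_positive:
        return LocClass.SHUTTLING
    if nes_positive:
        return LocClass.EXPORT_SIGNAL_ONLY
    return LocClass.NO_SIGNAL


@dataclass
class SignalProfile:
    locus_id: str
    n_pat4: int
    n_pat7: int
    n_bipartite: int
    basic_percent: float
    nls_score: float
    nls_positive: bool
    nes_track: np.ndarray
    nes_score: float
    nes_positive: bool
    loc_class: LocClass


def profile_sequence(
    locus_id: str,
    sequence: str,
    config: PipelineConfig | None = None,
    nes_track: Sequence[float] | np.ndarray | None = None,
) -> SignalProfile:
    """Full signal profile for one protein.

    When ``nes_track`` is None the surrogate scorer is used and residues
    contribute at any score above zero; an externally supplied track is
    thresholded at the configured NetNES-style cutoff.
    """
    cfg = config or PipelineConfig()
    p4 = scan_pat4(sequence)
    p7 = scan_pat7(sequence)
    bp = scan_bipartite(sequence)
    score = nls_score(len(p4), len(p7), len(bp), cfg.nls_weights)
    if nes_track is None:
        track = surrogate_nes_track(sequence)
        thr = 0.0
    else:
        track = np.asarray(nes_track, dtype=float)
        thr = cfg.nes_residue_threshold
    total, positive = nes_call(track, cfg.nes_window, cfg.nes_min_residues, thr)
    return SignalProfile(
        locus_id=locus_id,
        n_pat4=len(p4),
        n_pat7=len(p7),
        n_bipartite=len(bp),
        basic_percent=basic_fraction(sequence),
        nls_score=score,
        nls_positive=score > 0,
        nes_track=track,
        nes_score=total,
        nes_positive=positive,
        loc_class=classify_localization(score > 0, positive),
    )
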