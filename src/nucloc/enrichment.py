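"""Category composition and enrichment statistics.

Fold enrichment of a term in a category is the ratio of in-category frequency
to reference frequency, (k/n) / (K/N); significance is the upper-tail
hypergeometric probability P(X >= k) of drawing k or more term-positive
proteins in a sample of n from a universe of N containing K positives.
Multiple testing is controlled by Benjamini-Hochberg step-up FDR within one
family of terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import CATEGORY_ORDER, Category, ConsensusResult, ProteinRecord
from .reporting import percent


def fold_enrichment(k: int, n: int, K: int, N: int) -> Optional[float]:
    """(k/n) / (K/N); None when the reference frequency is zero/undefined."""
    _check_counts(k, n, K, N)
    if n == 0 or K == 0 or N == 0:
        return None
    return (k / n) / (K / N)


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    _check_counts(k, n, K, N)
    if k == 0:
        return 1.0  # certain event; also covers the empty universe (scipy: nan)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def _check_counts(k: int, n: int, K: int, N: int) -> None:
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid counts k={k}, n={n}, K={K}, N={N}")


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted q-values."""
    if len(p_values) == 0:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])


@dataclass
class EnrichmentResult:
    term: str
    category: str
    k: int
    n: int
    K: int
    N: int
    fold: Optional[float]
    p_value: float
    q_value: float


def go_enrichment(
    consensus: Mapping[str, ConsensusResult],
    go_map: Mapping[str, set[str]],
    universe: Iterable[str],
    categories: Sequence[Category] = (Category.CAT1, Category.CAT2, Category.CAT3, Category.CAT4),
) -> list[EnrichmentResult]:
    """Per-category GO-term enrichment against the whole supplied universe.

    BH adjustment is applied across all terms within one category.
    """
    universe = list(universe)
    N = len(universe)
    terms = sorted({t for pid in universe for t in go_map.get(pid, ())})
    K_by_term = {t: sum(1 for pid in universe if t in go_map.get(pid, set())) for t in terms}
    out: list[EnrichmentResult] = []
    for cat in categories:
        members = [pid for pid in universe if pid in consensus and consensus[pid].category is cat]
        n = len(members)
        rows = []
        for t in terms:
            k = sum(1 for pid in members if t in go_map.get(pid, set()))
            K = K_by_term[t]
            rows.append((t, k, K, fold_enrichment(k, n, K, N), hypergeom_p(k, n, K, N)))
        qs = bh_adjust([r[4] for r in rows])
        for (t, k, K, fold, p), q in zip(rows, qs):
            out.append(EnrichmentResult(t, cat.value, k, n, K, N, fold, p, q))
    return out


def score_distribution_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> Optional[tuple[float, float]]:
    """Welch two-sample t statistic and two-sided p; None when degenerate.

    Groups with fewer than two values, or with both variances zero, cannot be
    tested and are reported missing rather than forced to a number — except
    for the exactly-identical-groups case, which is trivially (t=0, p=1).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        return None
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return None
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


@dataclass
class CompositionRow:
    category: str
    n_proteins: int
    n_tf: int
    tf_percent: Optional[float]


def tf_composition(
    consensus: Mapping[str, ConsensusResult],
    tf_map: Mapping[str, str],
    ndigits: int = 2,
) -> tuple[list[CompositionRow], dict[str, Optional[float]]]:
    """TF count/percent per category and the TF distribution across categories."""
    rows = []
    tf_by_cat: dict[str, int] = {}
    for cat in CATEGORY_ORDER:
        members = [pid for pid, r in consensus.items() if r.category is cat]
        n_tf = sum(1 for pid in members if pid in tf_map)
        tf_by_cat[cat.value] = n_tf
        rows.append(CompositionRow(cat.value, len(members), n_tf, percent(n_tf, len(members), ndigits)))
    total_tf = sum(tf_by_cat.values())
    dist = {c: percent(k, total_tf, ndigits) for c, k in tf_by_cat.items()}
    return rows, dist


def keyword_screen(
    records: Iterable[ProteinRecord], keyword: str, ndigits: int = 2
) -> tuple[set[str], Optional[float]]:
    """Case-insensitive literal substring screen over functional annotations.

    Matches the literal keyword only (no stemming); percent is relative to
    the searched universe.
    """
    if not keyword:
        raise ValueError("empty keyword")
    kw = keyword.lower()
    records = list(records)
    hits = {r.locus_id for r in records if kw in r.annotation_text.lower()}
    return hits, percent(len(hits), len(records), ndigits)


@dataclass
class ProteomeOverlap:
    n_union: int
    n_seed_expressed: int
    by_category: dict[str, int]
    n_predicted_nuclear: int
    percent_predicted_nuclear: Optional[float]


def proteome_overlap(
    consensus: Mapping[str, ConsensusResult],
    proteome_locus_lists: Sequence[Iterable[str]],
    universe: Iterable[str],
    ndigits: int = 2,
) -> ProteomeOverlap:
    """Cross-tabulate external nuclear-proteome loci against categories.

    The lists are deduplicated by union, intersected with the seed-expressed
    universe, then distributed over the five consensus categories; "predicted
    nuclear" means category >= 1.
    """
    union = set().union(*map(set, proteome_locus_lists)) if proteome_locus_lists else set()
    uni = set(universe)
    seed = union & uni
    by_cat = {cat.value: 0 for cat in CATEGORY_ORDER}
    for pid in seed:
        if pid in consensus:
            by_cat[consensus[pid].category.value] += 1
    n_nuc = sum(v for c, v in by_cat.items() if c != Category.NON_NUCLEAR.value)
    return ProteomeOverlap(
        n_union=len(union),
        n_seed_expressed=len(seed),
        by_category=by_cat,
        n_predicted_nuclear=n_nuc,
        percent_predicted_nuclear=percent(n_nuc, len(seed), ndigits),
    )
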