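"""Composition and enrichment statistics for a categorized protein set.

Computes hypergeometric GO enrichment with BH-FDR control, TF composition
per category, a keyword screen, and a Welch t comparison of score
distributions.
"""

import numpy as np

from nucloc import (
    Category,
    ConsensusResult,
    ProteinRecord,
    fold_enrichment,
    go_enrichment,
    hypergeom_p,
    keyword_screen,
    score_distribution_test,
    tf_composition,
)


def cons(pid, votes):
    tools = ("wolfpsort", "yloc", "cello", "nucpred")[:votes]
    return ConsensusResult(pid, votes, Category.from_votes(votes), frozenset(tools))


rng = np.random.default_rng(0)
# 400 proteins: 100 in category 4 (GO 'nucleus' in 60%, TF in 25%),
# 300 non-nuclear (GO 'nucleus' in 15%, TF in 2%)
consensus, go_map, tf_map = {}, {}, {}
for i in range(400):
    pid = f"p{i}"
    nuclear = i < 100
    consensus[pid] = cons(pid, 4 if nuclear else 0)
    if rng.random() < (0.60 if nuclear else 0.15):
        go_map[pid] = {"GO:0005634"}
    if rng.random() < (0.25 if nuclear else 0.02):
        tf_map[pid] = "bZIP"

res = go_enrichment(consensus, go_map, sorted(consensus), categories=(Category.CAT4,))
for e in res:
    print(f"{e.term} in {e.category}: {e.k}/{e.n} vs {e.K}/{e.N} reference "
          f"-> fold={e.fold:.2f}, p={e.p_value:.2e}, q={e.q_value:.2e}")

rows, dist = tf_composition(consensus, tf_map)
for r in rows:
    if r.n_proteins:
        print(f"TF composition {r.category:12s}: {r.n_tf}/{r.n_proteins} = {r.tf_percent}%")

records = [ProteinRecord(f"r{i}", "MKV",
                         annotation_text="60S ribosomal protein" if i < 12 else "kinase")
           for i in range(800)]
hits, pct = keyword_screen(records, "ribosomal")
print(f"keyword 'ribosomal': {len(hits)} hits = {pct}% of the universe")

a = rng.normal(2.0, 1.0, 40)   # e.g. NLS scores, category 4
b = rng.normal(0.5, 1.0, 60)   # non-nuclear category
t, p = score_distribution_test(a, b)
print(f"Welch t between score distributions: t={t:.2f}, p={p:.2e}")
print("\nfold >1 with small q marks the term over-represented in the category")
print("relative to the whole-universe reference.")
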