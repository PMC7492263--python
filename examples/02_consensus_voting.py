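"""Consensus nuclear categorization from four predictors' outputs.

Normalizes a small long-format prediction table (WoLF-PSORT / YLoc / CELLO
rank compartments, NucPred emits a propensity score) to binary nuclear calls
and assigns the five-category consensus.
"""

from nucloc import ToolPrediction, categorize_dataset, normalize_predictions

rows = [
    # histone-like protein: every tool agrees on the nucleus
    ("histone_like", "wolfpsort", "nucleus", 9.0), ("histone_like", "wolfpsort", "cytoplasm", 2.0),
    ("histone_like", "yloc", "nucleus", 0.8), ("histone_like", "yloc", "cytoplasm", 0.2),
    ("histone_like", "cello", "nucleus", 2.4), ("histone_like", "cello", "cytoplasm", 1.1),
    ("histone_like", "nucpred", "nuclear", 0.95),
    # shuttling TF: two of four tools call nuclear; NucPred sits at the 0.8 boundary
    ("shuttling_tf", "wolfpsort", "nucleus", 5.0), ("shuttling_tf", "wolfpsort", "cytoplasm", 4.0),
    ("shuttling_tf", "yloc", "cytoplasm", 0.6), ("shuttling_tf", "yloc", "nucleus", 0.4),
    ("shuttling_tf", "cello", "nucleus", 1.9), ("shuttling_tf", "cello", "cytoplasm", 1.2),
    ("shuttling_tf", "nucpred", "nuclear", 0.80),  # strictly-above rule: not nuclear
    # metabolic enzyme: nothing points at the nucleus
    ("enzyme", "wolfpsort", "cytoplasm", 8.0), ("enzyme", "wolfpsort", "nucleus", 1.0),
    ("enzyme", "yloc", "cytoplasm", 0.9), ("enzyme", "yloc", "nucleus", 0.1),
    ("enzyme", "cello", "cytoplasm", 3.0), ("enzyme", "cello", "nucleus", 0.5),
    ("enzyme", "nucpred", "nuclear", 0.10),
]
preds = [ToolPrediction(*r) for r in rows]
results, counts = categorize_dataset(normalize_predictions(preds))

for pid, r in sorted(results.items()):
    tools = ", ".join(sorted(r.tools_called)) or "none"
    print(f"{pid:14s} votes={r.votes}  category={r.category.value:12s} called by: {tools}")
print()
print("category counts:", counts)
print("The category is simply the number of tools voting nuclear (0-4);")
print("'cat2_and_above' is the higher-assertion nuclear set (>=2 votes).")
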