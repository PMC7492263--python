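# Methods

## Consensus categorization

Each of the four predictor families is reduced to one binary nuclear call
per protein before any voting.

* **NucPred** emits a single nuclear-propensity score in [0, 1]; the call is
  nuclear iff the score is *strictly* above the threshold (default 0.8,
  configurable as `nucpred_threshold`). The boundary case therefore counts
  as non-nuclear.
* **WoLF-PSORT, CELLO, YLoc** rank compartments; the call is nuclear iff the
  nucleus compartment's score is strictly greater than every other
  compartment's. Argmax ties involving the nucleus count as *not* nuclear —
  the conservative reading, since a tie does not single the nucleus out.
  Dual-compartment labels (e.g. a combined nucleus/cytoplasm class) are not
  interpreted; callers must pre-split such scores per compartment in the
  normalized table. This is a documented limitation of the long-format
  carrier, not of the voting rule.

The consensus category is the vote count 0–4. Proteins with no prediction
rows at all are excluded from category tables rather than silently binned as
non-nuclear; proteins scored by only some tools are counted with the missing
tools as non-nuclear votes, with a logged warning. YLoc's confidence value
is carried through (`NuclearCall.confidence`) but never thresholded.

## NLS predicates and score

The scanners implement the classical PSORT II pattern definitions; the
predicate table is centralized in `signals.py`:

| pattern | window | rule |
|---|---|---|
| PAT4 | 4 | all four ∈ {K,R}, or exactly three ∈ {K,R} and the fourth ∈ {H,P} |
| PAT7 | 7 | starts with P; some 4-mer at offset 1–3 has ≥ 3 residues ∈ {K,R} |
| bipartite | 17 | positions 1–2 ∈ {K,R}; positions 3–12 free spacer; ≥ 3 of positions 13–17 ∈ {K,R} |

Positions are 1-based and windows are closed intervals throughout.
Overlapping windows are each reported (counts are per distinct start); no
published overlap convention exists for these counts, and counting each
start keeps the scanners equal to plain window enumeration. `X` never
satisfies any residue class, so unknown residues cannot create matches.

The cumulative NLS score is `1·n_pat4 + 1·n_pat7 + 2·n_bipartite − 1`
by default: any single bipartite match or any two monopartite matches (or
one monopartite plus anything) is positive, while a lone PAT4 — the weakest
and most frequent signal — is not sufficient on its own. The weights and
base are configurable (`nls_weights`); PSORT II's internal scoring formula
is not published in a recoverable form, so this weighted count is the
package's own definition of "cumulative NLS score", exposed as
configuration rather than hidden.

## NES track and windowed call

A protein's NES score is the plain sum of its per-residue track. The
presence call is windowed: the protein is NES-containing iff some stretch of
15 consecutive positions (any i..i+14) contains at least 3 *contributing*
residues, a residue contributing iff its track score is strictly above a
threshold. For external NetNES-style tracks the threshold is 0.5 (NetNES's
own per-residue decision line); the built-in surrogate emits binary scores,
so its calls use a threshold of 0.

The surrogate scorer marks the Φ anchors of every match (any start, any gap
combination) of the leucine-rich consensus Φ-x(2,3)-Φ-x(2,3)-Φ-x-Φ with
Φ ∈ {L,I,V,F,M}. It is a transparent pattern rule, not a trained predictor:
adequate for exercising and testing the windowed call, not a replacement
for a real export-signal model.

Joint classification: NLS only → nuclear-resident; NLS and NES → shuttling;
NES only → export-signal-only; neither → no-signal.

## Evidence merging and accuracy

Evidence rows are merged per protein by set union of compartments across
sources. "Nuclear-evidenced" means any source observed the nucleus —
conditionally nuclear movers count as nuclear; "nucleus-only" means the
merged set contains nothing else. Compartment vocabulary is free-text
lowercased tokens; only nucleus synonyms (`nucleus`, `nuclear`, `nucl`) are
interpreted. Tool accuracy is sensitivity on the evidenced-nuclear set only
(the natural denominator when evidence catalogs are strongly biased toward
positive observations); a category with no evidence reports a missing
percentage, never 0.

## Statistics

* Enrichment: fold = (k/n)/(K/N) against the whole supplied universe as
  reference (configurable); p = upper-tail hypergeometric P(X ≥ k)
  (`scipy.stats.hypergeom.sf`; the k = 0 certain event short-circuits to 1,
  which also covers the empty-universe edge where scipy returns NaN);
  BH step-up FDR within each category's term family
  (`statsmodels.multipletests`).
* Score-distribution comparisons use Welch's unequal-variance t-test,
  two-sided. Groups with fewer than two values or zero variance in both
  groups are reported missing (identical constant groups are the trivial
  t = 0, p = 1 case).
* Percentages are rounded half-up (`decimal`) at a configured number of
  places (default 2); undefined fractions (zero denominators) are reported
  as missing, never coerced to 0.
* Keyword screens match the literal keyword, case-insensitively, as a
  substring — no stemming, so "ribosome" does not match "ribosomal"; pass a
  stem explicitly to widen.

## Synthetic proteome

The generator's defaults are the study conditions the rest of the package is
exercised under:

| parameter | default | rationale |
|---|---|---|
| `n_proteins` | 5000 | large enough for ±2-point binomial bands on tool accuracy, small enough to run in seconds |
| length | uniform 80–400 | typical protein lengths; always fits all four motif literals |
| `fraction_nuclear` | 0.5 | about half of a seed-expressed set is nuclear-predicted |
| motif planting (nuclear) | pat4 0.60, pat7 0.35, bipartite 0.45, NES 0.19 | high NLS prevalence and ~19% NES carriers in the top category |
| motif planting (non-nuclear) | NLS 0, NES 0.075 | a small NES-only fraction among non-nuclear proteins |
| tool (sens, spec) | cello (0.79, 0.88), yloc (0.72, 0.86), wolfpsort (0.60, 0.82), nucpred (0.16, 0.98) | sensitivities follow the observed tool ranking; specificities are not published, so they are set to plausible values that reproduce a ~50/50 nuclear/non-nuclear call split, NucPred being rarely positive but precise |
| evidence coverage / error | 0.07 / 0.02 | evidence exists for a small minority of proteins and is occasionally wrong |
| TF fraction nuclear / non-nuclear | 0.20 / 0.01 | strong TF enrichment in high-vote categories |
| nucleus GO term P(nuclear / non-nuclear) | 0.45 / 0.15 | ~2-fold planted enrichment |
| `splice_fraction` | 0.20 | a fifth of genes carry 2–3 isoforms |

Backgrounds: the default `clean` alphabet excludes K/R *and* the NES anchors
L/I/V/F/M, so an un-planted stretch can satisfy neither an NLS predicate nor
the export-signal consensus — planted-motif recall is an exact test, not a
statistical one. The `uniform` mode draws from all 20 letters for tests
where realistic composition matters. Motifs are planted as literal
substrings at non-overlapping uniform positions (error if a motif cannot
fit); variants of a splice gene share the gene's truth class but draw
sequences independently.

One seeded `numpy` generator drives all draws in fixed stage order
(sequences → predictions → evidence → annotations), so a seed reproduces
every output file byte-for-byte.

What the simulation does *not* emulate: real amino-acid composition and
domain grammar, non-classical NLSs (PY-NLS and other karyopherin-β cargo
signals are explicitly out of scope), piggy-back import, correlated tool
errors (real predictors share training data and fail together; simulated
tools err independently, which makes consensus look better than it is on
hard proteins), and abundance bias in proteome lists. Passing recovery
tests therefore show the pipeline's bookkeeping and statistics are right
under the stated error model — not that the predictors themselves achieve
these accuracies on real proteins.

Category counts under the model follow a closed-form mixture of
Poisson-binomial distributions (`expected_category_probs`), which the test
suite compares against observed counts at 99.8% per-bin binomial bands
(Bonferroni over the five bins).

## Problem sizes used in checks

Scanner/oracle equivalence runs on 1000 random sequences of length ≤ 50
plus 300 planted-motif sequences; the NES rule on 1000 random tracks;
hypergeometric enumeration on every (k, n, K, N) with N ≤ 12; parameter
recovery on one 5000-protein simulation with evidence coverage 1.0 and
error 0 (so the evidenced-nuclear denominator ≈ 2500 supports 99% binomial
bands of about ±2 points). These sizes keep the whole suite under a minute
on one CPU.

## Known limitations

* The long-format prediction table is the only supported carrier; native
  predictor output dialects are not parsed.
* GO annotations are used as given — no ontology-graph propagation.
* The NLS score is a weighted motif count, not PSORT II's internal score.
* Cross-tool splice-variant analysis is not attempted; concordance uses one
  designated tool (default WoLF-PSORT).
* A printed percentage that was truncated rather than rounded in a source
  table can differ from this package's half-up value by 0.01.
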