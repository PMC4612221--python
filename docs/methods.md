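# Methods

This note records the model, the numerical choices, and the design
decisions behind `funfams`, in the order the pipeline runs.

## Similarity convention

All column scoring shares one residue-similarity matrix: BLOSUM62 entries
are first scaled to correlations `s(a,b) / sqrt(s(a,a) s(b,b))` (unit
diagonal) and then min-max mapped to [0, 1] keeping the diagonal at 1. The
unknown residue X has similarity 0 to everything, including itself, so it
contributes occupancy but never similarity. Gap characters `-` and `.` are
accepted on input and stored as `-`. Positions are 0-based internally and
1-based in every user-facing export.

## Conservation and DOPS

A column's conservation score is the (optionally sequence-weighted) mean
normalized similarity over **all ordered residue pairs including
self-pairs**, multiplied by the column's non-gap fraction. Including
self-pairs makes the score a pure function of the column's residue
frequency profile — exactly invariant under row duplication — at the cost
of a small upward shift relative to the self-pair-free estimator (an
affine reparameterization at fixed column occupancy, so ordering and
diversity are unchanged). Columns with fewer than two residues score 0;
columns scoring ≥ 0.7 are called highly conserved.

DOPS (Diversity of Position Scores) is `100 (u − 1)/(p − 1)` where `u` is
the number of distinct column scores after rounding to 3 decimals and `p`
the number of columns; a single-column profile returns 0. The linear form
is the unique one matching the two defining anchors (0 when all scores
tie, 100 when none do); rounding exists so float noise cannot inflate
distinctness.

Sequence weighting: the `score_columns` operation defaults to uniform
weights, with Henikoff position-based weighting available. The **tree
cut**, however, uses Henikoff weighting for its per-node DOPS values by
default: with uniform weights and 3-decimal rounding, the scores of a
20-sequence alignment live on a coarse lattice of rational values and
DOPS saturates near 70 regardless of true diversity; sequence weighting
restores a continuous score distribution (the scorer the DOPS construct
was designed around is itself sequence-weighted). For alignments of
near-identical sequences both weightings agree that DOPS is low, so the
informativeness gate keeps its protective role.

## Group-contrast (SDP) scoring

For a two-group column, `gs = ((s_w(1) + s_w(2))/2) · (1 − s_b)` with
`s_w(g)` the mean pairwise similarity within group `g`'s residues
(self-similarity 1 when a group has a single residue) and `s_b` the mean
similarity across group pairs, clamped to [0, 1]. A column is undefined
when either group's non-gap fraction falls below 0.5. Classification uses
the literal half-open intervals: `gs ≤ 0.3` conserved, `0.7 < gs ≤ 1`
SDP, the middle band neither. Two consequences worth knowing:

* any column with `s_w ≈ s_b` (e.g. neutral columns without group
  structure) scores at most `x(1 − x) ≤ 0.25` and therefore lands in the
  conserved count `N_c`;
* a column perfectly conserved on residues with similarity `s` per group
  scores `≈ 1 − s`, so the SDP call at 0.7 corresponds directly to the
  residue-pair dissimilarity 0.3.

Windowing from the original group-specificity literature is deliberately
omitted; the scorer is a plain per-column contract and is pluggable.

## Coherence index

Per parent node: `D_f = 1` iff **both** child alignments have DOPS
strictly above 70 (a child with < 2 rows or < 2 columns gets DOPS 0);
a column counts as gapped when its gap fraction is ≥ 0.5 and
`f_gap = 1` iff non-gapped columns do not outnumber gapped ones;
`R_sdp = N_sdp/(N_c + N_sdp) − 0.2` when `D_f = 1`, else
`N_sdp/N_c − 1`. Degenerate denominators: no scored columns at all gives
`R_sdp = −0.2` (no divergence evidence, merge); `D_f = 0, N_c = 0` with
SDPs present gives `+inf` (never merge).

Two decision rules are implemented:

* `as_printed`: FC = 1 iff `R_sdp · f_gap ≤ 0`. This is the canonical
  algebraic form and the default of the `functional_coherence` operation.
  Taken literally it makes every low-gap parent coherent (`f_gap = 0`
  forces the product to 0), i.e. on gapless alignments no amount of SDP
  evidence can ever split a node — which defeats the index's stated
  purpose.
* `strict_gap`: FC = 1 iff `R_sdp ≤ 0` **and** `f_gap = 0` — SDP excess
  and gap excess are each sufficient evidence against coherence. The tree
  cut uses this rule by default; the printed rule remains selectable.

With `D_f = 1` the merge condition `R_sdp ≤ 0` is algebraically
`N_sdp ≤ 0.25 · N_c`; with `D_f = 0` it is `N_sdp ≤ N_c` (verified by
exhaustive enumeration in the tests).

## Clustering and the tree

Starting clusters come from greedy 90%-identity preclustering (longest
sequence founds a cluster and acts as its representative; identity is
matches on the best ungapped diagonal divided by the shorter length),
followed by removal of clusters lacking any member with a high-quality GO
annotation (non-IEA evidence, plus EC2GO/Keyword2GO electronic
annotations) and of fragments shorter than 80% of the superfamily-wide
mean sequence length.

A single master alignment of all surviving sequences is built once —
with MAFFT (`--globalpair --maxiterate 2`) when available, which is the
accurate regime for globally homologous domains, else with an internal
progressive profile aligner (longest-first, affine-gap NW over expected
substitution scores; adequate for closely related sets, rougher on deeply
diverged ones). Every per-node alignment is a row restriction of the
master with all-gap columns dropped; there is no per-node realignment.

Starting-cluster profiles are per-column residue frequency vectors over
the master alignment; pairwise cluster similarity is the mean of
`1 − JSD` (Jensen–Shannon divergence, base 2) over columns where both
clusters are non-gap-majority. The tree is average-linkage (UPGMA)
agglomeration of these similarities. Centroid-style re-profiling after
each merge was tried and rejected: merged profiles smooth toward the
background composition, which makes the growing cluster the nearest
neighbour of everything and degenerates the tree into a caterpillar.

## The cut

The default strategy is merge acceptance ("subtree"): a node may stand as
one family only if every internal node in its subtree is coherent, and
the cut is the set of maximal such nodes — equivalent to evaluating FC
bottom-up during agglomeration and stopping merges at the first
incoherent parent. A pure top-down "first coherent node" descent is also
provided, but it is blind to divergence nested below a node whose own two
children happen to be balanced mixtures (with K ≥ 3 sub-groups the root's
group-vs-group contrast washes out, so the descent would stop
immediately). Family identifiers are assigned in traversal order; the cut
always partitions the sequences, and single-sequence leaves are valid
families.

## Family models and membership

Per family, match columns are those with < 50% gaps. Emission log-odds
(bits) compare smoothed residue frequencies against Robinson–Robinson
background frequencies; the smoothing prior is background mass
proportional to the observed count (`pseudocount` = prior mass per
observed sequence, default 2.0). Scoring is affine-gap local dynamic
programming over the emissions (gap open 4 bits, extend 0.25 bits).

The inclusion threshold is the minimum seed self-scan score, computed
**leave-one-out**: each seed is scored against emissions estimated from
the other seeds. With a count-based profile, a self-inclusive scan lets
every seed collect bonus score at its own private substitutions; the
bias scales with the count mass exactly as the seed-score spread does, so
no amount of smoothing removes it, and a threshold taken from
self-inclusive minima would reject a large fraction of genuine new
members. The leave-one-out scan is the unbiased seed score that the
lowest-seed rule presumes (heavily regularized profile-HMM
implementations approximate the same thing through entropy weighting).
Every seed still meets its family's threshold when scanned against the
full model — this is asserted after every build.

Assignment is best-hit: a query joins the highest-scoring family among
those whose threshold it meets (≥, so the defining minimum seed passes;
ties break toward the smaller family id); an all-models-above-threshold
mode is available. Whole-protein annotation resolves domains greedily by
descending bit score with a 15-residue overlap tolerance, transfers each
matched family's seed-frequency GO confidences, propagates them up the
DAG by maximum, and unions domains keeping each term's highest
confidence. Seed counting for frequencies is DAG-aware (a seed annotated
with a descendant of t counts for t); exact-term counting is a flag.

## Evaluation

* **EC purity**: unique four-field EC numbers per family over annotated
  members; families without EC-annotated members are excluded;
  `fraction_single_ec` is the headline number.
* **Precision–recall / F_max** (CAFA protein-centric): at each threshold
  τ ∈ {0.00, 0.01, …, 1.00}, precision averages per-protein
  `TP/(TP+FP)` over proteins with ≥ 1 prediction at τ, recall averages
  `TP/(TP+FN)` over all assessment proteins; F_max is the best harmonic
  mean; coverage (fraction of proteins with any prediction) is reported
  separately, mirroring protocols that evaluate only on covered subsets.
* **Enrichment**: per family, `|conserved ∩ catalytic|/|conserved| −
  |catalytic|/n_columns` over alignment columns (the committed reading of
  "residues"); undefined without conserved columns. Family values are
  averaged per superfamily and tested with a one-sided Wilcoxon
  signed-rank test against median 0 (exact for n ≤ 25 without ties,
  normal approximation with continuity correction otherwise; zeros
  dropped, mid-ranks for ties). The test is one-sample by construction —
  the cited usage with a single vector is signed-rank — though a
  two-sample mode is trivially available through `scipy`.

## Synthetic superfamilies

The generator emulates the alignment structure the method consumes: K
subfamilies (default 4) of 20 sequences, length 200, with 15%
family-conserved columns, 30% SDP columns and 55% neutral columns.
Subfamily SDP residues are the exhaustively optimal most-mutually-
dissimilar k-subset of the alphabet under the normalized matrix (the
assignment of residues to subfamilies is permuted per column); the
worst-pair similarity of the best 5-subset is 0.311, which is why the
feasibility bound defaults to 0.35. Substitution processes:

* per-column rate jitter around each class mean (conserved 0.1–4× of
  0.04 — a wide spread so conserved scores fill the high-conservation
  band; SDP 0.5–1.5× of 0.04 — narrow, keeping group contrast crisp;
  neutral 0.5–1.5× of 0.30) and a per-sequence rate multiplier
  U(0.8, 1.2) for lineage effects;
* conservative substitutions at functional sites (a mutant is drawn from
  the 4 most similar residues), as real functional sites tolerate;
* at least two substitutions per conserved column and one per SDP column
  per subfamily — without this guarantee, unmutated and single-mutant
  columns collapse onto a handful of score values and DOPS is flattened
  by ties rather than by biology;
* neutral lineage drift: each subfamily's consensus is substituted at 30%
  of neutral sites, so subfamilies diverge outside their functional
  sites too; at impure nodes drifted columns score mid-range (neither
  conserved nor SDP), as in real families.

Subfamilies are star-shaped (no deeper phylogeny); optional
subfamily-specific insertions (`indel_rate`) create length divergence and
`fragment_fraction` truncates a tail of each subfamily to exercise the
fragment filter. Annotations: per subfamily, unique leaf GO terms plus
shared family-wide terms under a single toy root, one distinct EC number,
and a configurable annotated fraction. Everything is deterministic under
the seed.

What the simulations do **not** emulate: realistic phylogenies and
rate matrices, correlated sites, indel length distributions, annotation
noise/bias, and superfamily-scale sequence counts. Passing tests
demonstrate that the machinery detects the signals it is defined on and
that the pipeline's orderings (family-level EC purity and F_max above
superfamily-level) hold when those signals are present — not performance
on real superfamily data.

## Problem sizes and determinism

Test and example runs use superfamilies of 40–100 sequences of length
200; the end-to-end recovery study is 20 seeded runs over K ∈ {2, 3, 4, 5}
with a 0%-SDP control, and the membership study uses an 80/20 seed/
held-out split. All randomness flows from explicit integer seeds; the
pipeline itself is deterministic (tie-breaks are lexicographic, linkage
is scipy's deterministic average linkage, MAFFT runs in its deterministic
progressive/G-INS mode).

## Known limitations

* The group-contrast scorer gives mid-range scores to partially
  structured columns, so `N_c` absorbs every column without group signal;
  with the 0.2 constant of the SDP ratio this means splits need SDP
  fractions above ~20% of scored columns — weakly diverged sub-groups
  merge by design.
* The internal fallback aligner degrades on deeply diverged sets; MAFFT
  is strongly recommended.
* Bit scores are raw log-odds without an extreme-value calibration, so
  thresholds are comparable within a family library but scores carry no
  E-value semantics.
* Domain resolution is a greedy interval selection, not a probabilistic
  domain architecture model.
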