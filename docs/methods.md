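# Methods

## Problem

Given a population of predicted multimeric protein structures for one target
— and no experimental answer — estimate, for every model, (i) a global fold
quality score (SCORE), (ii) an interface quality score (QSCORE), and (iii)
per-residue confidences that each residue belongs to the inter-chain
interface. The estimates follow the consensus (clustering) principle: a model
that agrees structurally with many other models of the same target is likely
to be close to the truth. Single-model terms are mixed in because pure
clustering fails when populations are small or dominated by one wrong
conformation.

## Pairwise similarity metrics

All pairwise comparisons operate on a resolved chain correspondence
(see *Chain mapping*) and are heavy-atom based; hydrogens are ignored.

- **oligo-lDDT** — superposition-free local distance difference test over the
  whole assembly. Assessed pairs are all reference heavy-atom pairs from
  different residues (intra- **and** inter-chain) within an inclusion radius
  of 15 Å; the score is the mean over thresholds {0.5, 1, 2, 4} Å of the
  fraction of pairs whose model distance deviates from the reference distance
  by at most the threshold. Atoms missing from the model fail at every
  threshold. Unlike the official lDDT tool, no stereochemistry checks are
  applied — a documented simplification.
- **DockQ** — composite of fnat (fraction of reference inter-chain residue
  contacts at ≤ 5 Å heavy-atom distance reproduced by the model), iRMS
  (backbone RMSD over reference interface residues, i.e. residues with any
  heavy atom within 10 Å of another chain, after superposing on those
  residues) and LRMS (backbone RMSD of the smaller chain of each contacting
  chain pair after superposing on the larger; for more than one interface the
  per-interface values are averaged unweighted):
  `DockQ = (fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²)) / 3`.
- **QS-score** — conservation of inter-chain Cβ–Cβ contacts (Cα for glycine)
  within 12 Å. The weighted dialect uses a linear ramp, weight 1 up to 5 Å
  falling to 0 at 12 Å, scoring Σ min(w_model, w_ref) over shared contacts
  against Σ max-side weights over the union; the "official-style" dialect
  uses binary weights (a Jaccard over contact sets). The two dialects back
  the two QS jury variants. The linear ramp is a stated simplification of
  the published QS weighting.
- **ICS / IPS** — F1 of the inter-chain contact sets (5 Å heavy-atom) and
  Jaccard of the interface residue sets, after translating the model's
  contacts into the reference residue labelling.
- **TM-score** — over the mapped Cα trace of the concatenated chains, with
  `d0 = 1.24·(L−15)^⅓ − 1.8` (floored at 0.5 Å), L the reference residue
  count. The superposition search seeds Kabsch fits from sliding windows of
  lengths L, L/2, L/4 (… ≥ 4) and iteratively re-fits on the residues within
  a selection cutoff until the selected core is stable, over three cutoff
  levels (d0+2.5 Å down to d0/2). The search is a bounded heuristic: every
  reported value is realised by an explicit rigid transform (so it never
  overshoots the true optimum), and on small cases it matches or exceeds a
  10⁴-subset brute-force lower bound.

Numeric constants (lDDT thresholds and radius; DockQ 1.5/8.5/5/10 Å; QS
5/12 Å; contacts at Cβ ≤ 8 Å for single-model terms; clashes at < 2.2 Å)
follow the standard published definitions of these scores; none are fitted
here.

## Chain mapping

Model populations carry missing, inconsistent or permuted chain labels.
Chains are grouped into sequence-identity groups (mutual identity ≥ 95%
after global alignment); groups are matched across models by sequence
(minimum 30% identity to map at all); within a matched group the chain
permutation maximising the shared inter-chain contact weight (the QS-score
numerator) is chosen — exhaustively for groups of up to 6 chains, greedily
by per-chain superposition RMSD above that. Residue correspondence within a
mapped chain pair comes from a global sequence alignment, so models with
gaps still compare position-by-position. The 95% / 30% thresholds and the
size-6 exhaustive cap are pragmatic choices; the contact-overlap objective
for the permutation is this package's concrete resolution of the
homo-oligomer ambiguity.

## Component scores

- **Juries** (DockQJury, QSscoreJury, QSscoreOfficialJury, lDDTOfficialJury):
  a model's mean pairwise metric against a reference set — normally the rest
  of the population (the scored model is always excluded from its own
  reference set, so identical populations score 1.0 rather than trivially
  inflating). Pairs whose metric is undefined (e.g. contactless reference
  for DockQ) are skipped; the pairwise values are summed in sorted order so
  results do not depend on how the reference set was assembled.
- **ModFOLDIA** (per-residue interface accuracy): for residue *i*, the mean
  over references of the Jaccard overlap between its cross-chain
  contact-partner sets (5 Å heavy-atom) in model and reference, with
  Jaccard(∅,∅) = 0 — the score reads as the likelihood the residue belongs
  to the interface. The global value averages over residues with model-side
  partners. This contact-Jaccard consensus is this package's concrete
  instantiation of an interface-accuracy clustering score; the original
  method's exact algorithm is not published in the open literature.
- **CDA** (contact distance agreement): consensus contacts are residue pairs
  (intra- or inter-chain, Cβ ≤ 8 Å) present in at least half of the
  references; the model's Cβ distance is scored against the median reference
  distance lDDT-style over the four thresholds. The 8 Å / 50% constants are
  this package's choices, likewise a documented instantiation.
- **voromqa**: an adapter around an external Voronoi-tessellation scorer
  (configurable command template emitting JSON). Without a configured tool,
  a self-contained fallback keeps the pipeline closed:
  `global = C / (C + 4X + 10)` with C the inter-chain Cβ ≤ 8 Å contact count
  and X the heavy-atom clash count (< 2.2 Å, excluding within-residue and
  sequence-adjacent same-chain pairs — covalent neighbours are not clashes);
  per-residue fallback is 1 for residues in a non-clashing inter-chain
  contact, else 0. The fallback is deterministic and rigid-motion invariant.

## Consensus variants

SCORE, QSCORE and residue confidences are **unweighted means** of the
variant's component lists; no learned weights.

| variant | SCORE | QSCORE | residues |
|---|---|---|---|
| dock  | DockQJury, lDDTOfficialJury | DockQJury, QSscoreOfficialJury | ModFOLDIA |
| dockR | QSscoreJury, lDDTOfficialJury, voromqa | DockQJury, QSscoreOfficialJury, voromqa | voromqa, ModFOLDIA |
| dockS | DockQJury, lDDTOfficialJury | DockQJury, QSscoreOfficialJury | CDA, voromqa, ModFOLDIA |

dock targets linear correlation with observed quality, dockR targets
ranking, and dockS is the quasi-single-model variant: it scores each model
against an externally supplied reference set (nominally 30 pre-computed
models) instead of the population, so it works even for a single submitted
model.

For populations above 1,500 total residues (dock/dockR), all-against-all
comparison is shortcut: all models are pre-scored once with voromqa and only
the top 40 serve as jury references. The subset is selected per scored model
from its peers (the model itself is never a candidate reference); a subset
covering all peers therefore reproduces the all-against-all result exactly,
and for n ≪ N the behaviour matches the published procedure up to
self-exclusion. Components that fail for one model are dropped from that
model's mean with a logged warning — server robustness over strictness —
and a model where everything fails is returned flagged `unscored`.

## Observed scores and evaluation

Against a native structure: interface quality = mean(ICS, IPS); fold quality
= mean(oligo-lDDT, TM). Predictors are compared by Pearson and Spearman
correlation, ROC-AUC for recovering models with observed score ≥ 0.6 (the
threshold is configurable; assessors do not publish theirs), top-1 loss
(best observed minus observed of the predictor's first pick, predicted ties
broken by model id), the combined formula
`0.5·Pearson + 0.5·Spearman + AUC − Loss` summed over the two observed
scores, and a Z-score sum standardising each raw score column over groups
((x − mean)/sd in one pass, without iterative outlier exclusion; a
zero-spread column contributes 0 with a warning).

## Synthetic decoy generator

Each chain is an idealised α-helix (100°/1.5 Å per residue, radius 2.3 Å)
carrying N, CA, C, O, CB heavy atoms built from local frames (glycines have
no CB); chains sit on a ring with 9.5 Å axis spacing, which yields a
contact-rich interface (≥ 5 contacts at 5 Å guaranteed by a generator
self-check) and no clashes. Homomeric mode reuses one random sequence,
heteromeric mode draws distinct sequences (a sprinkling of glycines
exercises the Cα fallback of Cβ-based scores). Decoys apply per-chain rigid
rotation/translation of stated magnitude about the chain centroid plus
i.i.d. Gaussian coordinate noise; tier allocation is deterministic from the
ladder fractions, and every decoy records its tier as ground truth. The
default ladder (σ = 0/0.5/1/2/4 Å with proportional rigid terms) spans
observed scores from 1.0 down to ≈ 0.2. Chain labels can be permuted among
sequence-identical chains to exercise the mapping machinery, and a
two-cluster preset (the last chain flipped 180°) reproduces the
conformational-heterogeneity failure mode of consensus scoring.

The generator emulates the population structure of blind-prediction model
sets, not protein physics: no side chains beyond Cβ, no secondary-structure
variety, isotropic noise. Passing tests therefore demonstrate correctness of
the scoring machinery and the qualitative behaviour of consensus scoring on
graded ensembles — not accuracy on real predictions.

## Numerical and design notes

- Comparisons are cached per model pair (chain mapping, residue/atom
  correspondence, metric values), with an identity fast path for models of
  identical topology; population scoring costs O(pairs) gather work. Models
  are treated as immutable once scored.
- Jury sums are computed in sorted order; reference lists are sorted by
  model id inside ModFOLDIA/CDA — so results are independent of reference
  set assembly order (and the top-40 route is bit-identical to
  all-against-all when the subset covers all peers).
- fnat's population mean is *not* monotone in pure per-atom Gaussian noise:
  around σ 0.5–2 Å the minimum over the ~25 atom pairs of a residue pair
  dips below the 5 Å cutoff more often as spread grows, so contact recovery
  plateaus before collapsing. The seven other bounded metrics are tier-wise
  monotone; tests assert exactly that, with end-to-end degradation for fnat.
- Degenerate inputs raise typed errors: contactless references
  (`NoInterfaceError`), no assessed lDDT pairs (`UndefinedScoreError`),
  < 15 mapped residues for TM, < 3 points for superposition, constant score
  vectors and single-class AUC labels in the evaluation harness.
- Problem sizes used in the test suite and the acceptance script — 20–24
  residues per chain, populations of 31–250 models, 30-model external
  reference sets — were chosen so that the full graded ladder (50 decoys per
  rung across five rungs) and all three variants run comfortably on one
  core; they sit at the small end of the generator's supported range
  (2–4 chains, 20–80 residues per chain).

## Known limitations

- The QMODE2 writer fixes 3-decimal scores and 20 residue values per line;
  the exact line width of the original submission system is not published.
- TM-score search is heuristic; the global optimum is not guaranteed
  (though never overstated).
- ModFOLDIA and CDA are documented instantiations, not reproductions, of
  the eponymous unpublished algorithms.
- Z-scores are one-pass (no iterative outlier exclusion as used in official
  rankings).
- Reference-model *generation* for the quasi-single-model variant is out of
  scope; reference models are an input.
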