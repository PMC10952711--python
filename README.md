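# assemblyqa

Consensus estimation of model accuracy (EMA) for **multimeric** protein
structure models. Given a population of predicted complex structures for one
target — and no experimental structure — `assemblyqa` estimates for every
model a global fold score (SCORE), an interface score (QSCORE) and
per-residue interface confidences, and writes them in the CASP QA QMODE2
submission format. It is aimed at structure-prediction groups who need to
pick the best model out of a pool of predictions, and at assessors who need
to evaluate such predictors against a native structure.

## Method in brief

The core idea is jury (clustering) scoring: a model's quality estimate is
its mean pairwise similarity to a reference set, normally the rest of the
population,

SCORE(m) = mean over components c of J_c(m),  J_c(m) = (1/|R|) Σ_{r∈R} s_c(m, r),

where the pairwise similarities s_c are oligo-lDDT (superposition-free local
distance differences over intra- and inter-chain atom pairs), DockQ
(fnat + interface RMSD + ligand RMSD composite), and QS-score (conservation
of weighted inter-chain Cβ contacts), plus single-model terms (a
Voronoi-contact score and a contact distance agreement score) and a
per-residue interface-accuracy consensus (contact-partner Jaccard against
the population). Three variants combine these components differently:
`dock` (optimised for linear correlation with observed quality), `dockR`
(optimised for ranking; adds single-model terms) and `dockS`
(quasi-single-model: scores against an external reference model set instead
of the population). Chain mapping for homo-oligomers — missing, swapped or
permuted chain labels — is resolved before any comparison by maximising
inter-chain contact overlap over the permutations of sequence-identical
chains. For evaluation against a native, observed interface quality is
mean(ICS, IPS) and observed fold quality mean(oligo-lDDT, TM-score), with
Pearson/Spearman, ROC-AUC, top-1 loss and Z-score sums ranking the
predictors. See `docs/methods.md` for the full account.

## Worked example

Everything runs on self-generated synthetic populations — no downloads:

```
assemblyqa simulate --out-dir demo --n-decoys 8 --seed 7 --chain-length 24
assemblyqa score demo/population --variant dock --target T0001 --out demo/scores.qa
assemblyqa evaluate demo/population --native demo/native.pdb \
    --predictions demo/scores.qa --out demo/report.tsv
```

which prints (the decoy population spans a quality ladder from exact copies
of the native down to strongly perturbed models):

```
wrote native + 8 decoys to demo
wrote 8 records to demo/scores.qa
pearson=0.982 spearman=1.000 auc=1.000 top1_loss=0.000
wrote report to demo/report.tsv
```

`pearson`/`spearman` correlate the predicted SCORE with the observed fold
quality of each decoy against the native; `auc` is the recovery of good
models (observed ≥ 0.6) and `top1_loss` the observed-quality gap between the
best model and the one ranked first — 0.000 means the jury put a true
near-native model on top. `demo/scores.qa` holds one QMODE2 record per
model: name, SCORE, QSCORE, then per-residue confidences, three decimals,
twenty per line.

The same machinery is available as a library:

```python
import assemblyqa as aq

spec   = aq.DecoyEnsembleSpec(n_chains=2, chain_lengths=(24, 24), seed=7, n_decoys=8)
native = aq.make_native(spec)
decoys = aq.make_decoys(native, spec)
estimates = aq.score_population(decoys, "dock")
observed  = aq.observed_scores(decoys, native)
```

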