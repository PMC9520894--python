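# bfsig

Transcriptional signatures of the BCL2 family for AML subtyping and
drug-response prediction.

Anti-apoptotic BCL2-family proteins (BCL2, MCL1, BFL1/BCL2A1, BCLXL/BCL2L1,
BCLW/BCL2L2) decide whether a leukaemic blast dies when a BH3-mimetic such
as venetoclax blocks BCL2. Their transcript levels alone predict response
poorly; the regulatory network around them does better. `bfsig` builds
**BCL2-family signatures (BFSigs)** from bulk RNA-seq: it starts from a
curated pool of BCL2-family-regulation genes, prunes it so the five anchor
genes' profiles are well imputed from the rest, factorizes the pruned
matrix by non-negative matrix factorization, and uses the per-sample
signature activities to subtype AML cohorts and to predict inhibitor
response. It is written for computational biologists who want each stage —
masked factorization, gene selection, rank selection, subtyping,
classification — as a tested, seedable building block rather than a
one-shot script.

## The model

Expression `A` (genes × samples, non-negative) is factorized as `A ≈ W H`
with `W, H ≥ 0`, fitted by multiplicative updates minimizing the mean
generalized Kullback–Leibler divergence over *observed* entries only:

    d(a, â) = a·ln(a/â) − a + â          (0·ln 0 = 0)

The observation mask makes the factorization a matrix-completion device;
hiding the anchor genes' entries fold by fold and scoring their
reconstruction (per-anchor range-normalized RMSE) gives the objective for
**backward gene selection**: the gene whose removal most improves anchor
imputation is dropped until nothing helps. The NMF rank is chosen where
the **cophenetic correlation coefficient** of the consensus matrix (over
repeated seeded fits, samples co-clustered by dominant factor) begins to
fall. Signature gene-weights are normalized to sum to one, signatures are
labeled by their dominant anchor (BCL2, MCL1/BCL2, BFL1/MCL1, ...), samples
are clustered on activities (average linkage, 1 − Pearson), and a
ridge-stabilized logistic model on the activities predicts binary response
(IC50 ≤ 1 μM sensitive / ≥ 10 μM resistant), evaluated by 10× repeated
stratified 70/30 splits with pooled AUROC, DeLong comparisons, and — for
small continuous-response cohorts — leave-one-out OLS scored by NRMSE.

A synthetic-data generator with full ground truth (factor loadings,
activities, gene roles, response model) stands in for the controlled-access
cohorts; see `docs/methods.md` for the generative model and what it does
and does not emulate.

## Worked example

A complete run on simulated data (120 samples, 5 anchors + 15 co-regulated
signal genes + 15 high-noise genes, 3 latent factors):

```bash
cat > config.yaml <<EOF
seed: 7
stages: [simulate, optimize, extract, subtype, classify]
simulate: {n_samples: 120, n_signal: 15, n_noise: 15}
optimize: {k: 3}
extract:  {ranks: [2, 6]}
classify: {drug: venetoclax}
EOF
bfsig run --config config.yaml --out run/
```

This takes under a minute and prints

```
completed stages: ['simulate', 'optimize', 'extract', 'subtype', 'classify']
```

with, in `run/`:

- `optimized_genes.txt` — 20 of the 35 pool genes survive selection; on
  this dataset that is all 5 anchors, all 15 signal genes and none of the
  15 noise genes (`optimization.json` holds the removal history and the
  non-increasing error trace).
- `signatures/rank_report.json` — cophenetic coefficients
  `{2: 0.993, 3: 1.000, 4: 0.998, 5: 0.990, 6: 0.987}`; the first fall is
  after k = 3, so rank 3 is chosen — the generator's true factor count.
- `signatures/labels.json` — labels `["BFL1", "BCL2/BCLXL", "MCL1/BCLW"]`:
  each signature is named after the anchor(s) dominating its normalized
  gene weights.
- `subtypes.tsv` — three balanced subtypes (41/40/39 samples) named after
  the dominant signature, matching the generator's three sample groups.
- `evaluation.json` — the signature-based classifier reaches a pooled
  AUROC of 0.894 (95% CI 0.858–0.930, n = 108 after IC50 binarization and
  latest-time-point de-duplication): close to the generating model's
  performance ceiling, since the three activities are exactly the features
  the response was simulated from.

Every stage is importable directly, in scikit-learn style:

```python
from bfsig import MaskedNMF, GeneSetOptimizer, simulate_bfsig_dataset

expr, pool, truth = simulate_bfsig_dataset(seed=7)
opt = GeneSetOptimizer(k=3, random_state=7).fit(expr, pool)
model = MaskedNMF(rank=3, random_state=7).fit(opt.transform(expr).values)
```

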