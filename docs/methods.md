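# Methods

## The model

The package predicts disease-related metabolites by completing and
factorizing a disease–metabolite association matrix.

**Initial matrix.** Curated associations define a 0–1 matrix `MDR_init` with
rows indexed by metabolites (|M|) and columns by diseases (|D|):
`mdr_init(m, d) = 1` iff metabolite m is recorded as associated with disease
d. Real corpora of this kind are extremely sparse, which is the motivation
for the two completion channels below.

**Similarity completion.** Two independent evidence channels estimate the
unknown cells:

- *Disease fill* `DF(m, d)`: 1 where d is already associated with m,
  otherwise the maximum disease–disease similarity between d and any disease
  in `D_m` (the diseases of m). The disease similarity matrix is an external
  input (in practice the output of a gene-functional-network semantic
  similarity method); this package does not recompute it.
- *Metabolite fill* `MF(m, d)`: the symmetric construction over `M_d` using
  metabolite literature similarity, obtained by min–max normalizing pairwise
  text-mining co-occurrence scores.

The channels are combined per cell by a noisy-OR,

    mdr(m, d) = 1 − (1 − DF(m, d)) (1 − MF(m, d)),

the probability that at least one channel fires if the two are independent.
The combination is bounded below by `max(DF, MF)` and above by `DF + MF`,
and any cell where either channel is 1 stays exactly 1.

**Score-normalization direction.** The literature similarity is
`(ST − ST_min)/(ST_max − ST_min)` by default (`direction="ascending"`),
mapping the strongest co-occurrence to similarity 1, since text-mining
scores grow with evidence. The inverted normalization
`(ST_max − ST)/(ST_max − ST_min)` is retained behind
`direction="as_printed"` because this formula also circulates in the
literature; the two differ only by orientation and the choice is surfaced,
never silent.

**Factorization.** The completed matrix is approximated as
`MDR* = MLF · DLFᵀ`, with `DLF` (|D|×|F|) and `MLF` (|M|×|F|) embedding
diseases and metabolites in a shared latent-factor space. The cost is

    L = Σ_{m,d} (MDR[m,d] − MDR*[m,d])² + (λ/2)(‖DLF‖² + ‖MLF‖²),

where the sum runs over **all** cells of the completed matrix — after
completion, zeros are genuine targets, not missing data. (Training can be
restricted to nonzero cells via `nonzero_only=True` for ablation.) The
regularizer in the reported cost is accumulated once per factor row; the
per-cell SGD update applies λ to the two visited rows, which is the standard
stochastic treatment of an L2 penalty. Both conventions are intentional and
documented here because they differ by a constant factor in how often the
penalty is counted.

**Training.** Plain SGD: each epoch visits every cell in a freshly shuffled
but seeded order and steps the two factor rows **against** the per-cell
gradient

    ∂L/∂DLF[d] = −2·err·MLF[m] + λ·DLF[d]
    ∂L/∂MLF[m] = −2·err·DLF[d] + λ·MLF[m].

Descending (subtracting the gradient) is the only sign consistent with
minimizing L; the sign is called out because recursive update formulas for
this model are sometimes printed with a `+`. Both row updates in a visit use
the pre-update values of the other row.

**Final predictions.** Cells with `mdr_init = 1` are pinned at exactly 1;
every other cell takes the reconstruction. Optional clipping to [0, 1]
never reorders cells strictly inside the clamp.

**Baselines.** `svd_baseline` replaces the factorization with a rank-k
truncated SVD of the completed matrix (same known-cell overlay); the
unregularized model is exactly `train` with λ = 0.

## Validation schemes

**Data-increment test sets.** Given two releases of the association map
(version 1 ⊂ version 2), a disease qualifies when at least one metabolite
present in both releases is associated with it in both (the detection-target
condition). Its positives are metabolites of `M1 ∩ M2` newly associated in
version 2; its negatives are metabolites of version 1 never associated with
it in either release. Three readings were genuinely open and are resolved as
follows: persisting version-1 associations are training knowledge, not test
positives (testing on training pairs would inflate AUC); negatives follow
the standard link-prediction convention above, since the scheme's original
statement does not define them; diseases with zero positives are dropped.
Per-disease positive/negative counts are always reported next to the AUC
because some diseases have a single test positive, which makes individual
AUCs coarse.

**AUC.** The probability that a random positive outranks a random negative,
ties counted one half (normalized Mann–Whitney U). Computed via
scikit-learn; an exhaustive pairwise count serves as the oracle in tests.
The mean over diseases/folds is unweighted.

**LOOCV.** One fold per known association: the pair is removed, the
**whole** pipeline is rebuilt — similarity completion and factorization,
because removing a pair changes the fill sets `D_m`/`M_d` — and the held-out
metabolite is scored against all metabolites never associated with that
disease.

## Disease-name normalization

Free-text disease names are annotated to ontology accessions through a
deterministic pipeline: lowercase; strip possessive markers; replace the
symbols `- _ , . ( )` with spaces and collapse whitespace; generate a
comma-inverted candidate ("A, B" → "B A", first comma only — multi-segment
rotations would explode the candidate space for no observed benefit); and
depluralize tokens by stripping a single trailing "s" only when the stripped
token already occurs in the vocabulary token inventory (so "diabetes" is
never mangled). Abbreviations are matched only through explicit synonym
entries — generating acronyms algorithmically would cause massive
collisions. Surface-form collisions between sources are resolved by source
priority (ontology name > ontology synonym > imported vocabulary entry via
cross-reference), then by the lexicographically smaller accession; every
collision is logged and counted, never dropped silently.

## Synthetic data generator

The generator encodes the model's core assumption — functionally adjacent
metabolites relate to the same or similar diseases — in a controllable way:

1. Non-negative ground-truth factors of rank `true_rank` are drawn uniformly
   on [0, 1]; their inner products, scaled by the global maximum, are the
   association probabilities.
2. Disease and metabolite similarities are cosine similarities of the true
   factor rows, perturbed with symmetric Gaussian noise of scale
   `similarity_noise` and clipped to [0, 1]. The metabolite similarity's
   off-diagonal is additionally min–max rescaled to span [0, 1] exactly so
   that the STITCH-style score file (`score = 150 + 750·sim`) round-trips
   bit-faithfully through the production normalization.
3. Version-2 association pairs are sampled (probability-weighted, without
   replacement, so pair counts are exactly reproducible) from the
   top-quartile probability cells; version 1 is a seeded strict subsample,
   giving the two releases the data-increment scheme needs.
4. A toy ontology/vocabulary attaches one instance of each of the five
   disease-naming phenomena (plural/possessive, special symbols,
   abbreviation, inverted order, true synonym) to the first five diseases,
   so the annotation pipeline is exercised end to end from XML free text.

Defaults — 40 diseases × 60 metabolites, rank 3, observation density 0.05,
version-2 increment 0.02, similarity noise 0.05 — give roughly 120 training
pairs and ~18–21 testable diseases, a sparsity regime comparable to curated
metabolite–disease corpora while staying desk-sized. What the generator does
**not** emulate: realistic disease-name frequency distributions, the heavy
right tail of real text-mining scores, confounded or systematically missing
annotations. Passing tests therefore demonstrate correctness of the
machinery and qualitative behaviour (completion helps ranking), not
performance claims on any real corpus.

## Numerical choices

- LFM defaults: `n_factors=20`, `reg_lambda=0.01`, `learning_rate=0.01`,
  `max_epochs=200`, `tol=1e-5`, `init_scale=0.1`. The source method states
  none of these, so its published AUCs are not numerically reproducible even
  with identical data; these defaults were chosen once for stable
  convergence on the synthetic fixtures and are all overridable.
- Initialization is uniform on `(0, init_scale/√|F|)`, seeded; the shuffle
  stream is seeded separately from the initialization stream.
- Convergence: relative epoch-cost change `|L_t − L_{t−1}|/max(L_{t−1},
  1e−12) < tol`. A non-finite cost aborts with advice to lower α.
- The SGD inner loop is JIT-compiled with numba when available, with an
  identical pure-NumPy fallback.
- Max over an empty fill set is 0 (a metabolite/disease with no known
  partner contributes nothing); missing labels in a similarity matrix align
  to zero rows.
- Degenerate coverage (no unknown cells) reports 100% with a flag instead of
  dividing by zero.
- Serialized numerics use 6 decimal places; per-disease rankings break ties
  by metabolite accession; known metabolites are excluded from rankings by
  default since evaluation scores only unknown candidates.
- Acceptance-script problem sizes: ten 40×60 generator replicates for the
  variant comparison, 120 LOOCV folds on one replicate, rank-2..4 recovery
  on 10×12 matrices — sizes chosen so the whole script reruns in seconds
  while keeping every estimate stable across seeds.

## Known limitations

- Disease semantic similarity is consumed, never computed; results inherit
  whatever biases the provided matrix carries.
- No fuzzy string matching: a disease name absent from every source synonym
  set simply does not annotate.
- The factorization has no bias terms and no implicit-feedback weighting;
  it is the plain regularized latent-factor model by design.
- LOOCV retrains the full pipeline per fold and is therefore quadratic-ish
  in corpus size; at real-corpus scale (hundreds of thousands of cells ×
  thousands of folds) it needs batching or sampling, which this package does
  not implement.
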