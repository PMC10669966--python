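# Methods

## The problem and the model

Bulk RNA-seq counts from a three-subtype liposarcoma cohort (DDLPS, MLPS,
PLPS) are screened for genes highly expressed in exactly one subtype.
Counts for gene *g*, sample *s* are modeled as negative binomial with mean
μ_gs and variance μ_gs + φ·μ_gs², where φ is the dispersion. Each subtype
is tested one-vs-rest with a conditional exact test, and the resulting
lists are cleaned with a tissue-specificity exclusion list built from a
reference expression compendium, so that genes highly expressed in many
tissues (housekeeping, broadly oncogenic) do not masquerade as
subtype-specific targets.

## Quality control

- **log-CPM** uses a library-size-adjusted prior: for sample *s* with
  library size L_s, prior p_s = prior_count·L_s/mean(L) and
  log-CPM = log2((y + p_s)/(L_s + 2p_s)·10⁶). This avoids log(0) and
  makes all-zero genes map to a constant within a sample.
- **Sample filter**: a sample is dropped when the median (over genes) of
  its log-CPM deviates relatively by more than 10% from the median of
  those per-sample medians. Medians are taken on log-CPM rather than raw
  log counts, removing library-size confounding; both the scale and the
  relative reading of "10%" are configuration options since either
  convention is defensible.
- **Gene filter**: keep genes with CPM ≥ k in at least n_min samples and
  total count ≥ 15, where k = 10/median(L)·10⁶ and n_min is the smallest
  group size. This is a documented simplification of the standard
  smallest-group expression filter; bit-compatibility with any external
  implementation is not promised — the rule above is the contract, and
  tests enforce it against brute-force re-evaluation.

## Exclusion list

Per tissue (labeled healthy or cancer), per-gene means are computed over
non-missing values, dropping genes with fewer than 6 datapoints in that
tissue. The top k = 500 genes per tissue (descending mean, ties broken by
ascending gene id for platform independence) form the tissue's top list.
A gene in the union of all top lists is *excluded* when it appears in at
most 1 healthy and at most 3 cancer top lists. Genes in no top list are
never excluded, since the list is defined as a subset of the union.

As written, the rule removes genes that are top-ranked *somewhere but in
few places*, while a ubiquitously high gene (top everywhere) survives.
That reading is implemented verbatim because it is what the procedure
states; the arguably intended complement (exclude when counts exceed the
bounds) is available as `invert=True` without any claim about intent.

## Differential expression

- **Library equalization**: counts are scaled by (geometric-mean library
  size)/(observed library size) and rounded deterministically to the
  nearest integer. Equal input sizes are returned unchanged. The exact
  test requires exchangeable samples; a mean-preserving deterministic
  rescale keeps runs reproducible (a stochastic-rounding variant was
  considered and rejected as needless nondeterminism).
- **Common dispersion**: conditional maximum likelihood. For one group of
  n iid NB(μ, φ) counts with total z, P(counts | z) is free of μ, so the
  summed conditional log-likelihood over genes and groups can be
  maximized in φ alone, bracketed on [10⁻⁶, 10] in log space.
- **Tagwise dispersion**: per gene, maximize l_g(φ) + (prior_df/2)·l̄(φ),
  where l̄ is the per-gene average conditional log-likelihood across all
  genes. Evaluated on a fixed log-spaced grid (61 points plus a fine
  cluster around the common estimate) with three-point parabolic
  refinement in log φ — deterministic and vectorized. prior_df → ∞
  recovers the common value; prior_df defaults to 10.
- **Exact test**: condition on S = S_A + S_B. Using the NB convolution
  identity (the sum of n iid NB(μ, φ) is NB with mean nμ and size n/φ),
  the two-sided p is the sum of probabilities of all splits (a, S−a) with
  probability ≤ observed×(1 + 10⁻¹⁰). This "small-p" two-sided
  convention is asserted in tests against exhaustive enumeration; some
  packages default to a doubled-tail convention instead, which differs in
  asymmetric cases.
- **logFC**: log2 of the ratio of group-mean CPM with a prior offset of
  prior_count expressed on the CPM scale via the mean library size, so
  identical groups give exactly 0 and swapping groups flips the sign.
- **Calling rule**: DEG ⇔ logFC > 1.5 and p < 0.05 and not excluded;
  records are ranked by descending logFC. Raw p-values are used for the
  call (matching the procedure being reproduced); BH-adjusted values are
  reported alongside for transparency. One-vs-rest pools the complement
  subtypes into a single group. No between-sample normalization factors
  are applied by default.

## Enrichment

One-sided Fisher exact test on the query/set overlap (hypergeometric
upper tail), BH-adjusted across the library. The background defaults to
the number of genes surviving the expression filter. Service-specific
combined scores that depend on precomputed internal rank distributions
are deliberately not replicated; p and adjusted p are both reported.

## Clinical statistics

- **H-score** = intensity (0–3) × percent positive (0–100), range 0–300.
  Quartile bins are the closed ranges (−,75], (75,150], (150,225],
  (225,300] (boundaries belong to the lower bin; fractional scores
  between printed integer bounds fall upward); the binary split is low ⇔
  h ≤ 150.
- **Pearson χ²** without continuity correction: the uncorrected statistic
  reproduces the published sex-association p = 0.016, the corrected one
  does not.
- **Fisher–Freeman–Halton**: exact two-sided p for r×c tables by full
  enumeration of all tables with the observed margins; a table counts
  toward p when its multivariate hypergeometric probability is ≤
  observed×(1 + 10⁻⁷). r×2 (and 2×c, by transposition) tables use a
  vectorized breadth-first expansion over rows; larger tables use a
  pruned depth-first recursion with an enumeration budget, beyond which a
  seeded Monte-Carlo estimator over margin-preserving random tables is
  provided. On 2×2 tables the test reduces exactly to Fisher's classical
  exact test.
- **ΔΔCt**: ΔCt = mean(target triplicate) − mean(reference triplicate);
  relative expression = 2^−(ΔCt − calibrator ΔCt). Triplicate means (not
  medians), no amplification-efficiency correction; NaN replicates are
  ignored unless a whole triplicate is missing.
- **Viability**: per-well (signal − mean background)/(mean
  background-subtracted control)·100; control mean maps to 100%.
  Treatment-vs-control comparison is a two-tailed unpaired t-test,
  pooled-variance by default with a Welch flag.
- Mann–Whitney U is exact for tie-free samples up to n = 20 per group and
  a tie-corrected normal approximation otherwise; Kruskal–Wallis is
  tie-corrected with χ² reference, with optional pairwise Mann–Whitney
  p-values Bonferroni-multiplied by the number of pairs and capped at 1.

## Synthetic data: what it emulates and what it does not

The count generator emulates a 53/54/24-sample three-subtype design:
gene-wise relative expression 2^b with b ~ U(3, 8), library sizes
log-uniform in [5·10⁵, 2·10⁶] (exercising CPM normalization), a single
dispersion φ = 0.1 (a typical bulk-tissue value), and planted genes whose
mean is multiplied by 2^effect in one subtype. It does *not* emulate
gene–gene correlation, gene-wise dispersion trends, batch structure, FFPE
degradation, or composition effects — a green recovery test therefore
establishes correctness of the inference machinery under the stated NB
model, not robustness to those real-data features.

The compendium generator produces continuous expression scores (the
exclusion-list procedure needs only per-tissue means and ranks, not
counts): a shared per-gene baseline N(5, 1), housekeeping genes offset
+10 everywhere, tissue-specific genes pinned 6 SD below baseline except
in their designated tissues, per-sample noise SD 0.25. Tissue sample
counts may fall below 6 to exercise the datapoint filter. Scale defaults
(95 healthy/106 cancer tissues) match the reference compendium's tissue
counts; tests use smaller compendia for speed.

IHC, qPCR and viability generators are constructed so that zero-noise
round trips are exact: the qPCR target Ct is reference Ct + calibrator
ΔCt − log2(true relative expression); viability wells are background +
control signal × effect, eight replicate wells per treatment.

## Numerical choices and degenerate inputs

- Dispersion search range [10⁻⁶, 10]; constant within-group counts drive
  the estimate to the lower bound.
- Exact-test ties use relative tolerance 10⁻¹⁰ (10⁻⁷ for the FFH test),
  protecting against floating-point asymmetry in symmetric tables.
- Zero library sizes, empty groups, subtypes without replication,
  all-NaN triplicates, non-positive background-subtracted controls, and
  constant vectors in correlations all raise errors naming the offender.
- Everything randomized is a pure function of an explicit integer seed;
  no global RNG state is touched.

## Known limitations

- The exact test is implemented only for the pooled one-vs-rest contrast;
  no GLM/quasi-likelihood framework.
- The exclusion-list rule's verbatim reading (see above) retains
  ubiquitously high genes; use `invert=True` to explore the complement.
- Survival analysis is out of scope.
- The FFH enumeration is exponential in table size; beyond the budget the
  Monte-Carlo estimator must be used.
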