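# Methods

## Problem setting

Targeted multiplex-PCR panels (for example a 46-gene hotspot panel with 189
primer pairs sequenced to ~2400x) summarize each amplicon by its mean read
depth. Depth is roughly proportional to the underlying copy number, but the
proportionality is distorted by two systematic biases: a *region effect*
(per-amplicon PCR efficiency, driven by GC content, length and sequence
complexity) and a *sample effect* (DNA input, library size, batch). Matched
normals are often unavailable for archival tumor material, so both biases
must be learned from a pool of unpaired normal controls.

## Model

All modeling is on log2 depth, which stabilizes the variance of depth
across its mean.

**Step 1 — control baseline.** For control depths `y_ij` (region `i` of `m`,
control `j` of `k`):

```
log2(y_ij) = mu_N + alpha_i + beta_j + e_ij,   e_ij ~ N(0, sigma_N^2)
```

with sum-to-zero constraints on `alpha` (region effects) and `beta` (sample
effects), so `mu_N` is the overall log2 control mean and `mu_N + alpha_i`
is the basal depth of region `i`. The design is balanced and complete, so
the constrained least-squares solution is closed-form: `mu_N` is the grand
mean, `mu_N + alpha_i` the row means, `beta_j` the column means minus the
grand mean. The implementation uses these closed forms; the test suite
verifies them against a generic constrained normal-equations solve and a
reference-level reparameterization (fitted values agree to 1e-10).
`sigma_N` is computed on `(m-1)(k-1)` degrees of freedom and kept as a fit
diagnostic only.

**Step 2 — tumor correction and residuals.** Tumor depths are
baseline-adjusted, `z_ij = log2(y_ij) - mu_N - alpha_i`, and a per-tumor
sample effect is absorbed:

```
z_ij = mu_C + beta_j + e_ij
```

The residual `eps_ij = z_ij - mu_C - beta_j` equals `log2(y_ij / yhat_ij)`,
the log-ratio of observed to model-expected depth — the relative
copy-number signal. Because `beta_j` absorbs each tumor's column mean,
residuals sum to zero within every tumor, and the calls are invariant to
rescaling any one tumor's depths (or rescaling one region jointly in
controls and tumors).

**Standardization and calling.** Residuals are divided per region by their
own sample SD `S_i` (ddof = 1) to make regions comparable. An amplicon is
called `AMP` when its adjusted residual exceeds the overall mean of *all*
adjusted residuals by more than `gamma` overall SDs, `DEL` symmetrically
below; default `gamma = 1.5`. The reference point is deliberately the
overall mean rather than per-region means: recentering each region would
overcorrect regions that are recurrently altered across the cohort.
Raising `gamma` strictly shrinks the altered-call set.

## Gene-level summary and consistency score

A gene's call in a sample is the majority state among its altered amplicons
(`AMP` if more amplicons are AMP than DEL and at least one is AMP; `DEL`
symmetrically; ties and all-normal genes are `NORMAL`). The tie rule is a
conservative no-call.

The consistency score of a (gene, sample) pair is `c = N_c / N_a`, where
`N_a` is the number of altered amplicons in the gene and `N_c` the number
of altered amplicons with at least one *adjacent* amplicon (in within-gene
panel order) in the same altered state. Adjacency is panel order, not
genomic distance: hotspot panels are sparse, and order is the only robust
neighbor relation. AMP next to DEL is inconsistent. The score is undefined
for single-amplicon genes and when `N_a = 0`; the cohort average is the
unweighted mean over all defined (gene, sample) pairs. A true whole-gene
event yields `c = 1`; isolated false calls yield low scores, so the cohort
average is a calibration check on `gamma`.

## Evaluation statistics

* **Accuracy** against a truth (or orthogonal-platform) matrix is the
  fraction of matching gene x sample cells, with one-vs-rest sensitivity
  and specificity per state.
* **Occurrence rate** is the per-sample fraction of panel genes called
  altered.
* **Call frequency** counts, per gene, the samples called AMP and DEL,
  sorted by total altered count (ties alphabetical).
* **Control QC**: mean pairwise Pearson correlation of control log2-depth
  profiles (the model's scale) and the mean per-region coefficient of
  variation of *raw* depths across controls (CV conventionally refers to
  the raw scale).
* **Concordance index**: a pair of patients is comparable when their
  times differ and the earlier time is an observed event; the pair is
  concordant when the earlier-event patient has the higher predicted risk;
  tied risks count 1/2. Pairs whose earlier time is censored, and
  tied-time pairs, are excluded — the standard reading of "all possible
  pairs" under right censoring. The implementation is cross-checked in the
  tests against an independent brute-force pair enumeration and against
  `lifelines`.

## Synthetic-data generator

The generator draws per-amplicon log2 depth as

```
log2(y_ij) = log2(mean_depth) + alpha_i + beta_j + log2(effective_CN_ij / 2) + N(0, noise_sd)
```

with `alpha ~ N(0, region_effect_sd^2)` shared by controls and tumors,
`beta ~ N(0, sample_effect_sd^2)` per sample, and
`effective_CN = purity * CN + (1 - purity) * 2` for tumors (controls are
diploid). With zero noise, a clonal CN=4 amplicon sits exactly one log2
unit above baseline, matching the depth-proportionality assumption.

Defaults and rationale:

| parameter | default | why |
|---|---|---|
| `n_genes` / `n_amplicons` | 46 / 189 | hotspot-panel scale |
| `n_controls` / `n_tumors` | 16 / 100 | unpaired PBMC control pool; cohort batch |
| `mean_depth` | 2443 | ultra-deep targeted coverage |
| `region_effect_sd` | 0.5 log2 | realistic multiplex-PCR efficiency spread (~1.4x typical fold) |
| `sample_effect_sd` | 0.01 log2 | near-uniform library loading across samples (see below) |
| `noise_sd` | 0.0289 log2 | targets control per-region CV ~= 0.02: CV ~= noise_sd * ln 2 |
| `cna_gene_fraction` | 0.2 | per-(gene, tumor) event probability |
| `amp_copy` / `del_copy` | 4 / 1 | one extra copy pair gained / one copy lost |
| `purity` | 1.0 | clonal events; lower values attenuate shifts toward 0 |
| `partial_gene_prob` | 0.0 | whole-gene events; partial events take a contiguous prefix/suffix (one breakpoint inside the gene) |

The per-region CV of control depths mixes noise with inter-sample library
spread, so the CV ~= 0.02 uniformity condition pins `sample_effect_sd` to a
small value; the model removes sample effects exactly regardless of their
size, and the invariance tests scale samples by up to 50x explicitly. Noise
is Gaussian on the log2 scale rather than Poisson/negative-binomial at the
count level: at ~2400x coverage counting noise is negligible against PCR
variability. Simulating reads, alignment artifacts or FFPE damage is out of
scope, so passing recovery tests demonstrate correctness of the
normalization and calling machinery under the stated generative model, not
robustness to artifacts the generator does not produce.

One seed drives panel layout, region effects, sample effects, events and
noise through independent substreams, so e.g. the panel is identical across
configs that differ only in noise.

## Numerical choices

* **Zero depths**: `log2(0)` is undefined; a configurable pseudocount
  (default 0.5) is added to zero cells only, with a warning listing them.
  Positive depths are never modified.
* **Zero-variance regions**: per-region SDs below `min_sd` (default 1e-8)
  are flagged and the region's adjusted residuals are set to exactly 0, so
  pure floating-point roundoff can never be amplified into calls. This also
  makes the zero-noise null simulation produce all-NORMAL calls
  deterministically.
* **Constant residual matrices**: the overall mean/SD short-circuit to the
  exact constant and 0, avoiding `np.std` roundoff at the 1e-16 level
  producing spurious thresholds.
* **SDs** use the unbiased (n-1) denominator throughout.
* **I/O**: floats are written with full `repr` precision and parsed with
  round-trip-exact parsing, so write/read cycles (including the persisted
  control baseline) are bit-exact. Run manifests contain parameters and
  input checksums but no timestamps, so identical runs are byte-identical.

## Problem sizes

The test suite and the acceptance script run the full default-scale design
(189 amplicons, 16 controls + 100 tumors) plus smaller fixtures; a complete
run takes well under a minute on one CPU.

## Known limitations

* Calls are relative, per-region states; no absolute copy number,
  purity/ploidy estimation, or segmentation across amplicons.
* The control pool must resemble the tumors' assay (same panel, chemistry);
  cross-batch harmonization beyond the per-sample effect is not attempted.
* Very high event recurrence at one region inflates that region's residual
  SD and dampens its adjusted residuals (sensitivity loss); the overall-mean
  reference mitigates but does not remove this.
* The concordance index assumes non-informative censoring within comparable
  pairs.
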