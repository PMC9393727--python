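# Methods

## Statistical model

### RNA level

Counts are library-size normalized: CPM_gj = c_gj · 10⁶ / Σ_g c_gj.
FPKM_gj = c_gj · 10⁹ / (L_g · Σ_g c_gj) is computed for reporting; all
testing runs on x_gj = log2(CPM_gj + 1) (pseudocount 1, configurable).
For each contrast, a per-gene Welch two-sample t-test compares the
treatment and control groups of x; Welch is the default because RNA-seq
group variances are rarely equal at n = 3. Fold changes are reported as
log2((mean CPM_B + pc)/(mean CPM_A + pc)) — a ratio of group means with
the same pseudocount, so constant genes give exactly log2FC = 0.
P-values are BH-adjusted (statsmodels `fdr_bh`); a gene is "up" iff
log2FC > 1 and FDR < 0.05, "down" iff log2FC < −1 and FDR < 0.05.
Inequalities are strict: values exactly on a threshold are not called.
Replicate quality is the minimum pairwise Pearson correlation of x
within a group; pairs involving a constant column are flagged as
undefined rather than propagated as NaN.

### Protein level

Student's t (equal variances pooled; configurable to Welch) on log2
intensities, NaNs omitted. A protein is "quantified" for a contrast
when both groups have ≥ 2 non-missing values; BH adjustment runs over
quantified proteins only. "Up" iff fold change > 1.5 and q < 0.05,
"down" iff fold change < 1/1.5. The q-value here is the BH-adjusted
p-value (not Storey's q); the names follow common proteomics usage.

### Association and screen

Nine-quadrant assignment uses strict inequalities against ±1 (RNA,
log2) and ±log2(1.5) (protein, log2): column index 0/1/2 for RNA
down/middle/up, row index 0/1/2 for protein up/middle/down, quadrant =
3·row + column + 1. Exactly-threshold values land in the middle band.
Quadrants 3 (both up) and 7 (both down) are the concordant corners; a
pair is "significant" in the quadrant counts when it is independently a
DEG and a DEP.

The screen statistic is Δ = log2(FC_treatment-genotype / FC_control-
genotype) of the within-genotype stress fold changes, computed at the
RNA and the protein level. A gene passes iff |Δ| > 1 strictly at either
level; Δ is NaN (never passes) when a fold change is missing or
non-positive. Two candidate pools are supported: `quadrant37`
(concordant, doubly significant genes in either genotype — the
conservative, biology-first pool) and `all` (every matched gene — used
when benchmarking recovery against planted truth). The choice is a
configuration field, not a hidden default switch.

### Enrichment

For a feature set of size n drawn from a background of size N with K
term members, the p-value is the exact hypergeometric upper tail
P(X ≥ k) via `scipy.stats.hypergeom.sf(k−1, N, K, n)`. Terms with at
least one hit are tested and BH-adjusted together. The direction
z-score is (n_up − n_down)/k over the hit's member directions. Top-20
reports sort by adjusted p, then raw p, then term ID (stable sort).

## Numerical choices

- BH is delegated to `statsmodels.stats.multitest.multipletests` and
  cross-checked in the tests against an independent step-up oracle.
- t-tests are delegated to `scipy.stats.ttest_ind` and cross-checked
  per gene against the closed-form statistic.
- The hypergeometric tail uses `sf(k−1, …)`, never `1 − cdf`, to avoid
  cancellation for small p; tests verify exact agreement with
  exhaustive enumeration for N ≤ 30.
- Thresholds are compared with strict `>` / `<`; no epsilon fuzzing.
  Published-style two-decimal rounding is applied only at the reporting
  layer, never before a comparison.

## Synthetic-data generator

`simulate_experiment(SimConfig)` produces a dataset with a complete
truth table. Defaults: 2,000 genes, 60% with a matched protein, 3
replicates per group, sequencing depth 10⁶ (per-sample library factor
uniform in [0.85, 1.15]), NB dispersion 0.1, protein CV 0.2, 20% DE
genes per genotype, planted |log2FC| in [1.5, 4], 5% differential-
response genes (planted |Δ| in [1.5, 3]), 50 annotation terms of which
20% are enriched in screen genes.

- RNA counts are negative binomial with mean μ = w_g · lib_j · 2^(e_gj)
  and shape r = 1/dispersion (p = r/(r + μ)); gene weights w_g are
  log-normal.
- Protein intensities are log-normal around a base intensity with the
  planted protein effect applied multiplicatively; protein effects are
  concordant with RNA (70%), null (15%) or independent (15%).
- Differential-response genes alternate between "responds in the
  overexpressor only" and "responds in both genotypes by amounts
  differing by the planted Δ".

**Mass-balanced effect signs.** Planted log2 effects e with uniform ±
signs inflate the expected treated-library mass because E[2^e] > 1
(Jensen's inequality); under per-library CPM normalization that shifts
every *null* gene's apparent fold change down by ~0.6 log2 units at
default settings, so the generator would contradict its own truth
table. Each planted effect's sign is therefore drawn up with
probability 1/(2^|e| + 1), which makes E[2^(s·e)] = 1 exactly: treated
and control libraries have equal expected mass and null genes stay
null after normalization. A consequence — consistent with real stress
transcriptomes — is that large planted effects are predominantly
downregulation. This is a design property of the generator, not a
tuning knob; the differential-response deltas and all magnitudes are
unaffected.

### What the generator does and does not show

Passing the recovery invariants (sensitivity ≥ 0.8 / specificity ≥ 0.9
for the screen, planted terms top-ranked) shows the pipeline's
estimators and decision rules are consistent under the generator's own
assumptions: NB counts with gene-wise constant dispersion, log-normal
proteins, independent genes, no batch structure, no isoform- or
peptide-level ambiguity. It does **not** validate performance on real
data, where composition shifts, correlated genes, heavy-tailed protein
noise and mapping ambiguity all degrade the simple t-test/CPM stack.
The generator is a correctness harness, not a benchmark.

## Reference table fixture

The bundled 36-gene table stores fold changes to two decimals; missing
cells ("\\") and the typographic minus are normalized on ingest. Its
printed Δ columns were derived from unrounded folds, so recomputation
from the two-decimal folds can only be expected to land inside the
rounding halo [log2((f₂−0.005)/(f₁+0.005)), log2((f₂+0.005)/(f₁−0.005))].
Five of 35 printed RNA deltas and two of 36 protein deltas fall outside
even that halo (transcription inconsistencies in the source table);
tests freeze those counts rather than loosening tolerances. The screen
itself always recomputes Δ from the fold columns.

## Limitations

- CPM/FPKM normalization is composition-sensitive; strongly asymmetric
  regulation in real data biases null genes' fold changes (see the
  mass-balance note above). Median-of-ratios or TMM normalization
  would be the production-grade fix and is out of scope here.
- Gene-wise t-tests at n = 3 have limited power and unstable variance
  estimates; empirical-Bayes moderation (limma/DESeq2-style) is not
  implemented.
- The BH "q-value" controls FDR under independence/PRDS; no effort is
  made to handle arbitrary dependence.
- One-to-one gene→protein mapping is assumed; a gene mapping to
  multiple proteins is rejected rather than resolved.
- Enrichment treats annotation terms as independent; no term-hierarchy
  pruning.
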