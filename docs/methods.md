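# Methods

This note documents the statistical model behind each step of the pipeline,
the defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical/design choices made where the
published description of this kind of analysis leaves room.

## Fingerprint processing

**Peak validity.** A peak is a valid transcript-derived fragment if its
height is ≥ 50 RFU (inclusive) and its called size lies in [75, 500] bp
(inclusive). 50 RFU is the conventional capillary-electrophoresis detection
floor separating fragments from background fluorescence.

**Binning (±2 bp).** Sizing error across runs means the same fragment is
called at slightly different sizes. Peaks are binned per primer combination
by single-linkage chaining over the sorted sizes, starting a new bin
wherever the gap between consecutive sizes exceeds the tolerance (2 bp).
This is deterministic and independent of input row order; the bin's
representative size is the median of its member sizes. Within one run, two
peaks falling into the same bin collapse to the taller one (the shorter is
assumed to be shoulder noise). Single linkage can in principle chain a bin
wider than ±2 bp around the representative; with well-separated true
fragments (the generator enforces ≥4 bp spacing) this does not occur.

**Sum-of-signal normalization.** Each run's intensities are multiplied by
(grand mean of per-run totals) / (that run's total), so all totals equal the
grand mean and the grand total is conserved. The choice of target constant
is immaterial downstream — every F statistic is invariant to a common
rescaling — the grand mean merely keeps values on the familiar RFU scale.

**Shared-transcript rule.** A transcript enters the ecotype comparison only
if present in ≥ ceil(f · n_runs) of all runs, biological and technical
pooled, with f = 0.90 by default ("at least 90%" is a lower bound, hence the
ceiling). The rule is applied globally, not per primer combination. A
stricter f keeps a subset of a looser f's panel.

**Technical-replicate imputation.** Per biological replicate: if a
transcript is detected in every technical run, its value is the mean; if
detected in some runs only, missing runs are set to the 50-RFU detection
limit before averaging (the peak was presumably just under the floor); if
detected in none, the transcript stays absent for that pool — absence is
evidence, not a missing value, and is not imputed.

**Reproducibility.** For each technical pair, the simple-matching
coefficient (both-present + both-absent over all transcripts) summarises
presence/absence agreement, and the Pearson correlation of jointly present
intensities summarises quantitative agreement. Absent is not zero in
fingerprint data, so absent cells are excluded from the correlation; pairs
with fewer than 3 jointly present transcripts are flagged undefined and
excluded from the mean. An optional per-pair randomization p-value uses the
shared permutation engine.

## Differential expression

**Nested ANOVA.** The design is 2 ecotypes × 2 transects (fixed), r
biological replicates (pools) nested in each ecotype×transect cell
(random), t technical replicates as residual. Sums of squares are computed
from cell/marginal means; the partition SS_total = SS_E + SS_T + SS_E×T +
SS_rep(E×T) + SS_residual is exact on every balanced input. Fixed effects
are tested against MS_rep(E×T) and the nested replicate against the
technical residual — the standard expected-mean-squares convention when the
nested factor is random; testing fixed effects against the residual would
confuse pool-to-pool variation with technical noise. Unbalanced designs are
rejected rather than approximated. A zero denominator with a positive
numerator is reported as F = ∞ with the below-machine p sentinel
(`np.finfo(float).tiny`); 0/0 is NaN (undefined, flagged). Cells still
absent at this stage are filled with the 50-RFU detection limit,
consistent with the imputation rule.

**Randomization ANOVA.** The permutation unit is the biological replicate
(technical replicates averaged first); ecotype labels are permuted freely
across transects. The p-value uses the add-one estimator
(1 + #{F* ≥ F}) / (B + 1), ties counted as exceeding — a valid, never-zero,
slightly conservative p. Default B = 10,000. Under a true null the test is
calibrated: the acceptance suite verifies a 5% ± 1.5% rejection rate at
γ = 0.05 over 1,000 null transcripts.

**Summary-statistic F.** For two groups of equal size n the one-way ANOVA F
collapses exactly to (m₁ − m₂)² / (SE₁² + SE₂²); this identity (tested
against raw-data F on random inputs) lets published group summaries be
converted back into test statistics.

**SGoF.** With n p-values and R = #{p ≤ γ}, the metatest asks whether R
exceeds its Binomial(n, γ) expectation, one-sided and exact. While the
metatest on the current count is significant at γ, one more smallest
p-value is declared and the count decremented; n is held fixed across
iterations. This is the conservative small-n variant; an asymptotic G-test
variant is available (`method="gtest"`) because historical implementations
differ, and the historical software's exact iteration rule is not published.
Correction is applied to the ecotype p-values only — the contrast of
interest. Consequences tested: declared p-values are always the smallest;
nothing is declared when R ≤ nγ; adding a sub-threshold p never decreases
the declared count.

## Clustering

Profiles are compared with the uncentered correlation distance
d = 1 − Σxᵢyᵢ/(‖x‖‖y‖) (cosine-type, no mean-centering, range [0, 2],
scale-invariant per profile) and clustered by average linkage (UPGMA), via
`scipy.cluster.hierarchy.linkage` on the condensed distance matrix; the
suite checks the result against an exhaustive-merge oracle on all small
instances. scipy's deterministic nearest-neighbor-chain order stands in for
an explicit tie-break rule; exact distance ties have measure zero for
continuous intensities. Merge heights are verified non-decreasing
(average linkage is monotone) and exported as Newick branch lengths
(parent height − child height; trees are ultrametric).

By default distances are computed on untransformed normalized intensities.
For the heat-map style sample clustering (the analysis that asks whether
pools group by ecotype using only the significant transcripts) the options
`log2=True, center=True` are used: log₂ first, then subtracting each
transcript's mean across samples. Untransformed cosine distances are
dominated by the few highest-baseline transcripts — intensities span orders
of magnitude — and carry almost no group signal; log + per-transcript
centering is the standard expression-heat-map preprocessing (it is what
desktop clustering tools apply before drawing red/green maps) and makes
every transcript contribute comparably. Absent cells are filled with the
detection-floor value before transformation.

## qPCR / geNorm

**Relative quantities.** RQ = E^(Cq_min − Cq), anchored at the per-gene
minimum Cq (max RQ = 1). The anchor cancels in every ratio-based statistic
— verified exactly for per-gene Cq shifts — so the convention is cosmetic.
Efficiency defaults to the theoretical 2.0 (perfect doubling), overridable
per gene; values must lie in (1, 2].

**Stability.** V_jk is the n−1 standard deviation over samples of
log₂(RQ_j/RQ_k); M_j is the mean of V_jk over the other panel genes.
Because a per-sample loading factor multiplies all genes alike, it cancels
in every within-sample ratio — M is exactly invariant to per-sample
rescaling, which is the entire point of ratio-based stability. Ranking
proceeds by stepwise exclusion of the highest-M gene (ties broken by gene
name for determinism) until two genes remain; the final pair is unordered —
with only ratios available the two cannot be distinguished. A full-panel
M ≥ 1.5 flags a gene as unsuitable for normalization. Missing Cq values are
handled pairwise-complete.

**Reference count.** NF_n is the per-sample geometric mean of the n most
stable genes' RQs; V_n/n+1 = SD(log₂ NF_n/NF_n+1). The smallest n with
V_n/n+1 < 0.15 is recommended; if none qualifies, all genes are used with a
warning (the threshold is a guideline, not a law).

**Target-gene comparison.** NRQ = RQ_target / NF over the chosen
references; ecotypes are compared by the same randomization one-way ANOVA,
with the direction (which ecotype is higher) and the geometric-mean ratio
reported. NRQ values are left unscaled (no rescaling to the mean); a
between-day reproducibility check (Pearson r on raw Cq with a
randomization p) is provided for technical validation.

## Synthetic data

**Fingerprints.** log₂(RFU) = baseline_t + effect_t·1[SU] + b_pool +
ε_run, with baselines N(9, 1.5²) (≈512 RFU median, spanning the dynamic
range), pool effects N(0, sd_bio²) shared by a pool's technical runs, and
run noise N(0, sd_tech²). Peak heights are log-normal — positive,
multiplicative noise, matching electrophoresis signal behaviour. A peak
below the 50-RFU floor is absent (hard truncation, not clipping), which is
what creates realistic presence/absence structure. Fragment sizes get
N(0, 0.15²) bp sizing jitter; true sizes are kept ≥4 bp apart so ±2 bp
binning cannot merge distinct transcripts (co-migration homoplasy is
deliberately out of scope). The default design is the study's: 2 ecotypes ×
2 transects × 8 pools × 2 technical runs (64 runs); 99 transcripts of which
12 carry a ±1.5 log₂ effect (≈2.8×, the middle of the reported 2–4× range),
3 of 4 up-regulated in SU.

Variance defaults (sd_bio = 0.6, sd_tech = 0.5) were chosen once so that
2–4× effects are reliably detectable with 16 pools per ecotype and pools
cluster by ecotype — the regime the published analysis demonstrably operated
in. They imply technical-replicate Pearson correlations around 0.85–0.9,
cleaner than the noisiest fingerprint studies report (~0.73); raising
sd_tech to 0.8 reproduces that figure but leaves the clustering property
marginal. What passing tests show is therefore that the *pipeline* recovers
truth under the stated signal-to-noise regime — not that any particular
real dataset occupies that regime. The generators also do not emulate
restriction-site biology, primer selectivity, dye effects or co-migration
of non-homologous fragments.

Randomness uses one `SeedSequence` split into a truth stream plus one
stream per biological replicate (technical noise drawn from the pool's
stream), so output is reproducible and independent of iteration order.

**Cq tables.** Cq_gs = a_g − (log₂Q_s + f_gs + effect)/log₂E +
N(0, cq_noise_sd²), with per-gene base levels a_g ~ U(18, 26), a shared
per-sample loading factor Q_s (log₂ sd 0.5) that cancels in all ratio
statistics, gene instability noise f_gs with sd 0.05 (stable references,
4 genes) or 0.5 (unstable, 2 genes), and a 1-log₂ SU effect on the gene of
interest. 9 biological replicates per ecotype, E = 2, technical Cq noise
0.2 cycles.

A note on recovery precision: with 0.2-cycle technical noise and 9
replicates per group, the geometric-mean NRQ ratio estimator has a sampling
sd of ≈0.117 log₂ units (floor 0.094 from the target gene's own noise even
with perfect references), so single runs land within ±10% of the true ratio
only ~80% of the time — a sampling-theory limit of the design, not an
estimator defect; the estimator is unbiased (mean recovered ratio 2.01
over 100 runs) and the direction + significance of the effect is recovered
in 100/100 runs.

## Numerical conventions

- Standard deviations use the n−1 denominator throughout (geNorm's
  published convention; SE of group means likewise).
- TSV output uses 12 significant digits so read/write round-trips are
  lossless to ≤1e-9 relative (6 digits would be prettier but lossy); JSON
  keeps full precision. Writers sort keys and fix float formatting, so
  identical inputs give byte-identical files.
- Missing values in inputs are an empty cell or `NA`, nothing else.
- Permutation engines accept either an integer seed or a shared
  `numpy.random.Generator`, so multi-transcript scans draw from one stream.

## Known limitations

- Binary electropherogram (.fsa) parsing and chromatogram peak calling are
  out of scope; input is peak tables.
- The nested ANOVA requires a balanced design (as in the study); there is
  no Type-II/III or REML machinery for unbalanced data.
- Homoplasy (co-migrating non-homologous fragments) is not modelled or
  detected; the study resolved it by cloning and sequencing.
- The SGoF variant used by the historical freeware is not fully specified;
  counts near the decision boundary can differ by one or two declarations
  between variants.
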