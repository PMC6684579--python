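# Methods notes

## Scope and data model

`tritrend` starts *after* peptide identification and protein roll-up: its
unit of input is a protein × sample abundance matrix per quantification
channel (MS1 intensity; spectral count), with a design sheet assigning each
sample a condition in {H, NL, L}, a replicate/pool identifier and a channel.
The emulated design is three replicate experiments per condition, each
replicate a pool of three donors; the replicate (pooled experiment) is the
experimental unit throughout — donor-level variation inside a pool is not
modelled and cannot be recovered from pooled data.

Assumptions: intensities are approximately log-normal within a condition
(so log2 intensities are Gaussian and the moderated t applies); spectral
counts are overdispersed counts; samples are independent across replicates;
missingness is unrelated to abundance (see limitations).

## Composite differential expression

**Fold change.** FC = mean(numerator)/mean(denominator) on the raw scale,
matching how ratio-scale fold changes are reported in this field. A
pseudocount (default 0.5) is added to *both* group means only when at least
one of them is exactly zero — well-measured ratios are therefore exact, and
all-zero groups yield a finite, shrunken ratio instead of 0 or ∞. Proteins
with fewer than `min_obs = 2` observed values in either group are reported
untested (missing FC and p); with n = 3 replicates this keeps at least a
rudimentary variance estimate behind every tested protein.

**Moderated t.** The prior (d₀, s₀²) is fit by the standard method of
moments on log sample variances: with e_g = log s²_g − ψ(d_g/2) + log(d_g/2),
the excess of var(e) over mean ψ′(d_g/2) equals ψ′(d₀/2), solved by Newton
iteration on the trigamma function; s₀² follows from mean(e). When the
excess is non-positive the variances are consistent with one common value:
d₀ = ∞ and s₀² is the arithmetic mean of the sample variances (their common
MLE) — in particular, identical variances v return exactly (∞, v). Zero
variances are excluded from the fit; if *all* variances are zero the fit
refuses with an instruction to add replicate noise or use an ordinary t.
The statistic uses s̃²_g = (d₀s₀² + d_gs²_g)/(d₀ + d_g) with reference
distribution t(d_g + d₀); d₀ = 0 reduces exactly to the pooled two-sample
t, and d₀ = ∞ uses the standard normal (the exact infinite-df limit; this
is the one place the implementation deliberately differs from Bioconductor
limma, which caps the total df at the pooled residual df — agreement with
limma is to machine precision whenever d₀ is finite, and this is asserted
in the test suite against `limma::eBayes` run through Rscript). Counts
enter the same machinery after log2(x + 0.5) variance stabilization.

**Rank product.** Within each replicate, proteins are ranked by their
within-replicate log2 fold change (descending for up-regulation, ascending
for down; ties get average ranks; replicates missing a protein simply do not
contribute a rank for it). RP is the geometric mean of the available ranks.
The null permutes each replicate's rank column independently; the p-value is
the null probability of an RP at or below the observed one. Because a
uniformly random column permutation makes a protein's null rank a uniform
draw from that column's rank multiset, the per-protein null is the product
distribution over the observed columns — the implementation enumerates it
exactly when its size (product of observed column sizes) is ≤ 10,000, and
otherwise samples it with B Monte Carlo draws (B ≥ 100 enforced; default
1,000) using the add-one estimate p = (b+1)/(B+1). The Monte Carlo null is
drawn once per missingness pattern from the *sorted* column values and
shared across proteins, which makes p-values invariant to protein row order
and to any reordering of equal inputs; comparisons use a 1e-9 tolerance on
log RP to make tied rank products count as "at or below". A two-sided p is
obtained by running both directions with the same seed and
Bonferroni-doubling the smaller tail (capped at 1), so reversing a
contrast's numerator and denominator leaves every p unchanged and inverts
every fold change exactly.

**Composite rule.** DE ⇔ (min available p < α) and (FC ≥ τ or FC ≤ 1/τ),
α = 0.05, τ = 2.0. The p-values are used raw, as in the emulated analysis;
BH q-values per channel are emitted for information only. "Three tests"
is a configuration: moderated t on intensities, moderated t on log counts,
rank product on intensities — spanning both named approaches and both
quantification readouts; any subset can be disabled, and skipped channels
are recorded in the output metadata.

## Trend taxonomy

With T = log2 τ, the flags are computed from the three composite DE calls
and the three log2 fold changes (see README for the table). Two boundary
conventions matter and are fixed deliberately: the DE fold gate is
*inclusive* (≥ τ, "at least two-fold or higher") while the within-band
comparison is *strict* (< τ, "less than two-fold"), so a fold change of
exactly τ is DE-eligible but never "similar". `sign()` treats
|log2FC| < 1e-9 as zero, and zero-sign proteins cannot be `group_III`.
Flags whose inputs are missing are reported missing rather than guessed;
the flags are not mutually exclusive by design — the published group lists
themselves overlap (ITGA7 and PLVAP fit both the NL-characteristic and the
opposite-direction pattern), so a single exclusive label would misrepresent
the taxonomy. `unclassified_divergent` catches L-vs-H DE proteins fitting
none of the named patterns (typically very large lesional changes with NL
partway but more than two-fold from both ends, like AKR1B10's 32.8×/25.3×
pattern).

## Synthetic data generator

The generator emulates the study design so every stage can be scored
against planted truth: per protein a trend class is drawn
(defaults: 30% null, 40% intermediate, 7.5% each for the other four), a
random direction is chosen, and condition means are set on the log2 scale —
null H=NL=L; lesion-only H=NL, L shifted by `effect_log2fc`; intermediate
L shifted, NL at `intermediate_position` (default 0.5) of the H→L span;
group I NL=L shifted; group II NL shifted, H=L; group III NL and L shifted
by ∓`effect_log2fc`/2 (the total split symmetrically, since only orderings,
not magnitudes, are specified for this pattern). Intensities add Gaussian
replicate noise on the log2 scale (`noise_sd_log2`, default 0.3 — chosen as
a conventional within-group CV of ~20–25% for label-free pooled replicates,
and documented as a convention because the emulated study's true
within-group variance is not recoverable from its text); protein baselines
spread around `base_abundance` = 16 log2 units with SD 1.5. Spectral counts
are negative-binomial with mean `count_scale`·2^(relative abundance)
(default mean 20 for a baseline protein) and size `count_dispersion` = 5 —
low-replicate, overdispersed counts. Missingness is completely at random at
rate `missing_rate`. Identical configs (including seed) give byte-identical
matrices.

`truth_to_expected_flags` maps planted true log2 fold changes to the flags
the classifier would emit with unlimited replicates: any nonzero effect
reaches p → 0, so expected DE reduces to the inclusive fold gate
|log2FC| ≥ T, and the trend predicates are then applied *via the same code
path* as the real classifier.

**Boundary effect worth knowing about.** At the default
`effect_log2fc` = 2.0 and `intermediate_position` = 0.5, a planted
"intermediate" protein has true |log2FC(NL/H)| = |log2FC(NL/L)| = 1.0 —
*exactly* the two-fold boundary. Under the strict band it is therefore not
expected-intermediate (it is expected DE in all three contrasts), and any
finite-replicate estimate falls on either side of the boundary with roughly
equal probability. More generally the intermediate band is geometrically
squeezed: it requires |log2FC(L/H)| < 2T while the DE gate requires ≥ T, and
with replicate noise σ per log2 fold-change estimate
(σ = noise_sd_log2·√(2/3) ≈ 0.245 at the defaults) no planted placement
satisfies both with high probability. Recovery experiments at these
defaults consequently show near-perfect recovery for the DE calls and the
group II/III patterns on their own classes, but unstable intermediate
labels — which is a faithful property of the two-fold taxonomy at this
noise level, not an estimator defect. Passing recovery tests on planted
classes far from the boundary says nothing about classification stability
near it.

## Enrichment

Upper-tail hypergeometric p per term, P(X ≥ k) with X ~
Hypergeom(N, K, n), where the background N is the set of proteins
quantified in the run — the only defensible null universe for a
detection-limited proteome — and term sizes are computed after intersection
with it; terms outside [3, 500] members are dropped and counted. BH
q-values across retained terms; rows sorted by p, ties broken by term id.
Categories (e.g. development / proliferation / expression / response to
stimulus) are taken from the annotation file's description field, never
inferred. The four-process central-regulator screen is a plain intersection
of the DE set with exactly four named process sets. No network-aware
statistics are attempted.

## Pipeline and reproducibility

Per-sample total-sum normalization (each column's observed sum scaled to
the across-column median of sums; `none` available for pre-normalized
inputs) precedes testing; an all-missing column is a hard error naming the
sample. Normalized count matrices are allowed to be fractional (the
integrality invariant applies to raw counts at parse time). The full run
derives one sub-seed per contrast from the master seed, records all seeds,
the config, the package version and input SHA-256 checksums in
`manifest.json`, and is byte-reproducible; per-protein results are
invariant to protein row order. Logs go to standard error; exit codes are
0 (success), 2 (validation/format error), 3 (statistical-stage failure).

Problem sizes used by the validation suite and `scripts/acceptance.py` —
2,000 proteins × 3 replicates for the null and recovery simulations, 5,000
variances for the prior-recovery check, ≤ 4 × 3 grids for the enumeration
oracles, 1,000 Monte Carlo permutations — were chosen as the smallest sizes
at which the binomial/moment sampling error is well inside the tolerances
asserted (e.g. ±0.02 on a 0.05 rate needs ≳ 1,100 proteins).

## Known limitations

- Entry point is the protein-level table: no peptide-level inference,
  identification FDR, or search-engine specifics.
- Missingness is treated as completely at random; real label-free data are
  left-censored (low-abundance proteins go missing preferentially), which
  biases fold changes near the detection limit.
- Raw per-test p < 0.05 in the composite rule follows the emulated
  analysis; it does not control the FDR of the DE lists (the BH columns
  quantify this).
- The pooled design confounds donor and pool; n = 3 replicates gives the
  moderated t most of its power through the shared prior, and single-protein
  conclusions at this depth remain fragile.
- Two-sided rank-product p-values are Bonferroni-doubled minima of the two
  directional tests — slightly conservative.
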