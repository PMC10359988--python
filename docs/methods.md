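# Methods

This document describes the statistical model behind `cnvscatter`, every
tunable parameter with its default and rationale, the simulator's scope, and
the numerical/design choices that are not obvious from the code.

## 1. Signal model

Illumina SNP arrays report two values per probe and sample:

- **LRR (Log R Ratio)** — log-scale normalized total intensity. Expected 0
  for two copies; deletions shift it down, duplications up. Individual-probe
  LRR is noisy (SD ≈ 0.1–0.3), so single-probe evidence is weak.
- **BAF (B-allele frequency)** — normalized relative B-allele signal.
  Diploid genotypes cluster at 0, 0.5, 1; a three-copy locus puts
  heterozygotes at 1/3 and 2/3; a hemizygous locus has no heterozygote band.

For a predefined region with a target interval and 5′/3′ flanking intervals,
the per-sample summary statistic is

Δ = median LRR(target) − median LRR(flank),

computed separately for each flank. The median aggregates ~100 probes, so Δ
has an SD smaller than single-probe noise by roughly √n, and the flank
subtraction cancels sample-wide baseline offsets. Across a cohort, Δ values
form clusters: the diploid mass at 0 and satellite clusters at
copy-number-specific shifts. Canonical shifts used for labelling:

| CN | shift |
|----|-------|
| 0  | −2.0  |
| 1  | −0.50 |
| 2  | 0.0   |
| 3  | +0.25 |
| 4  | +0.45 |

These are the theoretical/empirical per-copy LRR displacements for Illumina
arrays (duplication shifts are compressed relative to deletions because LRR
is logarithmic in total intensity).

### BAF genotype categories

Within the target interval each probe's BAF is classified with strict
inequalities (boundary values fall into `other`):

- homozygous: BAF < 0.01 or BAF > 0.99
- di-allelic heterozygote: 0.47 < BAF < 0.53
- tri-allelic heterozygote: 0.3 < BAF < 0.36 or 0.63 < BAF < 0.69
- missing: NaN

## 2. Cluster genotyping

`DeltaMixtureGenotyper` is an sklearn-style estimator over the 1-D Δ values
of one region/flank across the cohort:

1. Fit `sklearn.mixture.GaussianMixture` for K = 1…`max_components` (default
   5, one per plausible CN state) with `n_init=10` and a fixed
   `random_state`; keep the K minimizing BIC. Components are re-sorted by
   mean so downstream labels are deterministic.
2. The **reference component** is the one with mean closest to 0. If its
   mean is farther than `reference_tolerance` (default 0.1, roughly the
   inter-cluster gap scale) from 0, `NoReferenceClusterError` is raised —
   without an anchored diploid cluster no labelling is trustworthy.
3. Every component is labelled with the CN of its **nearest canonical
   shift**, provided the distance is at most `label_tolerance` (default 0.1,
   same scale); farther components stay unlabelled and their samples become
   no-calls. The mapping is deliberately *not* injective: the mixture
   routinely splits a contaminated cluster into two components, and both
   halves must keep the same CN. Ties between shifts resolve toward CN 2.
4. Per sample, the posterior membership over components gives a CN call; a
   maximum posterior below `membership_threshold` (default 0.95) is a
   no-call. Requiring 95% membership trades a ~1% call-rate loss for
   near-zero boundary misassignments.
5. Fitting requires ≥ 20 finite Δ values; below that a 5-component BIC
   search is meaningless.

The region-level call combines both flanks: agreeing flanks confirm each
other; disagreeing flanks are resolved by the higher membership probability
and flagged (`flank_agreement=False`); one missing flank yields a
single-flank call.

### BAF confirmation

Called genotypes are screened against the target heterozygote counts:

| CN | rule | status |
|----|------|--------|
| 1 | n_di_het = 0 | confirmed, else contradicted |
| 2 | n_di_het ≥ 1 | confirmed, else contradicted |
| 3 | n_tri_het ≥ 1 and n_tri_het > n_di_het | confirmed, else contradicted |
| 0, 4 | — | uninformative |

CN 0 is uninformative by design: a locus with zero copies has no alleles, so
the array reports noise BAF and het counts carry no signal (the simulator
accordingly draws CN 0 BAF uniform on [0, 1]). CN 4 heterozygotes sit at
0.5, indistinguishable from diploid. Contradicted calls are demoted from
"scatterplot-positive" in the concordance analysis (see §4) —
`require_baf_confirmation=False` restores the literal Δ-only rule.

## 3. Wave noise reduction

Genomic waves are sample-specific, long-range (megabase-scale) LRR
undulations. For review of ambiguous samples, the pipeline:

1. Bins a chromosome into 1-Mb windows (`bin_size=1_000_000`, matching the
   wavelength scale; the CNV target is excluded so a real CNV cannot drive
   reference selection) and takes the median LRR per bin (`wave_profile`).
2. Picks as reference the candidate sample with the highest Pearson
   correlation over pairwise-complete bins (≥ 10 shared bins required; ties
   broken by mean absolute profile difference, then sample id, for
   determinism).
3. Subtracts the reference's per-probe LRR from the query
   (`subtract_reference`). Shared wave structure cancels; a CNV private to
   the query survives at full amplitude. Independent noise adds in variance,
   so the procedure only pays off when waves dominate — it is a review tool,
   not a default preprocessing step.

## 4. PennCNV concordance

rawcnv files are parsed into calls (1-based inclusive coordinates, length =
end − start + 1 throughout the package). A call **matches** a region when

- overlap with the target ≥ 50% of the target length, and
- call length ≤ 2 × target length (a genome-wide call spanning the region by
  accident is not evidence for the targeted CNV).

Each (sample, region) is scatterplot-positive when its called CN ≠ 2 and the
call is not BAF-contradicted; PennCNV-positive when ≥ 1 call matches (the
largest-overlap call is kept). Positives are partitioned into `concordant`,
`scatterplot_only` and `penncnv_only`; direction conflicts (one method says
deletion, the other duplication) count as one discordant record per method.

## 5. Sample QC and false-to-true curves

Per-sample metrics: number of PennCNV calls, autosomal LRR variance
(population variance, n denominator — the metric is a descriptive statistic
of the sample itself, not an estimate of a superpopulation), and call rate
(fraction of probes with non-missing BAF). `filter_by_quality` excludes the
⌊f·n⌋ worst samples by a metric (ties broken by sample id). For each
exclusion fraction in {0, 1, 5, 10, 15, 25, 50}% and each method, findings
among retained samples are split into true/false against a truth table and
reported as the false-to-true ratio (NaN when no true finding remains).

## 6. Synthetic cohorts

`SimulationConfig` / `simulate_cohort` generate a full cohort with truth:

- **Layout** — two synthetic 30-Mb chromosomes, probes every 5 kb, one CNV
  region per chromosome (0.5-Mb target, 0.5-Mb flanks ≈ 100 probes each —
  large enough that median noise ≈ 0.008 at probe SD 0.08, small enough to
  keep a 500-sample cohort around 100 MB of text). Sizes are this package's
  own choice for desk-scale experiments, not derived from any dataset.
- **Genotypes** — per region, two independent alleles ∈ {0, 1, 2} (deletion
  frequency 0.08, duplication 0.04 by default), CN = allele sum: a
  Hardy-Weinberg population with CN 0–4.
- **Signals** — LRR = per-sample sinusoidal wave (half-normal amplitude,
  U(1, 10) Mb wavelength, random phase) + N(0, 0.08) noise + CN shift at
  target probes. BAF is drawn from the CN-appropriate support (CN1: {0, 1};
  CN2: {0, ½, 1} binomial; CN3: Binomial(3, ½)/3; CN4: Binomial(4, ½)/4;
  CN0: uniform noise) with N(0, 0.02) jitter clipped to [0, 1].
- **Low-quality stratum** — 10% of samples get 3× noise, 3× wave amplitude
  and 10× missingness, reproducing the high-variance tail real QC targets.
- **Shared-wave pairs** — optionally, leading sample pairs share one wave
  (amplitude 0.3), the planted ground truth for reference selection.
- **PennCNV emulation** — true carriers emit a call with probability
  1 − fn_rate (default 0.05); diploid (sample, region) pairs emit a false
  call at rate 0.002 (0.10 in the low-quality stratum); boundaries are
  jittered by up to ±15% of the target length, small enough that every
  emitted call still satisfies the overlap rule.

All randomness flows from one `numpy` `SeedSequence`; identical configs give
byte-identical outputs. **Scope limits:** sinusoidal waves are a stylized
stand-in for real GC-correlated waves; probe noise is homoscedastic
Gaussian; PennCNV errors are independent Bernoulli events rather than
HMM-driven; there is no LD, batch structure, or X/Y handling. The simulator
validates pipeline *logic and statistics*, not array chemistry.

## 7. Numerical and design choices

- Coordinates are 1-based inclusive everywhere (probe intervals, rawcnv,
  overlap arithmetic); no internal conversion layer exists, so the printed
  overlap rule is implemented literally.
- Medians use `numpy.median` (mean of central order statistics for even n);
  missing values are excluded before the median, and an interval with no
  usable probe yields NaN rather than an error (flagged downstream as a
  missing flank or no-call).
- Mixture determinism: `n_init=10` with fixed `random_state`; components are
  re-sorted by mean after fitting so component indices, labels, and
  therefore all downstream tables are reproducible bit-for-bit.
- `label_tolerance`/`reference_tolerance` both default to 0.1 — half the
  smallest inter-shift gap (0.25 between CN2 and CN3), so tolerance windows
  of adjacent states cannot overlap.
- Regions are expected to contain ≥ 30 probes per interval; fewer triggers a
  warning (the median becomes unstable), not an error.
- CLI outputs are TSV with a two-line `#` header (description + column
  list) plus a JSON manifest per command (input paths, parameter hash, no
  timestamps) so that reruns are diffable.
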