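# Methods

## The inference chain

`thermoscore` infers a thermotolerance ranking of cultivars from four
mutually reinforcing lines of evidence, run in order:

1. **Physiology.** Heat damage is measured as after/before-stress ratios of
   Fv/Fm, root weight and shoot weight, plus the leaf wilting index (LWI).
   Ratios are computed from replicate *means*, not per-replicate pairs,
   because before- and after-stress replicates are not assumed to be the
   same plants. Each parameter is z-scored across cultivars with sample SD
   (ddof = 1) and the composite index is the unweighted mean of the four
   z-scores. z-scoring makes parameters with different units commensurate;
   it also makes the index scale-invariant (multiplying any parameter by a
   positive constant changes nothing).
2. **Induction.** log2 induction per gene, cultivar and regime is the mean
   log2 stress expression minus the mean log2 control expression, tested
   with a two-sided Welch (unequal-variance) t-test across replicates.
   Up/down calls use |log2FC| ≥ 1 (boundary inclusive) and raw p < 0.05;
   no multiple-testing correction is applied by default because the calls
   feed rank- and overlap-based summaries rather than significance claims —
   a Benjamini–Hochberg option exists but is off.
3. **Cis-element enrichment.** Occurrences of five degenerate elements are
   counted in 1-kb upstream sequences, summed over a focal gene set, and
   compared with the same total over random same-size gene sets:
   z = (N − μ)/σ with μ, σ the resampling mean and SD (ddof = 1). Sampling
   is without replacement within a draw, the focal genes stay in the
   universe, and the default is 1000 draws of 100 genes. The z is reported
   untransformed, without a p-value.
4. **Biomarkers.** Candidates pass three strict criteria (tolerant-cultivar
   induction > 6 log2; tolerant-minus-sensitive stress level > 1.4 log2;
   absolute tolerant stress level > 12 log2). Cultivars are scored by the
   mean, over the panel, of each gene's cross-cultivar z-score of
   stress-time expression, and concordance with the physiological index is
   Spearman's rank correlation.

All expression is log2 throughout; inputs arriving on a raw intensity scale
must be transformed at ingestion. Missing values propagate as NaN; any
replicate group left with fewer than two non-missing values is an error, not
a silent drop.

## Matching conventions

* Motif alphabet: A/C/G/T literal, N = any base, R = A/G, K = G/T.
* An N in the *sequence* satisfies no motif position, including motif N —
  ambiguous bases must never inflate counts.
* Overlapping occurrences all count; this is the simplest deterministic
  convention.
* Scanning is forward-strand only by default, since the element definitions
  are written as single-strand strings. In `both` mode, reverse-complement
  matches are added, and a footprint that matches both strands because the
  site is its own reverse complement is counted once.
* The observed statistic is total occurrences summed over the set; a
  genes-with-≥1-hit variant would be less sensitive to multi-site promoters
  but is not the default.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `upstream_len` | 1000 | bases | promoter window ending at the start site |
| `top_n` | 100 | genes | focal set size for enrichment |
| `null_set_size` / `null_reps` | 100 / 1000 | — | resampling null of the z-statistic |
| `fc_call_log2` / `call_alpha` | 1.0 / 0.05 | log2 / — | up/down call: twofold with Welch p |
| `diff_induction_log2` | 1.0 | log2 | twofold differential-induction flag |
| `biomarker_*_min_log2` | 6 / 1.4 / 12 | log2 | the three strict selection criteria |
| `strand_mode` | forward | — | see matching conventions |
| `zscore_ddof` | 1 | — | sample SD in all z-scores |

Ties are always broken lexicographically (gene id or cultivar id) so every
ranking is bit-reproducible.

## The synthetic-study generator

The generator emulates the *structure* of a five-cultivar heat-stress
screen, not any particular dataset. Design choices, fixed once:

* **Cultivars.** Five, with tolerance coefficients τ = 0.9 (AT, tolerant),
  0.55, 0.5, 0.45 (intermediates), 0.1 (SF, sensitive). One unique maximum
  and minimum are required so a true ranking of extremes exists.
* **Regimes.** control 25 °C (0 h), acute 50 °C shock (1 h), stepwise
  40→50 °C ramp (6 h); three replicates per cell.
* **Gene classes.** 2000 genes — the scale of the heat-responsive fraction
  of a genome-wide array — 5 % each HSE, DRE_HSE, EE, ABRE, 80 % background.
  Hsf-pathway genes (HSE, DRE_HSE) are induced under both regimes (mean
  effect 7 log2 acute, 6 stepwise, SD 1, truncated at 0); circadian/ABA
  pathway genes (EE, ABRE) respond only to the ramp (mean 6 stepwise, 0
  acute). The acute effect is attenuated by s(τ) = 0.5 + 0.5 τ — tolerant
  cultivars maintain induction at 50 °C, sensitive ones lose up to half —
  while the ramp is mild enough that all cultivars respond fully.
* **Expression noise** is Gaussian, SD 0.25 log2 units per replicate, a
  typical technical + biological spread for well-behaved array probes.
* **Promoters** are i.i.d. uniform A/C/G/T of length 1000 with two
  non-overlapping instances of the class element planted per regulated gene
  (DRE_HSE genes get one complete HSE and one DRE). Degenerate positions are
  instantiated uniformly at random so the null scanner cannot shortcut to a
  fixed literal.
* **Physiology**: after/before ratio targets 0.35 + 0.6 τ, LWI
  min(1.1, 0.55 + 0.5 τ), four replicates, Gaussian noise at 5 % of the
  mean — tolerant cultivars near LWI 1, sensitive ones wilted.

What it deliberately does **not** emulate: probe effects, dye bias and
normalization artifacts of real arrays; circadian time-of-day structure
beyond the regime dichotomy; correlated noise between genes; paired
before/after plants. Passing tests therefore demonstrate that the
statistics recover a known planted structure under clean Gaussian noise,
not that any particular field dataset will behave as cleanly.

## Numerical choices and degenerate inputs

* Identical stress and control replicate vectors make the Welch statistic
  0/0; the p-value is reported as 1 (no evidence of change).
* A parameter or panel gene with zero cross-cultivar variance cannot be
  z-scored: parameters error ("degenerate parameter"), panel genes are
  dropped with a warning, and an emptied panel errors.
* A zero-variance resampling null (σ = 0) errors rather than returning ±∞.
* The Venn percentage is the share of set B found in set A, rounded half-up
  to the nearest integer; it is undefined (reported missing) when B is
  empty.
* Promoters longer than `upstream_len` keep their 3' end — the bases
  nearest the start site; shorter ones are kept with a warning.
* Floats are written with ≥6 significant digits so tables round-trip within
  1e-9.

## Problem sizes used in checks

The test suite and `scripts/acceptance.py` exercise the default design
(2000 genes × 45 samples) for single-study claims, 5 seeds for the
enrichment-pattern claim, a 100-seed sweep (promoter synthesis disabled,
since only expression and physiology are consumed) for ranking-recovery
rates, and 200 trials × 500 resampling draws on a 1000-gene universe for
null calibration of z. These sizes give stable Monte-Carlo estimates while
keeping a full run to a few seconds.

## Known limitations

* The up/down call criterion on the original microarray platform is not
  part of the data model; the twofold + Welch default is a reasonable
  reconstruction and fully configurable.
* Whether physiological z-scores use population or sample SD is a
  convention; sample SD (ddof = 1) is the default and ddof is exposed.
* Biomarker selection uses one stress time point and scoring another in the
  motivating workflow (1 h vs 2 h); the stress selector is therefore always
  an explicit argument, never inferred.
* The LWI is consumed as a measured scalar; its geometric definition from
  plant images is out of scope.
* Enrichment z-values are not converted to p-values; resampling nulls of
  count sums are discrete and mildly skewed, so |z| should be read as a
  ranking statistic, not a Gaussian tail probability.
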