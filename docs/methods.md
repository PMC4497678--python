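# Methods

This note documents the statistical procedures implemented in `zipflemma`,
the defaults they use, and the design choices made where the procedure was
genuinely open.

## The tail model

Type frequencies are modeled above a lower cutoff by the discrete power law

    f(n) = n^-γ / Z,   n = a, a+1, ...,  (optionally n ≤ b),

with `Z = ζ(γ, a)` (Hurwitz zeta, computed by `scipy.special.zeta`) in the
unbounded case and a partial sum when truncated. The support starts at an
integer cutoff `a ≥ 1`; unbounded support requires `γ > 1`. Exponents map
between the frequency and rank forms by `γ = 1 + 1/α`.

The model's sampler inverts a precomputed cumulative table reaching the
1 − 10⁻⁹ quantile (capped at 2²⁰ entries); draws beyond the table fall back
to a continuous Pareto tail rounded to the nearest integer. The fallback
carries at most 10⁻⁹ of the mass unless the cap binds, in which case the
affected mass is still below 10⁻⁶ for every exponent/cutoff combination
used here; sampling is reproducible under a stated seed.

## Fitting and cutoff selection

Fitting is a two-step procedure. For a fixed cutoff the exponent maximizes
the log-likelihood `-γ Σ ln n_i - N ln Z(γ)` over γ ∈ (1 + 10⁻⁶, 10],
solved by bounded scalar minimization to 10⁻⁶ in γ (a dense grid search
oracle in the test suite confirms agreement to 10⁻³). The interval upper
end comfortably covers all exponents that occur in word-frequency work.

Goodness of fit uses the Kolmogorov–Smirnov distance on the fitted range.
Because the empirical CDF is a step function, the supremum over the whole
integer support is attained either at an observed value or at the integer
just below the next one; both sides are evaluated. The p-value comes from
Monte-Carlo replicas of the fitted model, each of the tail sample size;
**each replica is re-fitted by maximum likelihood at the same cutoffs and
its KS distance taken against its own re-fit** — comparing replicas against
the original fit would inflate p-values. Replicas are counted toward p
when their KS distance is ≥ the empirical one (conservative). The
exponent's standard deviation σ is the standard deviation of the replica
exponents. The default is 1000 replicas; validation suites use 100–200,
which resolves p around the 0.20 acceptance threshold to ±0.03–0.04.

Candidate cutoffs lie on a geometric grid built by successively
multiplying by `10^(1/per_decade)` (default 10 points per decade, ~26%
spacing) and rounding **up** to the next integer, deduplicated. Successive
multiplication is deliberate: accumulated floating-point error nudges exact
powers of ten to the next integer (… 80, 101, 126 …), matching the grids
used in published tail fits. The scan walks the grid upward and returns
the smallest cutoff whose p-value exceeds the threshold (default 0.20),
giving the widest accepted power-law range; when every candidate is
rejected the result is an explicit "no power-law tail", not an error. A
fit is flagged Zipf-valid when it spans at least two decades
(`n_m / a ≥ 100`). The second-regime scan fixes the lower end at n = 1 and
tries truncation points descending from the maximum frequency, returning
the largest accepted one.

The Monte-Carlo replicas re-fit only the exponent at the candidate cutoff;
the cutoff scan itself is not repeated inside each replica. This follows
the two-step structure (fit at fixed a, then test that a) and keeps the
replicas under the same procedure as the data at that step; re-running the
whole scan per replica would be a different, far costlier bootstrap and is
not what the two-step description implies.

## Cross-text battery

For per-text parameter pairs (x_i, y_i) — exponents or cutoffs of words
vs lemmas across 𝒩 texts:

* **σ_d combination**: under independence the difference of two fitted
  exponents has standard deviation `σ_d = sqrt(σ_w² + σ_l²)`; the per-text
  table reports 2σ_d as a 95% band. Within one text the two estimates are
  in fact positively dependent (the samples overlap), so the true σ_d is,
  if anything, smaller; the band is conservative in that direction.
* **Paired t**: `t = mean(d)·√M / sd(d)` with the unbiased standard
  deviation and M the pairs kept. Outlier removal drops the pairs with the
  largest |d| (ties broken by input order). The p-value is simulated: each
  replica draws 𝒩 standard normals (zero-mean, equal-variance differences
  under the null), applies the same removal rule, and computes t; p is the
  two-sided exceedance fraction. With no removal this reproduces the
  closed-form Student-t(𝒩−1) p-value (verified within Monte-Carlo error);
  with removal it keeps the selection effect in the null distribution.
  The equal-variance normal null is an approximation — the fitted σ's
  differ across texts — so its p-values are indicative rather than exact.
* **Coin-flip test**: exact enumeration of all 2^𝒩 within-text swaps of
  the statistic |mean(x) − mean(y)|; p is the fraction of configurations
  at or above the observed value (the identity configuration counts, so
  p ≥ 2^−𝒩). Enumeration is limited to 𝒩 ≤ 25.
* **Correlations**: Pearson, and Spearman as Pearson on average ranks
  (scipy implementations). Permutation p-values reshuffle one variable
  only and are two-sided in |ρ|; all 𝒩! orderings are enumerated when
  𝒩! ≤ 10⁶ (𝒩 ≤ 9), otherwise 10⁵ seeded permutations with the identity
  included. Mean independence of a ratio from its denominator is probed by
  these correlation tests (uncorrelation is necessary for mean
  independence, so a significant correlation rejects it).
* **Regressions**: ordinary least squares with classical standard errors
  (df = 𝒩 − 2) and reference t-tests of slope against 1 and intercept
  against 0. No multiple-testing correction is applied by default;
  Bonferroni and Šidák-adjusted p-values are emitted alongside the raw
  ones for the ratio-correlation block.

## Frequency spectra and collapse

Spectra are kept over raw integer frequencies for fitting; binning is
cosmetic. The rescaling `x = n⟨n⟩/⟨n²⟩`, `y = f(n)⟨n²⟩²/⟨n⟩³` is a pure
log-log shift and therefore preserves power-law shape. The collapse
distance between two rescaled spectra is the mean |Δ log₁₀ y| over
geometric bins (5 per decade) in a window of the requested width at the
top of the overlapping x-range. Two numerical choices make this robust:
bin values average the bin's mass over *all* integer frequency sites the
bin covers (in the sparse tail the raw spectrum is isolated 1/V spikes,
not a density), and bins carried by fewer than 3 occupied sites are
skipped, with the window sliding down from the top until at least half its
bins are usable in both spectra. Without these, the single largest draw —
which also dominates ⟨n²⟩ when γ ≤ 3 — would control the comparison.

## Synthetic corpora

The generator emulates the statistical skeleton the analysis assumes:

* lemma frequencies: V iid draws from the discrete power law; defaults
  γ = 2.0, a = 1, V = 5000 — a Zipf-like single-author text of moderate
  length (L ≈ 30–50k tokens at these settings);
* broken-stick splitting: each lemma of frequency n ≥ 2 breaks into two
  word forms (m, n − m) with m uniform on {1, …, n−1}; both parts are
  nonzero by construction, since a zero part would silently recreate the
  unsplit lemma, and hapax lemmas stay unsplit. k-way splitting uses
  min(k−1, n−1) distinct uniform cut points. Uniform splitting preserves
  the tail exponent — verified empirically here (the fitted word and lemma
  exponents agree within 2·sqrt(σ_w²+σ_l²) in ≥ 90% of seeded replicas)
  rather than derived;
* ambiguity: a fraction of word types (default 5%, a minority as in real
  lemmatized text) is linked to a second lemma. The link lives in the
  word↔lemma map; when the corpus file is written, tokens of an ambiguous
  word draw their lemma uniformly from the linked set, so ambiguity is
  realized in the stream at the price of approximate lemma counts
  (unambiguous corpora round-trip exactly);
* the token stream is a seeded random shuffle — no sentence structure,
  morphology, POS content (a placeholder tag), or vocabulary-growth
  (Heaps-law) dynamics are modeled.

Consequently, passing tests demonstrate the correctness of the estimators
and the internal consistency of the pipeline under the stated model; they
do not certify behavior on real text, where the head of the distribution
deviates from the tail law, lemmatization errors concentrate at low
frequencies, and word/lemma samples are dependent in ways the generator
does not reproduce.

## Validation problem sizes

The test suite validates: exponent recovery coverage (γ̂ ± 2σ covers the
truth in ≥ 90/100 replicas) across γ ∈ {1.8, 2.0, 2.13} × a ∈ {1, 10, 51}
at sample size 2000 with 200 Monte-Carlo replicas per fit; goodness-of-fit
calibration (P(p < 0.2) ≈ 0.2) over 100 null datasets of size 500;
broken-stick exponent preservation over 20 corpora of 5000 lemmas; and the
exact reproduction of every published cross-text statistic that can be
recomputed from the bundled reference table (the cutoff-side battery
agrees to all printed digits; the exponent-side published statistics were
computed from unrounded exponents and are reported but not asserted).

## Known limitations

* The MLE σ is conditional on the selected cutoff; cutoff selection adds
  uncertainty the reported σ does not include.
* The coin-flip and permutation tests are exact only at small 𝒩; the
  sampled variants carry Monte-Carlo error of order 1/√n_resamples.
* For γ ≤ 3 the empirical ⟨n²⟩ is dominated by the largest draw, so
  moment-rescaled comparisons between independent samples are noisy by
  nature; the collapse distance is designed for paired (same-text)
  comparisons.
* The discrete sampler's continuous-tail fallback introduces a sub-10⁻⁶
  mass approximation beyond the cumulative table cap.
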