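# zipflemma

Zipf's-law tail statistics for word forms versus lemmas.

## The problem

Zipf's law for word frequencies can be written in two equivalent forms: the
rank-frequency form `n(r) ∝ r^-α`, and the frequency form used throughout
this package — the probability that a type has frequency `n` follows

    f(n) = C n^-γ   for n ≥ a,       γ = 1 + 1/α,

with exponent `γ` (near 2 for natural text) and a low-frequency cutoff `a`
above which the power law holds. The law is considered *valid* when the
fitted tail spans at least two decades, `n_m / a ≥ 100`, up to the largest
frequency `n_m`.

A text can be counted in word forms (*houses*, *housed*) or in lemmas
(both → *house*). Lemmatization changes the whole frequency distribution —
fewer types, higher mean frequency — so it is a real question whether the
tail parameters `(γ, a)` survive the transformation. This package provides
everything needed to ask it quantitatively:

* **corpus statistics** — frequency tables from annotated token-per-line
  TSV corpora under four unit definitions (word, lemma, lemma+POS,
  word+lemma+tag), dictionary coverage, the word↔lemma association map,
  words-per-lemma and frequency-ratio statistics, rank-frequency;
* **power-law fitting** — discrete power-law maximum likelihood (the
  normalization is the Hurwitz zeta `ζ(γ, a)`), Kolmogorov–Smirnov
  goodness of fit with Monte-Carlo p-values (each simulated replica is
  re-fitted before its KS distance is taken), and automatic scanning of
  lower cutoffs (10 grid points per decade, smallest accepted cutoff wins)
  or upper truncation points for a second low-frequency regime;
* **spectra** — empirical `f(n)` and the moment rescaling
  `x = n⟨n⟩/⟨n²⟩`, `y = f(n)⟨n²⟩²/⟨n⟩³` whose tail collapse signals a
  shared exponent;
* **cross-text comparison** — paired t-tests with simulated nulls and
  principled outlier removal, the exact 2^N sign-flip ("coin-flip") test,
  Pearson/Spearman correlations with permutation p-values, and
  mean-independence regressions testing slope = 1 / intercept = 0;
* **synthetic corpora** — seeded generation of power-law lemma
  frequencies, broken-stick splitting of lemmas into word forms (which
  preserves the tail exponent), optional word ambiguity, and exact
  realization as a shuffled annotated corpus file.

The package ships a reference table of published tail-fit parameters for
ten long novels in four languages (English, Spanish, French, Finnish), the
canonical input for the comparison battery.

## Worked example

Fitting a tail with known ground truth (`examples/fit_power_law_tail.py`):

```
$ python examples/fit_power_law_tail.py
table: V=5000 types, L=31584 tokens, n_m=2591
selected cutoff a=1, gamma = 2.006 +/- 0.015
KS distance 0.0062, p-value 0.30 from 200 simulations
tail holds over n_m/a = 2591x, two-decade Zipf validity: True
```

The generator drew 5000 frequencies from a discrete power law with γ = 2;
the scan accepts the very first cutoff and recovers the exponent within
one standard deviation.

Running the cross-text battery on the bundled reference table
(`examples/compare_words_vs_lemmas.py`):

```
cutoffs a_w vs a_l over 10 novels
  coin-flip |mean difference| = 16.9, exact p = 0.0156 over 1024 sign patterns
  paired t without Clarissa: t = -3.091, simulated p = 0.018
  Pearson(a_w, a_l) = 0.961
  E[a_l|a_w]: slope 0.912 +/- 0.093, intercept 20.009 (t vs 0 = 3.19, p = 0.013)

exponents gamma_w vs gamma_l
  coin-flip statistic = 0.036, exact p = 0.047
  texts whose exponent difference exceeds 2 sigma_d: Moby-Dick, Don Quijote, Kevät ja takatalvi
```

Read: the lower cutoffs shift upward significantly under lemmatization
(the positive intercept of `E[a_l|a_w]` and the sign-flip test agree),
while the exponents stay close — word and lemma cutoffs are strongly
correlated (ρ = 0.961) and the exponent differences rarely exceed their
own uncertainty band.

Each script in `examples/` is a short narrative of one capability; the
`zipflemma` command exposes the same pipeline from a shell
(`zipflemma count|fit|compare|simulate|spectrum --help`).

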