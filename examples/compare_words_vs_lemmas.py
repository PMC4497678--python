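"""The cross-text battery on the bundled ten-novel reference parameters.

Runs paired t-tests (with and without one outlier), the exact sign-flip
('coin-flip') test, correlations with permutation p-values and the
mean-independence regressions for both the tail exponents and the lower
cutoffs of ten long novels.
"""

from zipflemma import compare_texts, reference_tail_fits

fits_w, fits_l = reference_tail_fits()
report = compare_texts(fits_w, fits_l, seed=1, n_sims_t=100_000)

cut = report["cutoffs"]
print("cutoffs a_w vs a_l over", cut["N"], "novels")
print(f"  coin-flip |mean difference| = {cut['coin_flip']['statistic']:.1f}, "
      f"exact p = {cut['coin_flip']['p_exact']:.4f} over {cut['coin_flip']['n_configurations']} sign patterns")
t1 = cut["paired_t_remove1"]
print(f"  paired t without {t1['outliers_removed'][0]}: t = {t1['t']:.3f}, simulated p = {t1['p_sim']:.3f}")
print(f"  Pearson(a_w, a_l) = {cut['direct_correlation']['pearson']['rho']:.3f}")
reg = cut["regressions"][1]  # E[a_l | a_w]
print(f"  {reg['model']}: slope {reg['slope']:.3f} +/- {reg['se_slope']:.3f}, "
      f"intercept {reg['intercept']:.3f} (t vs 0 = {reg['t_intercept_vs_0']:.2f}, p = {reg['p_intercept']:.3f})")

exp = report["exponents"]
print("\nexponents gamma_w vs gamma_l")
print(f"  coin-flip statistic = {exp['coin_flip']['statistic']:.3f}, exact p = {exp['coin_flip']['p_exact']:.3f}")
outside = [r["label"] for r in exp["sigma_d_table"] if r["outside_2sigma_d"]]
print("  texts whose exponent difference exceeds 2 sigma_d:", ", ".join(outside))
# Cutoffs shift systematically upward under lemmatization (significant
# coin-flip and intercept tests); the exponents stay close, with only a few
# texts outside their own 2-sigma band.
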