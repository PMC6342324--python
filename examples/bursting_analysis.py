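"""Fit and test the negative-binomial bursting model for one allele.

Simulates two independently bursting alleles (burst size 2, burst
frequency 1.5 per mRNA lifetime), recovers the parameters by the method of
moments, checks goodness of fit across a grid of imposed burst sizes, and
locates the observed allele-allele correlation in the random-pairing null.
"""

import allelesim as al

true = al.NegBinParams.from_bursting(burst_size=2.0, burst_frequency=1.5)
counts = al.gen_bursting_population(5000, true, true, rng_seed=7)

fit = al.fit_negbin_moments(counts["n_bl6"])
print(f"moments fit: burst size {fit.burst_size:.2f} (true 2.0), "
      f"burst frequency {fit.burst_frequency:.2f} (true 1.5)")

scan = al.burst_size_scan(counts, "BL6", n_sims=500, rng_seed=8)
good = scan.loc[scan["good_fit"], "burst_size"].tolist()
print(f"burst sizes consistent with the data (central 95%): {good}")

corr = al.paired_correlation_test(counts, fit, fit, n_sims=5000, rng_seed=9)
print(f"observed allele correlation {corr.observed:+.3f} at percentile "
      f"{corr.percentile:.1f} of the random-pairing null "
      f"(null mean {corr.null.mean():+.4f})")
print("\nIndependent bursting predicts zero correlation between alleles;")
print("an observed value inside the null is consistent with that model.")
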