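"""How dropping duplicate haplotypes biases genetic diversity estimates.

Public barcode submissions sometimes omit duplicate alleles.  Computing
diversity on unique haplotypes only removes the closest pairs, which
inflates the mean — strongly when duplicates are common (small Ne, low
theta) and not at all once every sampled copy is distinct (large Ne).
"""

from macrogd import duplicate_allele_experiment

table = duplicate_allele_experiment([1e3, 1e4, 1e5, 1e6], n_reps=200, seed=0)
cols = ["Ne", "theta_per_site", "gd_all_mean", "gd_unique_mean", "bias_mean", "bias_se"]
print(table[cols].to_string(index=False, float_format=lambda v: f"{v:.6f}"))
print("\nbias_mean shrinks toward 0 as Ne grows: diversity computed with and "
      "without duplicate alleles converges for Ne >= ~1e5 here.")
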