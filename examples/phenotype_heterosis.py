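"""Phenotype-level heterosis: K+ content and the three heterosis indices.

Converts a flame-photometry reading into leaf K+ content, then computes
over-high-parent (OPH), mid-parent (MPH) and over-low-parent (BPH)
heterosis of simulated replicate measurements.
"""

from triohet import heterosis_indices, kplus_content, simulate_phenotype

# one flame-photometry measurement: 20 ppm in 100 mL extract from 0.5 g leaf
k_pct = kplus_content(c_ppm=20.0, volume_ml=100.0, dry_weight_g=0.5)
print(f"K+ content of the measured sample: {k_pct:.2f}% of dry weight")

# replicated K+ phenotype for a trio with a superior hybrid
table = simulate_phenotype(
    f1_mean=3.0, pf_mean=2.4, pm_mean=2.0, cv=0.05, n_reps=3, seed=1
)
means = table.groupby("genotype")["value"].mean()
idx = heterosis_indices(
    means["hybrid"], means["female_parent"], means["male_parent"]
)
print(f"replicate means: F1={means['hybrid']:.3f}, "
      f"P_f={means['female_parent']:.3f}, P_m={means['male_parent']:.3f}")
print(f"OPH = {idx.oph:.1f}%  MPH = {idx.mph:.1f}%  BPH = {idx.bph:.1f}%")
print("Positive OPH means the hybrid exceeds even its better parent — "
      "the strongest form of hybrid vigor.")
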