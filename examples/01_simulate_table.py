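"""Generate a synthetic salinity-phenotype table and inspect its structure.

Builds the default emulated glasshouse design — 10 rice genotypes x 3
salinity levels (0/50/100 mM NaCl) with replicates, 146 records — and
prints the cell means so the salinity gradient is visible: stomatal
conductance and shoot K+ fall with salt, shoot Na+ rises, and shoot dry
weight follows the planted quadratic response surface plus 0.28 g/plant
noise.
"""

from saltreg import SyntheticConfig, generate

data, truth = generate(SyntheticConfig(seed=7))
frame = data.to_frame()

print(f"records: {data.n}   genotypes: {frame['genotype'].nunique()}   "
      f"salinity levels: {sorted(frame['salinity_mM'].unique())}")
print("\nmeans by salinity level:")
cols = ["spad", "gs_mmol_m2_s", "shoot_na_mM", "shoot_k_mM", "sdw_g"]
print(frame.groupby("salinity_mM")[cols].mean().round(1))
print("\nfirst records:")
print(frame.head(5).round(2).to_string(index=False))
print(f"\nplanted outliers: {truth.outlier_ids or 'none'}")
# Falling Gs/K+ and rising Na+ across 0 -> 100 mM mimic the physiological
# response of salt-stressed rice; sdw_g is the quantity the pipeline models.
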