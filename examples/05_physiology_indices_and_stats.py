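"""Compute RWC, succulence and MDA and star the control-vs-salt contrast.

Simulates the daily physiology table (4 replicates per group per day),
computes the three indices per replicate, aggregates to daily means ± SE,
and runs per-day Student's t-tests with the */** annotation convention
(p < 0.05 / p < 0.01).
"""

from phenokit import SimConfig, daily_comparison, index_series, \
    simulate_physio
from phenokit.physio import mda_concentration, mda_per_gram

samples = simulate_physio(SimConfig(seed=1))
indices = index_series(samples)

mda = indices[indices["index"] == "mda_nmol_g"]
print("MDA (nmol g-1 FW), mean +/- SE:")
for day in (0, 5, 7, 10, 14):
    row_c = mda[(mda["day"] == day) & (mda["group"] == "control")].iloc[0]
    row_s = mda[(mda["day"] == day) & (mda["group"] == "salt")].iloc[0]
    print(f"  day {day:2d}: control {row_c['mean']:.2f}+/-{row_c['se']:.2f}"
          f"   salt {row_s['mean']:.2f}+/-{row_s['se']:.2f}")

samples["value"] = [
    mda_per_gram(mda_concentration(r.od532, r.od450), tissue_mass=r.tissue_g)
    for r in samples.itertuples()]
results = daily_comparison(samples[["day", "group", "value"]])
starred = [int(r.day_index) for r in results if r.stars]
print(f"\ndays with a significant MDA difference: {starred}")
# Oxidative stress (lipid peroxidation, read out as MDA) rises in the salt
# group around the CAM transition; stars appear from roughly day 7 on.
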