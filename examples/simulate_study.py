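"""Generate a synthetic fractionation study with planted taste-actives.

Builds the default scenario (50 ordered fractions, 300 LC-MS features, 3
taste-active compounds, a 12-member panel) and prints what was planted and
what the raw data look like.
"""

import sensomics as sm

gt = sm.generate_ground_truth(n_compounds=300, n_fractions=50, n_active=3, seed=1)
ft = sm.simulate_feature_table(gt)
records = sm.simulate_taste_records(gt, ft)
masses = sm.simulate_fraction_masses(gt)

print("planted taste-active compounds:")
for c in gt.active_compounds:
    cat, pot = next(iter(c.taste_potencies.items()))
    print(
        f"  {c.compound_id}: {cat:8s} potency {pot:.2f}, "
        f"elutes around fraction {c.elution_center:.1f} "
        f"(width {c.elution_width:.1f})"
    )

missing = ft.intensities.isna().mean().mean()
print(f"\nfeature table: {ft.n_features} features x {len(ft.fractions)} fractions, "
      f"{missing:.0%} cells below the detection limit")
print(f"sensory records: {len(records)} (panelist, fraction, descriptor, score) rows")
print(f"fraction masses: total {masses.sum():.0f} mg, "
      f"range {masses.min():.1f}-{masses.max():.1f} mg")
print("\nThe missing feature cells are left-censored detections; the sensory "
      "rows are the raw panel output before any consolidation.")
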