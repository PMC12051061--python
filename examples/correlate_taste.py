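"""Find taste-active MS features by segment-wise correlation.

The core statistic: every (feature, taste category, 5-9-fraction window)
triple is correlated — Kendall's tau-b when either vector fails a
Shapiro-Wilk normality screen, Pearson's r otherwise — then
Benjamini-Hochberg adjusted, retained at (adjusted p < 0.05, coefficient
> 0.95) and refined by requiring the window to hold at least four of the
feature's five most intense fractions.
"""

import sensomics as sm

gt = sm.generate_ground_truth(300, 50, 3, seed=1)
ft = sm.simulate_feature_table(gt)
records = sm.simulate_taste_records(gt, ft)
cmap = {syn: cat for cat, syns in gt.panel.synonym_table.items() for syn in syns}
profile = sm.aggregate_profile(
    sm.consensus_filter(sm.map_descriptors(records, cmap), 2),
    fractions=gt.fraction_ids,
    categories=sorted(gt.panel.categories),
)

report = sm.run_correlation(ft, profile)
m = report.meta
print(f"{m['n_tested']:,} correlations computed "
      f"({m['n_triples']:,} triples, {m['n_skipped']:,} constant windows skipped)")
print(f"{m['n_retained']} retained (BH p < 0.05, r > 0.95), "
      f"{m['n_refined']} refined by the top-5-rank rule")

refined = report.records[report.records["refined"]]
best = (
    refined.sort_values("p_adj")
    .groupby(["feature_id", "category"], as_index=False)
    .first()
    .sort_values("p_adj")
)
planted = {f"M_{cid}": cat for cid, cat in gt.planted_pairs()}
print("\ntop refined (feature, category) pairs:")
for _, r in best.head(8).iterrows():
    tag = "PLANTED" if planted.get(r["feature_id"]) == r["category"] else "co-eluter"
    print(f"  {r['feature_id']} ~ {r['category']:8s} r={r['coefficient']:.3f} "
          f"p_adj={r['p_adj']:.2e} [{tag}]")
print("\nEvery planted compound should surface for its planted taste; other "
      "hits are features co-eluting with a taste-active compound.")
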