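"""The headline analysis: does h2 track trait evolutionary importance?

Runs the whole pipeline on an adaptive-divergence panel (traits coupled to
growth carry more fixed additive divergence) and prints the h2-RTGR and
QTL-count correlations, overall and for exemplar traits only.
"""

import segvar as sv

res = sv.run_synthetic_analysis(sv.PipelineConfig(seed=42))
traits = res["traits"]
corr = res["correlations"]

print(f"{len(traits)} traits, "
      f"{int(traits['is_exemplar'].sum())} exemplars "
      f"(affinity propagation on trait profiles)")
print(f"estimated h2 range: {traits['h2'].min():.3f}-{traits['h2'].max():.3f}")

for name, label in [("h2_vs_RTGR", "h2 ~ RTGR, all traits"),
                    ("h2_vs_RTGR_exemplars", "h2 ~ RTGR, exemplars only"),
                    ("h2_vs_one_minus_cv", "h2 ~ 1-CV, consistent traits"),
                    ("qtl_count_vs_h2", "QTL count ~ h2"),
                    ("qtl_R2_vs_h2", "QTL variance explained ~ h2")]:
    row = corr[name].iloc[0]
    print(f"{label:34s} R = {row['pearson_r']:+.3f}  "
          f"p = {row['p_value']:.2e}  (n = {row['n']})")

print("\nPositive R for importance indices means evolutionarily important "
      "traits carry more additive variance, the signature expected after "
      "adaptive divergence followed by admixture.")
print("\nby stage:")
print(corr["h2_vs_RTGR_by_stage"].to_string(index=False))
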