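"""Rank features with the three selection methods and the combined rule.

A 30-participant table with three informative features (global indices 16,
29, 37 — horizontal max amplitude SD in NTF, percent time to peak
acceleration SD and vertical amplitude SD in NTE) at effect size 2.5.
"""

import imitkin as ik

fm = ik.simulate_feature_table(
    n_asc=14, n_ctrl=16, n_features=40,
    informative_idx={16, 29, 37}, effect_size=2.5, seed=3,
)
X, y = fm.values, fm.y

svm = ik.rank_by_svm_weights(X, y, seed=0)
lopo = ik.lopo_impact(X, y)
pca, ratios = ik.pca_first_pc_contrib(X)

print("top-8 by linear-SVM |weights|:", svm.top(8))
print("top-10 by leave-one-parameter-out impact:", lopo.top(10),
      f"(baseline LOOCV accuracy {lopo.baseline_accuracy:.0%})")
print("top-3 by first-PC contribution:", pca.top(3),
      f"(PC1 explains {ratios[0]:.0%} of variance)")

selected = ik.combined_select(X, y, seed=0)
print("\ncombined rule (SVM top-8 union (PCA top-3 intersect LOPO top-10)):")
print("  selected:", selected)
print("  planted features recovered:", sorted({16, 29, 37} & set(selected)),
      "of {16, 29, 37}")
for idx in sorted({16, 29, 37} & set(selected)):
    cond, name = ik.index_to_label(idx)
    print(f"    {idx}: {name} SD in {cond}")
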