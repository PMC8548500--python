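"""Five-fold cross-validation against a baseline and an ablation.

All disease-miRNA pairs of a planted-block study are partitioned into five
folds; per fold the held-out positives are masked, the GIP kernels and the
WKNKN completion are recomputed from the masked matrix, and the held-out
pairs are scored.  The same seeded folds evaluate the degree-product
baseline and a no-completion ablation, so the comparison is paired.
"""

from hetmda import FixtureSpec, degree_product_scores, five_fold_cv, make_fixture

fx = make_fixture(FixtureSpec(seed=7))  # 60 diseases x 80 miRNAs, 4 blocks

full = five_fold_cv(fx.A, fx.DSS, fx.MFS, seed=7)
baseline = five_fold_cv(fx.A, fx.DSS, fx.MFS, seed=7, score_fn=degree_product_scores)
ablated = five_fold_cv(fx.A, fx.DSS, fx.MFS, seed=7, use_wknkn=False)

print(f"{'':18}  AUC    AUPR")
print(f"{'full pipeline':18} {full.mean_auc:.4f} {full.mean_aupr:.4f}")
print(f"{'no WKNKN':18} {ablated.mean_auc:.4f} {ablated.mean_aupr:.4f}")
print(f"{'degree baseline':18} {baseline.mean_auc:.4f} {baseline.mean_aupr:.4f}")
print()
print("The degree-product baseline is blind to the planted co-clusters;")
print("skipping the WKNKN completion costs most in AUPR, the metric that")
print("rewards concentrating the sparse positives at the top of the list.")
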