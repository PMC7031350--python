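"""Full partition-and-local-models run on a hidden two-regime mixture.

The dataset mixes two 5-D Gaussian blobs with conflicting within-regime
linear laws, so no single linear model fits (pooled R² ≈ 0.5) although each
regime alone is exactly linear.  The recursive binary partition is forced
(tree ensembles would otherwise satisfy the user threshold during
exploration) and recovers the regimes; per-leaf meta-models plus a router
then beat the linear baseline by a wide margin.
"""

import warnings

from sklearn.metrics import adjusted_rand_score

from partwise import RunConfig, SyntheticSpec, make_dataset, run_pipeline

ds = make_dataset(SyntheticSpec(kind="two_regime", n=400, seed=7))
config = RunConfig(task="regression", metric_of_interest="r2",
                   x_user=0.9, linear_threshold=0.9,
                   min_subset_fraction=0.3, seed=7)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(ds, config, force_partition=True)

tree = result.tree
ev = result.evaluation
hidden = ds.meta["regime"][result.split.train_indices]
ari = adjusted_rand_score(hidden, tree.leaf_labels())

print(f"leaves               : {tree.n_leaves} "
      f"(sizes {[leaf.size for leaf in tree.leaves]})")
print(f"adjusted Rand vs truth: {ari:.3f}")
print(f"x_linear             : {ev.x_linear:.3f}   (pooled OLS fails)")
print(f"x_hat  (expected)    : {ev.x_hat:.3f}   (size-weighted leaf CV R2)")
print(f"x_modgen (realised)  : {ev.x_modgen:.3f}   (router + leaf models, held out)")
print(f"improvement I        : {ev.improvement_percent}%")
print(f"over-fitting IOF     : {ev.iof_percent}%   "
      f"({'re-partition advised' if ev.repartition_recommended else 'no action'})")
print(f"router accuracy      : {result.global_model.router.router_metrics['accuracy']:.3f}")
print()
print("An adjusted Rand index of 1.0 means the unsupervised partition")
print("recovered the hidden regimes exactly; negative IOF means the")
print("assembled model beats its own leaf-level expectation (synergy).")
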