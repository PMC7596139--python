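"""Compare small-world organization of the disease subspace between groups.

Builds each group's metabolic correlation network over the salient-ROI
subspace, thresholds it at 25% connection density, computes clustering (C),
characteristic path length (L) and small-worldness (S), and tests the
group difference in C with a subject-relabeling permutation test.
"""

from pdrpnet import (
    SimulationConfig,
    group_correlation_matrix,
    min_full_connectivity_sparsity,
    permutation_metric_test,
    simulate_cohort,
    sparsity_sweep,
)

# patients carry a stronger latent factor on the subspace ROIs, which
# concentrates their strongest correlations inside the salient core
cfg = SimulationConfig(
    n_hc=30,
    n_pd=30,
    score_sd=0.05,
    score_mean_pd=0.5,
    noise_sd=0.3,
    subject_scale_sd=0.05,
    subspace_factor_loading_hc=0.0,
    subspace_factor_loading_pd=0.9,
    seed=2,
)
cohort, truth = simulate_cohort(cfg)
nodes = tuple(cohort.roi_ids[j] for j in truth.salient_all)

for group in ("HC", "PD"):
    sub = cohort.subset_group(group)
    gm = sparsity_sweep(sub, nodes, grid=(0.25,), n_rand=100, seed=0)[0]
    corr, _ = group_correlation_matrix(sub, nodes)
    smin = min_full_connectivity_sparsity(corr)
    smin_txt = f"{smin:.0f}%" if smin is not None else "> 50%"
    print(
        f"{group}: C = {gm.C:.3f}  L = {gm.L:.3f}  S = {gm.S:.3f}  "
        f"(min fully-connected sparsity {smin_txt})"
    )

res = permutation_metric_test(
    cohort.subset_group("PD"),
    cohort.subset_group("HC"),
    nodes,
    sparsity=0.25,
    metric="C",
    n_perm=1000,
    seed=0,
)
print(
    f"clustering difference PD - HC = {res.observed:+.3f}, "
    f"permutation p = {res.p_value:.4f} ({res.n_perm} relabelings)"
)
print()
print(
    "Higher C with similar L gives the patient subspace an exaggerated"
    " small-world coefficient (S > 1): locally dense, metabolically costly"
    " wiring concentrated among the salient regions."
)
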