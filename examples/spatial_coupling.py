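"""Are neighbouring cells' expression states coupled?

Generates a tissue whose extrinsic factor is a spatially correlated field
(nearest-neighbour coupling 0.34, decaying with distance), then estimates
the coupling with the covariance-normalized cross-reporter statistic,
tests it by randomization, and profiles its decay over distance tiers.
"""

from noisetissue import (
    SpatialConfig,
    TissueGenConfig,
    analyze_spatial,
    average_duplicates,
    generate_tissue,
    normalize_table,
)

config = TissueGenConfig(n_cells=2000, coupling=0.34, corr_length_um=40.0, seed=8)
table, truth = generate_tissue(config)
norm = normalize_table(average_duplicates(table))

res = analyze_spatial(norm, SpatialConfig(n_permutations=5000, seed=2))
print(f"n = {res.n_cells} cells, mean nearest-neighbour distance "
      f"{res.mean_nn_distance:.1f} um")
print(f"nearest-neighbour coupling r = {res.r:.3f} (generator target 0.34)")
print(f"randomization test p = {res.p:.4f}  (floor = {1 / 5001:.4f})")
print("\ntier profile (ring width = one mean nearest-neighbour distance):")
for t in res.tier_profile:
    print(f"  tier {t.tier}: mean = {t.mean:6.3f}  (n = {t.n_pairs} pairs)")
print("\nCoupling is strongest between immediate neighbours and decays with")
print("distance; the permutation p-value shows it is not a sampling artefact.")
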