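"""Estimate the spatial cluster size of X-inactivation choice.

Simulates a tissue section whose cells made their X-inactivation choice in
contiguous clusters of 4 cells, computes the grid-variance metric of the
BL6 fraction, compares it to a permutation null, and matches it against
seeded-cluster simulations at sizes 1-10 to recover the cluster size.
"""

import numpy as np

import allelesim as al
from allelesim.spatial import grid_variance, permutation_null

layout = al.gen_tissue_layout(2000, p_bl6=0.5, seed_size=4, rng_seed=10)
print(f"{layout.n_cells} cells, realized BL6 fraction "
      f"{layout.bl6_fraction:.3f}, true seed size 4")

prof = grid_variance(layout, (8, 8))
null = permutation_null(layout, (8, 8), n_perm=1000, rng_seed=11)
print(f"8x8 grid variance: observed {prof.variance:.4f}, permutation null "
      f"{null.mean():.4f} +/- {null.std():.4f}")

result = al.estimate_seed_size(
    layout, grids=[(g, g) for g in range(4, 17, 2)], n_sim=200, rng_seed=12
)
print(f"estimated seed size: {result.mean_seed:.1f} +/- {result.sd_seed:.1f}")
print("\nClustered allelic choice inflates the between-rectangle variance")
print("of the BL6 fraction; the seed size whose simulations match that")
print("variance, averaged over grids, estimates the cluster size.")
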