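"""Assign mRNA spots an allelic identity by two-channel colocalization.

Simulates a three-channel spot field with a known chromatic shift between
the guide and allele channels, estimates and corrects that shift, scans
matching radii against the pixel-shifted control, and aggregates the
per-spot assignments into per-cell allelic counts.
"""

import numpy as np

import allelesim as al

spec = al.SpotFieldSpec(
    n_guide=2000, chromatic_shift=(0.4, -0.3), localization_jitter_sd=0.15,
    coloc_prob_bl6=0.3, coloc_prob_jf1=0.3, spurious_density=1e-4, rng_seed=4,
)
guide, bl6, jf1, truth = al.gen_spot_field(spec)

disp = al.estimate_displacement(guide, bl6)
print(f"estimated chromatic shift: ({disp[0]:+.3f}, {disp[1]:+.3f}) px "
      f"(true (+0.400, -0.300))")

radius, scan = al.select_radius(guide, bl6, jf1, displacement=disp)
print(f"chosen matching radius: {radius:.1f} px")

result = al.colocalize_spots(guide, bl6, jf1, radius, displacement=disp)
control = al.pixel_shift_null(guide, bl6, jf1, radius, displacement=disp)
print(f"unique colocalization rate: {result.unique_coloc:.3f} "
      f"(ground truth {(truth['true_assignment'] != 'none').mean():.3f})")
print(f"pixel-shifted (chance) rate: {control.overall_coloc:.3f}")

cells = np.arange(len(guide)) // 10  # 10 guide spots per synthetic cell
counts = al.per_cell_counts(result, cell_ids=cells)
print(f"\nper-cell table: {len(counts)} cells, mean "
      f"{counts[['n_bl6', 'n_jf1']].to_numpy().sum(axis=1).mean():.1f} "
      f"assigned RNAs per cell")
print("Guide spots matched to exactly one allele channel inherit that")
print("allele; the pixel-shift control measures how often that happens by")
print("chance at the same spot densities.")
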