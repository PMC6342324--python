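"""Detect Xist-like RNA foci in an image and classify their allele.

Renders a guide-channel image of bright diffraction-limited foci plus the
two SNV-channel images, detects foci with the LoG pipeline, measures the
normalized SNV intensity ratio per focus, and splits the resulting angle
distribution with two-cluster k-means.
"""

import allelesim as al

image, truth = al.gen_foci_image(n_foci=50, extent=(512, 512), rng_seed=5)
bl6_img, jf1_img = al.render_foci_channels(truth, extent=(512, 512), rng_seed=6)

detection = al.detect_foci(image)
print(f"detected {len(detection)} of {len(truth)} rendered foci")

table = al.measure_snv_intensities(detection, bl6_img, jf1_img)
table, critical = al.classify_by_kmeans(table)
n_b = int((table["assignment"] == "BL6").sum())
n_j = int((table["assignment"] == "JF1").sum())
print(f"critical angle: {critical:.3f} rad")
print(f"assignments: {n_b} BL6, {n_j} JF1 "
      f"(truth {int((truth['true_assignment'] == 'BL6').sum())} BL6)")
print("\nEach focus is placed at theta = atan2(I_JF1, I_BL6); foci above")
print("the critical angle are dominated by the JF1 channel and called JF1.")
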