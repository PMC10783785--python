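"""Extract the 153-feature slide descriptor from a synthetic tile.

The vector is 18 first-order gray-level statistics of the global ROI plus
135 nucleus-shape features (27 descriptors x {mean, sd, min, max, mrate}).
"""

import wsisurv as w

slide = w.generate_slide(w.SlideSimParams(image_size=512, n_nuclei=60, heterogeneity=0.3, seed=7))
config = w.FeatureConfig(sample_block_size=256, n_blocks=8)
vec = w.extract_slide_features(slide.image, config, seed=7)

print(f"feature vector length: {len(vec)} "
      f"({len(vec.global_features)} global + {len(vec.shape_features)} shape)")
print(f"nuclei pooled across blocks: {vec.provenance['n_nuclei_sampled']}")
for name in ("gray_mean", "gray_entropy", "area_mean", "area_mrate", "aspect_ratio_mean"):
    print(f"  {name:>20s} = {vec.to_series()[name]:.3f}")
# area_mrate is the min/max rate of nucleus area across sampled nuclei:
# a smaller value indicates a higher level of morphological variation.
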