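"""Generate one synthetic DCE-MRI lesion and inspect its ground truth.

The phantom embeds an ellipsoidal tumor in a homogeneous background and
assigns each tumor voxel a kinetic class (washout / plateau / persistent)
whose noise-free percent-enhancement (PE) and signal-enhancement-ratio
(SER) targets are hit exactly by construction.
"""

from angiokin.phantom import PhantomSpec, generate_lesion

spec = PhantomSpec(
    class_fractions=(0.4, 0.35, 0.25),  # washout, plateau, persistent
    noise_sd=2.0,
    seed=7,
)
series, mask, truth = generate_lesion(spec)

print(f"grid {series.shape}, spacing {series.spacing_mm} mm, "
      f"timepoints {series.timing_s} s")
print(f"tumor voxels: {mask.n_voxels} "
      f"({mask.n_voxels * mask.voxel_volume_mm3 / 1000:.3f} cm^3)")
print(f"designed washout fraction : {truth.true_wf_pct:.1f} %")
print(f"designed peak PE          : {truth.true_peak_pe_pct:.0f} %")
print(f"designed peak SER         : {truth.true_peak_ser:.2f}")
print(f"class voxel counts (w/p/p): {truth.class_counts}")
# The washout fraction is the percentage of tumor voxels designed to
# clear contrast rapidly (PE >= 50% and SER >= 1.1) - the quantity the
# downstream kinetic analysis should recover.
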