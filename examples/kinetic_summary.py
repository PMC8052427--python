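"""Compute the four semi-quantitative kinetic summaries for a lesion.

PE = 100*(S1-S0)/S0 measures early enhancement (~120 s); SER =
(S1-S0)/(S2-S0) measures washout between ~120 s and ~480 s. The
per-lesion summaries are the 3x3x3 hot-spot peaks of each map, the
functional tumor volume (FTV, PE >= 50%) and the washout fraction
(WF, PE >= 50% and SER >= 1.1).
"""

from angiokin import kinetics
from angiokin.phantom import PhantomSpec, generate_lesion

series, mask, truth = generate_lesion(PhantomSpec(noise_sd=2.0, seed=7))
summary = kinetics.summarize_lesion(series, mask)

print(f"peak PE  : {summary.peak_pe_pct:6.1f} %   (designed {truth.true_peak_pe_pct:.0f})")
print(f"peak SER : {summary.peak_ser:6.2f}     (designed {truth.true_peak_ser:.2f})")
print(f"FTV      : {summary.ftv_cm3:6.3f} cm^3 (designed {truth.true_ftv_cm3:.3f})")
print(f"WF       : {summary.wf_pct:6.1f} %   (designed {truth.true_wf_pct:.1f})")
print(f"voxels   : {summary.n_washout_voxels} washout / "
      f"{summary.n_enhancing_voxels} enhancing / {summary.n_mask_voxels} tumor")
# Small deviations from the designed values reflect the additive image
# noise; with noise_sd=0 all four summaries match to 1e-9.
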