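# angiokin

Semi-quantitative DCE-MRI kinetics, gray-level radiomics and
microvessel-density (MVD) association analysis for breast-tumor
angiogenesis studies — with a seeded synthetic phantom cohort so the
whole pipeline is testable end-to-end without any image download.

## The problem

Tumor angiogenesis is conventionally graded by counting CD31-stained
microvessels in fixed-area microscope fields (MVD). Dynamic
contrast-enhanced MRI offers a non-invasive surrogate: tumors with
dense, leaky microvasculature take up and clear gadolinium contrast
faster. With a pre-contrast volume `S0` and post-contrast volumes `S1`
(~120 s) and `S2` (~480 s), the package computes per voxel

- **PE** = 100·(S1 − S0)/S0 — percent enhancement (%),
- **SER** = (S1 − S0)/(S2 − S0) — signal enhancement ratio
  (computed only where PE ≥ 50%; SER > 1 means washout),

and per lesion

- **peak PE** and **peak SER** — the best 3×3×3 hot-spot window means,
- **FTV** — functional tumor volume, the summed volume of voxels with
  PE ≥ 50% (cm³),
- **WF** — washout fraction, the percentage of tumor voxels with
  PE ≥ 50% and SER ≥ 1.1.

A 108-feature radiomics catalog (shape, first-order, GLCM, GLRLM,
GLSZM, GLDM, NGTDM; implemented from scratch and verified against
brute-force enumeration) describes the 120 s post-contrast volume, and
a statistics layer relates everything to MVD: two-reader count merging
(mean, adjudication flag at a difference ≥ 12), median dichotomization
(low ≤ median < high), Wilcoxon rank-sum tests, per-1-SD logistic odds
ratios, AUC with DeLong confidence intervals, Spearman sensitivity
analysis, Bonferroni threshold α = 0.05/4 = 0.0125 for the four kinetic
parameters and a screen at α = 0.01 for the radiomics features.

Because no patient images accompany the measurements this methodology
comes from, the `phantom` module generates seeded synthetic lesions
whose kinetic classes (washout / plateau / persistent) hit designed
PE/SER targets exactly, and cohorts whose MVD counts are
negative-binomially coupled to the designed washout burden — known
ground truth for every downstream stage.

## Worked example

```bash
python examples/kinetic_summary.py
```

```
peak PE  :  223.3 %   (designed 220)
peak SER :   1.92     (designed 1.90)
FTV      :  0.897 cm^3 (designed 0.897)
WF       :   40.0 %   (designed 40.0)
voxels   : 1104 washout / 2760 enhancing / 2760 tumor
```

A lesion designed with a 40% washout class is recovered exactly; the
small peak-PE excess over the designed 220% is the expected upward bias
of a hot-spot maximum under additive image noise (sd 2 on a baseline of
100). On a cohort (`python examples/mvd_association.py`, 27 lesions
with group WF medians 22.5% and 50.6%):

```
   variable  odds_ratio_per_sd   auc  auc_ci_lo  auc_ci_hi  p_wilcoxon  spearman_r  significant
peak_pe_pct              1.279 0.567      0.334      0.774       0.581       0.035        False
   peak_ser              1.445 0.567      0.329      0.777       0.581       0.162        False
    ftv_cm3              0.540 0.342      0.167      0.573       0.172      -0.339        False
     wf_pct              2.697 0.744      0.517      0.888       0.032       0.483        False
```

WF — the designed group separator — posts the largest AUC of the four
kinetic rows, while peak PE and FTV, which carry no designed MVD
signal, sit near 0.5. Other examples cover lesion simulation, the
radiomics vector and the full pipeline (`examples/full_pipeline.py`),
and the `angiokin` CLI wraps the same functionality
(`angiokin run --seed 1 --out myrun`).

## Layout

- `src/angiokin/phantom.py` — synthetic lesions/cohorts with ground truth
- `src/angiokin/kinetics.py` — PE/SER maps, hot spots, FTV, WF, NIfTI I/O
- `src/angiokin/radiomics/` — preprocessing, texture matrices, the
  108-name catalog (`catalog.json`)
- `src/angiokin/stats.py` — MVD merging and the association battery
- `src/angiokin/pipeline.py`, `cli.py` — orchestration and CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
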