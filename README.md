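# coroqca

Automated 3D quantitative coronary angiography (QCA) lesion quantification and
myocardial-infarction risk statistics, with a fully synthetic cohort generator
so the entire pipeline is testable without clinical data.

## The problem

Mild coronary lesions (≤ 50% diameter stenosis) are usually left untreated,
yet some of them destabilise and cause a myocardial infarction (MI) years
later. On a 3D-reconstructed vessel, QCA software measures the lumen
cross-sectional area A(s) along the centerline arc length s. Against an
interpolated *reference* line R(s) — the lumen the vessel would have if it
were healthy — a lesion is the segment containing the minimum lumen area
(MLA), delimited by the two edges where A crosses R. This package computes
the anatomical descriptors of that segment:

    MLR  = MLA / PROXA                       minimum lumen ratio
    LSL  = s_dist − s_prox                   lesion segment length (mm)
    PLSL = s_mla − s_prox                    proximal lesion segment length (mm)
    LLR  = PLSL / LSL
    %AS  = (1 − MLA / R(s_mla)) · 100        percent area stenosis

where PROXA/DISTA are the lumen areas at the proximal/distal edge. A low MLR
means the lumen collapses sharply just downstream of the lesion entrance — a
converging-flow geometry that concentrates the pressure drop (by Bernoulli,
loss scales like 1/A²) and marks lesions at risk. From a vessel pressure-ratio
profile (vFFR — the computational estimate of fractional flow reserve) the
package reads the distal vFFR and the translesional gradient
ΔvFFR = v(s_prox) − v(s_dist).

The statistical layer reproduces the standard prediction workflow on a cohort
of *future culprit lesions* (FCL: the vessel of the later MI) vs *non-culprit
lesions* (NCL: other vessels of the same patients): Mann–Whitney group
comparisons with Bonferroni adjustment, Spearman correlations, ROC/AUC with
DeLong confidence intervals, Youden-J optimal cutoffs, and Kaplan–Meier /
Cox survival for the dichotomised metric.

Because no per-vessel clinical data are distributable, the package ships a
synthetic-cohort generator whose defaults encode the summary statistics of a
published registry (80 patients, 188 vessels, 65% NSTEMI, median follow-up
25.9 months; per-group median/IQR of every metric; the reported MLR–ΔvFFR and
MLR–vFFR rank correlations). Crucially, the generator *inverse-constructs*
an actual area profile and pressure profile for every drawn vessel, and the
analysis table is populated by re-measuring them through the same code path a
real vessel would take. See `docs/methods.md` for the model and its
limitations.

## Worked example

```bash
coroqca simulate --out runs/demo --seed 42
coroqca analyze --cohort runs/demo/cohort.csv --out runs/demo-stats
coroqca report --report runs/demo-stats/report.json
```

prints (abridged):

```
Cohort: 188 vessels from 80 patients

Group comparison (median [IQR], Bonferroni-adjusted p):
  MLR      FCL 0.433  vs  NCL 0.52   p_adj=0.000163
  MLA      FCL 2.36  vs  NCL 3.04   p_adj=0.0986
  dvffr    FCL 0.0723  vs  NCL 0.0455   p_adj=0.000359
Spearman MLR-dvffr: r=-0.263 (p=0.000263, n=188)

ROC (any_mi):
  MLR      AUC 0.683 (95% CI 0.605-0.761, p=4.05e-06)
  MLA      AUC 0.609 (95% CI 0.527-0.690, p=0.00891)
  dvffr    AUC 0.675 (95% CI 0.595-0.756, p=1.96e-05)

Youden cutoff MLR: 0.4836 (sens 0.75, spec 0.63, J=0.38)
Survival (any_mi) MLR < 0.4836: HR 3.12 (95% CI 1.88-5.18, log-rank p=3.66e-06)
```

Reading: on this 188-vessel synthetic cohort the re-measured MLR separates
future culprit from non-culprit lesions (medians 0.43 vs 0.52; AUC 0.68 at
this sample size), outperforms MLA, correlates negatively with the
translesional pressure gradient (r = −0.26), and lesions below the Youden
cutoff carry a ~3-fold hazard of MI with a confidence interval excluding 1.

To quantify your own vessels, supply geometry as JSON
(`{"vessel_id", "points": [[x,y,z]...], "areas": [...]}` or contour
`sections`) or CSV (`vessel_id, s_mm, area_mm2`), optionally joined with a
vFFR CSV (`vessel_id, s_mm, vffr`):

```bash
coroqca quantify vessel.json --vffr vessel_vffr.csv --out runs/q
```

All lengths are mm, areas mm², rows ordered proximal → distal.

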