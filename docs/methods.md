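# Methods

This note documents the models, algorithms and numerical conventions of
`coroqca`: what each stage computes, which choices were genuinely open, why
the defaults are what they are, and what the synthetic cohort does and does
not establish about real angiographic data.

## 1. Vessel geometry and the reference line

A vessel is an arc-length-parameterised lumen area function A(s) (mm² over
mm), sampled proximal → distal. Input may be per-point areas along a 3D
centerline (arc length computed as the cumulative polyline length) or planar
contour polygons (converted by the shoelace formula). Profiles are resampled
to a uniform 0.1 mm grid with monotone (PCHIP) interpolation before any
detection — sub-voxel for angiographic reconstructions, and fine enough that
edge locations are grid-stable.

**Reference ("healthy") line.** Commercial QCA systems interpolate a
reference lumen across the lesion from the adjacent non-diseased segments;
the interpolation algorithm itself is proprietary and undocumented, so this
package uses a documented stand-in rather than a reverse-engineering claim:

* fit the *equivalent diameter* d(s) = 2√(A/π) with a straight line in s —
  linear-diameter tapering is the long-standing QCA convention, and working
  in the diameter domain keeps the fit linear for vessels that taper
  linearly in calibre;
* seed the fit from the proximal and distal 20% of the vessel (the flanking
  segments a reference interpolates across; an all-samples seed can be
  captured by a long lesion and never recover);
* iterate trimmed least squares: discard samples with residual
  < −3·σ, refit on the retained set, repeat until the retained set is stable
  (≤ 20 passes, re-entry allowed). σ is a MAD-type scale estimated from the
  *positive* residual side only, because diseased samples all lie below the
  line: a two-sided MAD of the censored retained set shrinks every pass and
  trimming then cascades into the healthy cloud. The 3σ threshold must clear
  the measurement noise — with a 1σ threshold the refit drifts upward ~0.5σ
  per pass and the retained set collapses;
* map back to area, R = π(d/2)². Fewer than 25% retained samples raises a
  degenerate-vessel error (a reference is meaningless on a diffusely
  diseased profile), as does a fitted lumen reaching zero.

For a noiseless linear-*diameter* taper the fit is exact; a profile linear in
*area* is √-curved in the diameter domain and is recovered only to the
curvature level (≈2% over a typical vessel) — an inherent property of the
diameter-domain convention, exercised in the tests.

## 2. Lesion detection and metrics

The below-reference run containing the global minimum of A defines the
lesion; grid ties for the minimum break toward the most proximal sample
(the converging-flow reading of MLR). Edges are the linearly interpolated
zero crossings of A − R nearest the MLA on each side, with |A − R| < 1e−9
treated as a crossing (grazing contact). A run touching a vessel end has no
crossing on that side and raises an ostial/truncated-lesion error, mirroring
the clinical exclusion of ostial lesions. A vessel with A ≥ R everywhere has
no lesion (`None`, not an error). Other below-reference runs are available
behind an `--all-lesions` flag for exploration; the primary path reports one
lesion per vessel.

%AS uses the reference area at the MLA section, not PROXA — a PROXA-based
stenosis would equal 1 − MLR exactly and carry no information.

## 3. Translesional hemodynamics

vFFR profiles are *inputs* (or synthetic surrogates); no pressure physics is
computed here. Distal vFFR is the last profile sample ("distal segment of
the vessel" is not otherwise defined; the endpoint read is the simplest
documented convention). ΔvFFR = v(s_prox) − v(s_dist), with v read by linear
interpolation at the detected edge arc lengths. Non-monotone (noisy)
profiles are accepted; a negative gradient is returned as-is with a warning,
so measured anomalies surface instead of being silently clipped.

## 4. The synthetic cohort

### Marginals

Each metric's per-group distribution is a two-piece (split) normal — the
minimal family matching a median and an asymmetric IQR — truncated to its
natural support (ratios in (0,1); areas/lengths positive with generous
physical ceilings; lesion lengths at least 3 mm / 1.5 mm for LSL / PLSL,
below which a "lesion segment" is not measurable at 0.1 mm resolution).
For right-skewed metrics the support truncation is not negligible (ΔvFFR and
PLSL put 7–9% of untruncated mass below zero), so the three parameters are
solved numerically such that the *truncated* distribution reproduces the
configured quartile triplet; where truncation is negligible this reduces to
the closed form m = q50, s1 = (q50−q25)/0.6745, s2 = (q75−q50)/0.6745.

### Joint structure

Metrics are linked by a Gaussian copula (Spearman → latent Pearson via
ρ_P = 2 sin(πρ_S/6)). The configured MLR–ΔvFFR (−0.26) and MLR–vFFR (+0.15)
targets are *pooled* correlations over both groups; since the groups differ
in location, pooling adds rank correlation on top of the within-group
dependence, so the within-group copula values are calibrated by solving
ρ_S,pooled(ρ_w) = target with ρ_S = 12·E[F̄x F̄y] − 3 evaluated by 48-node
Gauss–Hermite quadrature (deterministic; e.g. a pooled −0.26 needs ρ_w ≈
−0.19 under the default marginals). Three additional within-group
correlations are feasibility devices, documented and configurable:
MLA–MLR = +0.3 (keeps the emergent PROXA spread near its configured
quartiles), LSL–PLSL = +0.7 (part–whole dependence; cuts infeasible
PLSL ≥ LSL draws from ~20% to ~5%), ΔvFFR–vFFR = −0.5 (the translesional
drop is a component of 1 − vFFR; reduces clipping). No other dependence
information is available, so all remaining pairs are independent in the
copula.

Only MLR, MLA, LSL, PLSL, ΔvFFR and distal vFFR are sampled. PROXA is
*derived* as MLA/MLR — the three quantities are algebraically linked, so at
most two can be controlled; MLR and MLA are the ones carrying the headline
results. DISTA emerges from the constructed taper and LLR from PLSL/LSL.
Consequences, measured at n = 10⁴/group: emergent PROXA quartiles sit within
~8% of the configured triplets; the LLR median comes out ≈ 0.45 rather than
the configured groups' ≈ 0.53 (nothing in the available summary statistics
pins the PLSL/LSL dependence that would raise it); the PLSL marginal shifts
≤ ~11% at the quartiles because infeasible draws (PLSL outside
(0.05, 0.95)·LSL) are redrawn conditionally on the vessel's LSL latent —
which preserves the LSL marginal exactly.

### Inverse geometry construction

Each draw becomes an area profile on the 0.1 mm grid (landmarks snapped to
the grid; ≤ 0.05 mm quantisation, recorded as the nominal draw):

* reference: linear-diameter taper through PROXA at the proximal edge,
  losing 0.45% of diameter per mm (a mild physiological taper; it places the
  emergent DISTA medians at the configured values);
* lesion: *absolute* quarter-sine descents from each edge value down to MLA
  at s_mla — transversal at the edges, smooth at the minimum, and guaranteed
  to have the global minimum exactly at the prescribed place and value even
  for long lesions where a taper-relative carve would displace it (the
  binding feasibility condition is MLA < R(s_mla); shallower draws are
  skipped and replaced, as are draws with MLA ≥ 0.93·R at the distal edge);
* small compensatory *shoulders* straddling each edge (height
  min(0.01, 0.03·depth)·R, half-width 1.5 mm, fading inside the lesion
  within the shorter side), as seen on real area functions where plaque
  displaces lumen into the adjacent segment. They guarantee a band of
  measured area strictly above the fitted reference next to each edge, so
  noise excursions elsewhere form *separate* below-reference runs instead of
  smearing the detected crossings;
* smooth multiplicative measurement noise (0.25% of area, 0.5 mm correlation
  length, also capped at 2% of the lesion depth) on the healthy segments
  only. The lesion carve itself stays deterministic: a flat-bottomed lesion
  plus bottom noise would let the detected minimum wander along the bottom
  and break the prescribed MLA/PLSL placement;
* healthy margins of max(10, 0.35·LSL) mm on each side.

Measured back through the full stack, the default generator reproduces each
vessel's MLR within 0.003 (audited bound 0.01), MLA essentially exactly, and
LSL/PLSL within ≈2% (99th percentile 1.9%, worst case 2.5% — the systematic
part is the crossing shift the shoulders introduce, ≈ h/depth ≤ 3% of the
side length).

The vFFR surrogate is a monotone profile from 1.0 to the drawn distal value;
the drawn ΔvFFR share of the total drop (clipped to ≤ 1 − vFFR, with a
warning) is distributed over the detected lesion proportionally to 1/A(s)²
— the Bernoulli-motivated weighting — and the remainder uniformly per mm
outside, with the detected edge positions inserted into the grid so the
edge reads are exact. It is a shape surrogate, not a physics computation.

### Cohort assembly

Every patient carries exactly one FCL (event = 1 at the patient's event
time) and round-robin-assigned NCL vessels censored at the same time (under
the defaults: 28 patients with 2 NCL, 52 with 1 → 2.35 vessels/patient).
Event times come from the split normal fitted to quartiles
(21.9, 25.9, 29.8) months truncated to (1, 60); exactly
round(0.65·n_patients) patients are labelled NSTEMI, the label pattern laid
out deterministically over the patient index and the assignment shuffled by
the seeded generator. All randomness flows from one `numpy` Generator seeded
by `config.seed`, so cohorts are byte-reproducible.

### What the generator does not emulate

Real lesion morphology (eccentric plaque, serial lesions, bifurcations),
image segmentation error structure, within-patient correlation of metrics
beyond shared censoring times, and any dependence between metrics not listed
above. Two study-level quantities are *structurally* out of the family's
reach and are reported as computed rather than forced: the pooled MLR AUC
comes out ≈ 0.69 instead of the reported 0.75 (with split normals calibrated
to the group quartiles the FCL upper and NCL lower half-widths are the fat,
overlapping sides; 0.75 would require symmetric-normal tails — note 0.69
still lies inside the reported 95% CI of 0.68–0.82), and the re-measured FCL
ΔvFFR median lands near 0.074 rather than 0.080 because the physical clip
ΔvFFR ≤ 1 − vFFR trims the upper tail of draws the copula makes feasible
only approximately. Passing tests therefore show the *measurement and
statistics stack* is correct under controlled conditions — not that the
generator reproduces real angiographic variability.

## 5. Statistics

* **Mann–Whitney U**, two-sided: exact enumeration when the combined sample
  is < 16 without ties (testable against a brute-force permutation oracle),
  tie-corrected normal approximation otherwise; Bonferroni adjustment with
  m = 9 (the comparison-table metric count) by default, configurable.
* **Spearman** with midrank ties and t-approximation p (scipy).
* **ROC/AUC** by Mann–Whitney pair counting with half credit for ties;
  variance by the DeLong structural components (V10 per event, V01 per
  non-event; var = S10/m + S01/n), Wald 95% CI clipped to [0,1], two-sided
  p against AUC = 0.5. Orientation is declared per metric and never
  auto-flipped — silent flipping manufactures optimistic AUCs.
* **Youden cutoff**: scan of midpoints between consecutive distinct scores
  plus the two degenerate classify-all/none thresholds (J = 0); ties in J
  break toward higher specificity.
* **Survival**: strata metric < threshold vs ≥ threshold (strict `<` for the
  low stratum); product-limit Kaplan–Meier per stratum; hazard ratio from a
  single-covariate Cox fit with Efron tie handling (ties are heavy because
  all of a patient's vessels share one censoring time), CI from the
  coefficient standard error; log-rank p alongside. Vessels are analysed as
  independent units — no within-patient clustering correction — which
  matches the study design being emulated and is a known limitation.

The DeLong implementation is checked against exhaustive pair counting (exact
for n ≤ 50), against scikit-learn's AUC as an independent oracle, and by CI
coverage (92–98% over 1,000 two-Gaussian simulations with the closed-form
true AUC Φ(Δμ/√(σ₁²+σ₂²))). The Cox path is checked by recovering a known
rate ratio of 2 from exponential samples (n = 2,000/stratum, estimate
required in [1.8, 2.2]).

## 6. Problem sizes and runtime

The packaged default cohort (188 vessels) generates in well under a second.
Cohort-level recovery checks run at 10,000 vessels per group (sampling error
on a median ≈ 0.002, on an AUC ≈ 0.004) and 100,000 event-time draws —
about half a minute on one CPU; these sizes are the package's chosen
operating points for separating generator bias from sampling noise. All
tolerances asserted in the test suite are stated next to the computation
they check.

## 7. Known limitations

* The reference-line algorithm is a documented convention, not the
  commercial one; absolute metric values on real vessels may differ
  systematically from a CAAS-style analysis even where rankings agree.
* One lesion per vessel is quantified on the primary path.
* The split-normal/copula cohort is exchangeable within group; hierarchical
  (patient-level) effects beyond shared censoring are absent, so clustered
  standard errors cannot be exercised on it.
* The vFFR surrogate's in-lesion 1/A² weighting is a plausibility device;
  only the edge values (ΔvFFR, distal vFFR) are calibrated, not the pullback
  shape between them.
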