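# Methods

## Forward model

The digital phantom is a homogeneous slab body of anterior–posterior (AP)
thickness *T* containing uniform-activity source regions. A region is
described by its projected pixel footprint, its AP extent *x*, and the
distance *a* from the posterior body surface to its posterior edge. For a
detector viewing through *d* cm of overlying tissue, the detected count
rate of a source slab of thickness *x* integrates exponential attenuation
over the source depth:

    R = k · A · e^(−μd) · (1 − e^(−μx)) / (μx)

with *k* the camera sensitivity (cps/MBq) and *μ* the *effective* linear
attenuation coefficient. μ is deliberately broad-beam: it absorbs scatter
for the camera/energy-window combination, exactly as it is measured in
the depth-series calibration, so no separate scatter model is used.
Anterior images are left-right mirrored relative to posterior images, as
on a physical gantry. Box kidneys have a constant AP chord; ellipsoid
kidneys get an analytic elliptic chord evaluated at each pixel center
(no sub-pixel integration). Box kidneys exist specifically so that the
quantification estimators can be checked for *exact* inversion of the
forward model. Counting noise is Poisson per pixel on rate × dwell time.

Whole-body scans (10 cm/min in the emulated protocol) are modeled as
static images with an effective per-pixel dwell time; the default of
240 s is the time a point spends inside a 40-cm field of view at that
scan speed. This keeps all quantification in count-rate units matching
*k* in cps/MBq.

## Calibration

`fit_depth_series` fits log(rate) vs. depth by unweighted ordinary least
squares; *k* is the extrapolated zero-depth intercept divided by the
source activity and *μ* is minus the slope. The model is exactly
linearizable, and calibration counts are large (a 330 MBq source imaged
for 300 s), so log-domain heteroscedasticity is negligible; the noiseless
fit recovers (k, μ) to machine precision, and the Monte-Carlo tests show
both parameters within 2 % of truth in ≥ 95 of 100 noisy realizations.
R² is reported on the log scale.

## Quantification

The conjugate-view estimator uses the geometric mean of the
background-corrected anterior and posterior kidney ROI rates:

    A = sqrt(R_A · R_P) · e^(μT/2) · μx / (k · (e^(μx/2) − e^(−μx/2)))

The exponent signs are fixed by the requirement that the estimator
exactly inverts the noiseless slab forward model — for a box source the
depth *a* cancels in the geometric mean, which is the CV method's key
property. The posterior-only estimator

    A = R_P · e^(μa) · μx / (k · (1 − e^(−μx)))

corrects the overlying attenuation explicitly and therefore inherits a
bias of exactly e^(μΔa) when the assumed depth is wrong by Δa. Both
thickness factors tend to 1 as x → 0.

Background subtraction follows the thickness-scaling rule: the
background ROI samples activity across the full body thickness *T*,
while at kidney pixels only *T − x* of background tissue remains, so the
background per-pixel rate is scaled by (T − x)/T before subtraction.
This is an approximation — it ignores where in depth the background
tissue sits relative to the kidney — and the synthetic patients
reproduce that geometry (background split into compartments in front of
and behind the kidney) so the residual error of the rule is present in
the simulations, as it is in practice. Negative corrected rates are
clamped to zero and flagged. Partial-kidney ROIs (used when overlapping
uptake obscures part of the organ) are extrapolated by pixel count,
assuming uniform counts per pixel; this is exact for the uniform sources
simulated here and unbiased in expectation under Poisson noise.

## Kinetics and cumulated activity

Measured activities are decay-corrected (multiplied by e^(+λ_phys·t),
λ_phys = ln 2 / 6.647 d for ¹⁷⁷Lu), then fitted with
A(t) = A₀·e^(−λ_bio·t) by nonlinear least squares on the *linear* scale,
seeded by a log-linear regression. Linear-scale fitting was chosen
because a log-domain fit would over-weight the small late values that
dominate the tail uncertainty. R² is reported on the linear scale. The
effective decay constant is λ_eff = λ_bio + λ_phys — the only reading
that makes Ã = A₀/λ_eff dimensionally consistent with fitting
decay-corrected data — and the cumulated activity is the closed-form
integral Ã = A₀/λ_eff, cross-checked against numerical quadrature to
10⁻⁶ relative tolerance. When the fitted retention is still rising
strongly enough that λ_eff ≤ 0 the integral diverges; such fits
propagate as flagged "unbounded" values so cohort code can count and
exclude them instead of failing. The 30-min infusion period is ignored:
t = 0 is infusion onset.

## Dose

Mean absorbed kidney dose is the local-deposition (MIRD-style) self-dose

    D [Gy] = Ã [decays] · nE · φ / m [kg]

with nE = 147 keV per decay for ¹⁷⁷Lu electrons (1 keV =
1.602177×10⁻¹⁶ J), absorbed fraction φ = 1, and the kidney mass *m* from
a CT-style ellipsoid approximation m = (π/6)·L·W·x·ρ at ρ = 1.05 g/cm³.
Photon cross-dose from the rest of the body is a single optional term:
(Ã_wb − Ã_kidneys) times a user-supplied whole-body-to-kidney S value —
no default S value is shipped, since it depends on the phantom family
used. Standard geometries implement the ICRP 89 reference masses (310 g
for men, 275 g for women, both kidneys — halved per kidney, since the
dose equation operates per kidney) with MIRD-5 body dimensions (trunk
20 cm / kidney 6 cm for men, 18 / 5 cm for women).

## Synthetic cohorts and what they show

The cohort studies run on synthetic patients built from the phantom, so
every comparison exercises the same code path as a real analysis
(projection → ROI rates → background correction → estimator → fit →
dose).

*Reduced time points.* The generator mixes the two retention patterns
seen clinically: ~65 % of kidneys peak at the first image and clear
biexponentially (fast component half-life 10–30 h carrying 35–65 % of
the activity, slow component 100–250 h), and ~35 % show an uptake phase
(half-life 5–15 h) over a 60–150 h clearance, peaking around day 1.
Initial activities are 100–300 MBq — a few percent of a typical 7.4 GBq
administration — with a whole-body background carrying 15 % of the
administration and clearing with an 80-h half-life. On 200 such series,
omitting the day-7 image yields the largest mean |dose ratio − 1| of
the four possible omissions and drives a substantial fraction of the
late-peak kidneys to unbounded refits; omitting any earlier point is
comparatively benign. Because the bounded day-7-omission ratios come
from kidneys whose tail was anchored mainly by that point, their mean is
an *underestimate* of the true error — the diverging fits are excluded.

*CV vs. PA.* Patients are simulated with kidneys 1–3 cm deeper than the
depth the PA analysis assumes; the PA dose is then biased low by
e^(−μΔa) per kidney while CV is unaffected, and a paired t-test detects
the difference at p < 0.001 with 20 patients.

*Standard vs. patient-specific sizes.* Synthetic patients span
per-kidney masses 60–250 g with the kidney axes scaled isotropically
(x ∝ m^(1/3)) around the 155 g / 6 cm reference and the trunk held at
the reference 20 cm, isolating the organ-size effect. The
standard-to-specific dose ratio then falls monotonically with the true
mass — small kidneys are underdosed, large ones overdosed — dominated by
the m_standard/m_specific factor, modulated by the thickness terms.

What these simulations do *not* capture: collimator blur and septal
penetration, overlapping high-uptake organs (liver, spleen, intestine),
kidney motion and repositioning between sessions, and inhomogeneous
intra-organ uptake. Passing tests therefore validate the estimators and
the relative behavior of the method variants under controlled geometry,
not the absolute clinical accuracy of planar dosimetry.

## Numerical choices and edge cases

* μ = 0 degenerates gracefully everywhere (projection uses the linear
  limit; thickness factors evaluate to 1).
* The CV/PA thickness factors use the analytic x → 0 limit rather than
  dividing by zero.
* A depth-independent calibration series returns μ = 0 exactly; a rising
  series (negative fitted μ) is rejected rather than clamped.
* Fits that fail to converge fall back to the log-linear seed.
* All cohort statistics use the n−1 standard-deviation denominator;
  comparisons against printed table values round half-up at the printed
  precision.
* Seeds are threaded through `numpy.random.default_rng`; every
  simulation is reproducible given its seed, and per-patient sub-seeds
  are drawn below 2³¹.

## Packaged data

`data/table2_doses.tsv` is a verbatim transcription of a published
33-patient table of per-kidney, per-cycle absorbed dose per administered
activity with the patients' kidney thickness, mass, trunk thickness and
sex, and the original NA/ND/NP missing-data markers preserved (including
one pair of adjacent patients with duplicated cycle-1–3 values, kept as
printed). The summary operations reproduce that table's published
statistics exactly at printed precision.

## Known limitations

The PA method requires the kidney depth, which the phantom provides
exactly; in practice it must come from CT and is the method's dominant
error source. The mono-exponential model cannot represent an uptake
phase followed by clearance within one bounded fit — that is a property
of the published procedure, reproduced deliberately, not a limitation of
the implementation. Remainder-of-body dose depends entirely on the
supplied S value and whole-body kinetics.
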