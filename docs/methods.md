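# Methods

`tautrt` quantifies dynamic tau-PET scans with reference-tissue models and
characterizes the test–retest (T-RT) reliability of the resulting outcome
measures. Because real subject scans of this kind are rarely shareable, the
package ships a synthetic phantom generator that reproduces the statistical
structure of a short-interval T-RT study in older cognitively normal (oCN)
and Alzheimer's disease (AD) cohorts, and the full pipeline is exercised
end-to-end on those phantoms.

## Temporal model

All times are minutes post-injection; activity concentrations are kBq/mL.
The default acquisition is a two-segment 37-frame dynamic schedule — 29
frames over 0–65 min (6×10 s, 6×20 s, 2×30 s, 2×60 s, 2×120 s, 11×300 s) and
8×300 s frames over 80–120 min — with a 15-min subject break in between.

A frame's stored value is the *time average* of the underlying continuous
concentration over the frame (reconstructed-frame semantics), never an
instantaneous sample. Consequently the running integrals used by the
linearized kinetic models treat the curve as piecewise constant on frames.
Across the acquisition break the curve is bridged by the straight line
through the midpoints of the two adjacent frames; this is a modeling choice
(any bridge is an assumption — the data contain no samples there) and it is
exact whenever the underlying curve is locally linear across the break,
which late-time washout curves nearly are. Before the first frame start the
first frame value is extended as a constant; with schedules starting at
t = 0 this path never contributes.

## Outcome measures

**SUV.** SUV = C̄ / (D/W) with C̄ the unweighted mean concentration over the
frames fully inside the late window (90–110 min by default, exactly four
5-min frames), D the injected dose and W body weight; with D in MBq and W in
kg the normalizer D/W is in kBq/g and SUV carries g/mL. **SUVR** is the
ratio of two SUVs computed on identical windows and identical
partial-volume-correction status; mixing PVC and non-PVC values inside one
ratio is a hard error.

**SRTM.** The simplified reference tissue model

  C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·[C_R ⊗ e^(−k2a·t)](t),  k2a = k2/(1+BP)

is fitted by basis functions: k2a is scanned on a 256-point log-spaced grid
over [10⁻³, 1] min⁻¹; for each k2a the model is linear in (R1, β) and solved
by weighted least squares in closed form; the grid minimizer of the weighted
residual sum of squares is then refined by bounded 1-D minimization between
its grid neighbors. Weights are frame durations (a count-statistics proxy).
This is deterministic and avoids nonlinear-optimizer seed sensitivity.
Degenerate targets (identically zero) are errors; a ridge-flat RSS surface
(e.g. target ≡ reference, where k2 is unidentifiable) is flagged in the
diagnostics and BP pinned at 0; a best k2a at the grid boundary sets a
warning flag.

The forward convolution is *not* evaluated on a dense grid: for a piecewise
constant input (with a linear bridge across the break) the convolution state
obeys a scalar linear ODE whose per-segment solution is available in closed
form, so both the frame-end states and the within-frame averages are exact
up to floating point. The test suite cross-checks this against an
independent `scipy.integrate.solve_ivp` solution restarted at each frame
boundary.

**MRTM2.** With the reference efflux k2′ fixed, frames with midpoint ≥ t*
(default t* = 30 min, k2′ = 0.04 min⁻¹, interpreted per minute) enter a
duration-weighted linear regression

  C_T(T) = γ1·[∫₀ᵀ C_R + C_R(T)/k2′] + γ2·∫₀ᵀ C_T,   DVR = −γ1/γ2.

For a target generated by SRTM from the reference, this relation is exact at
all T when k2′ equals the implied reference efflux k2/R1, with γ1 = R1·k2′
and γ2 = −k2a — hence the recovery property DVR = 1 + BP that the tests and
the acceptance script verify to well under 1%. t* is applied to frame
midpoints; the t*-rule matters only under model mismatch or noise.

**Iterative Yang PVC.** Given a full tessellation of the grid into regions
(voxels outside every named region form an implicit background region), each
iteration builds the piecewise-constant regional-mean image m_k from the
current estimate, forms the voxelwise correction map m_k / G(m_k) where G is
the Gaussian PSF (σ = FWHM/2.3548 per axis in voxel units, isotropic in mm,
nearest-edge extension at borders), and multiplies the *original* data by
the map; 10 iterations and FWHM 5 mm by default (the FWHM should match the
scanner's effective resolution and is configurable). Denominator voxels
below 10⁻⁶ of the robust (99.9th-percentile) maximum get correction factor 1.
Uniform images are exact fixed points, as are images already piecewise
constant on the labels; correction is equivariant under intensity scaling.

## Region machinery

Morphology is mm-aware via Euclidean distance transforms with the physical
voxel size. Erosion removes voxels within the stated distance of the mask
boundary; the distance to the boundary *surface* is estimated as the
distance-transform value minus half the mean voxel size (the surface runs
between voxel centers), with a strict inequality at the threshold. The
offset keeps eroded volumes stable (<10% change) under grid refinement and
makes an erosion by exactly one voxel size remove the boundary layer.
Dilation (used for the extracerebral shell) keeps plain center-to-center
distances, which already track the continuous-geometry volume well. The
shell is the dilation of the cortical mask (default 5 mm, configurable down
to 2 mm) minus all brain voxels, so it is disjoint from every cerebral
region by construction.

Derived regions provided as presets: 3-mm eroded cerebellar grey, 4-mm
eroded cerebral white matter, whole cerebellum (grey ∪ white), inferior
cerebellum (cerebellar grey minus a supplied superior-cerebellum mask — the
template registration that would produce that mask on real data is out of
scope), and the meta-temporal composite of six temporal-lobe structures
(entorhinal, parahippocampus, amygdala, fusiform, inferior and middle
temporal). Left/right pairs are merged by pooling voxels before averaging —
the volume-weighted mean — rather than averaging two hemisphere means;
identical region definitions applied to test and retest volumes give
voxel-identical masks.

## Reliability statistics

T-RT% = 200·|test − retest| / (test + retest): symmetric, scale-invariant,
bounded in [0, 200). For Gaussian session pairs with within-subject CV c its
expectation is (200√2/√π)·c ≈ 112.8·c, the calibration the acceptance suite
checks at c = 0.05.

ICC is the two-way single-measure coefficient from the subjects × sessions
mean-squares decomposition. The default form is two-way random-effects
absolute agreement (ICC(A,1)); the consistency form (ICC(C,1)) is available
by flag, since study reports often do not state which was used. 95%
confidence intervals follow the standard F-based formulas (McGraw & Wong);
the implementation is cross-checked against `pingouin.intraclass_corr` in
the tests. Qualitative bands: <0.5 poor, 0.5–0.75 moderate, 0.75–0.9 good,
>0.9 excellent, with boundary values assigned to the higher band (the
verbal definitions are open intervals; a deterministic convention is
required). Zero total variance yields a flagged undefined result; zero
within-subject variance yields ICC = 1 with an explanatory message. Note
that the single-measure estimator is biased low at small n (about −0.035 at
n = 7 for a true value of 0.9), which matters when interpreting per-region
estimates from 7-subject cohorts (sampling SD ≈ 0.25).

Bland–Altman bias is mean(test − retest) with limits of agreement ±1.96 SD
of the differences; paired comparisons use the exact Wilcoxon signed-rank
distribution where available (zeros dropped), rank association uses
Spearman's ρ with midranks, cross-region comparisons use Kruskal–Wallis.
No multiple-comparison adjustment is applied anywhere. AD subjects are
excluded from ICC computation by default (they inflate between-subject
variance for reasons unrelated to measurement reliability); they still
contribute to T-RT% and Bland–Altman summaries.

## Synthetic phantoms: what they emulate

Geometry: a 64³ grid at 2 mm isotropic voxels holds a spherical brain
(radius 50 mm) containing a cerebellar grey-matter annulus (the reference
region), cerebellar white matter, pons, a cerebral white-matter core, nine
target blobs — including an entorhinal-like region of ~650 voxels, the
smallest structure of interest — nonspecific surrounding tissue, and a 5-mm
extracerebral shell built by dilating the brain surface. The grid is small
enough for minutes-scale tests yet large enough for 5-mm morphology.

Kinetics: the reference input is a fast rise (rate 2 min⁻¹, peak < 5 min)
times a bi-exponential washout, with amplitude calibrated so the reference
SUV(90–110) sits near 0.55 g/mL at 185 MBq / 74 kg — the middle of the
published cognitively-normal reference-region range (0.35–0.72 g/mL).
Every other region follows SRTM around that input with per-group (yCN, oCN,
AD) truth tables of (R1, BP); k2 is set to R1·0.04 min⁻¹ so the implied
reference efflux equals the default analysis k2′, making the phantom
internally consistent with the MRTM2 settings. Truth BP values are
calibrated so *group-mean* regional SUVR lands inside the published bands
(oCN ≈ 0.6–1.2; AD up to ≈ 2.8 in the precuneus) and oCN R1 truths span
0.66–1.39. Between-subject variability: a global amplitude factor
(CV 0.20, clamped so the reference SUV stays in its band), additive
per-region R1 jitter (SD 0.10, clamped to [0.66, 1.39]) and DVR jitter
(SD 0.10, loose safety clamps only — hard per-subject clamping to the group
band would truncate exactly the between-subject variance that produces
realistic ICC). The extracerebral shell follows a slow accumulation curve
A(1 − e^(−0.02t)) calibrated to SUVR ≈ 1.38, with lognormal between-subject
amplitude (CV 0.4) and a smooth multiplicative spatial heterogeneity field
(SD 0.3, normalized to mean 1 over the shell) fixed per subject.

Acquisition: regional time-activity curves are painted into the label map,
each frame is blurred with the Gaussian PSF (5 mm default — the partial
volume generator), and zero-mean Gaussian noise is added with SD =
noise_cv · value · √(5 min / duration), i.e. noise_cv (default 0.03) is the
CV at 300-s frames. The noise is white; reconstructed-PET noise is spatially
correlated, so voxel-level noise properties are not emulated — regional
means, which the pipeline uses, are.

Test–retest: both sessions share one subject truth and one label volume.
Each session independently draws multiplicative session-state factors: one
global scale (CV 0.05 — the dose/weight analogue, cancels in ratios) and one
factor per region with class-specific CV (reference 0.02, target 0.05,
extracerebral 0.12). The factors multiply the *measured* (post-blur)
signal: applied before blurring, independent per-region factors would be
partially averaged with neighboring tissue and the realized within-subject
CV would undershoot the nominal one by ~30%. With these defaults the
generated cohorts show reference SUV T-RT ≈ 6%, target SUVR/DVR/R1 T-RT ≈
5–7%, extracerebral SUVR T-RT ≈ 13–14% — the qualitative ~2× contrast
between shell and targets — and SUVR ICC mostly in the moderate-to-good
range (~0.5–0.8). The generated ICCs sit at the lower end of published
values because PSF mixing shrinks measured between-subject contrast while
the session CVs are held at their nominal values; passing tests therefore
demonstrate correct statistical machinery and realistic T-RT magnitudes,
not a claim that the phantom reproduces any specific cohort's reliability.

What the phantoms do *not* emulate: real anatomy (no template brains),
scanner physics (no sinograms, attenuation, motion, scatter), arterial
input functions (outcomes are reference-normalized only), sinus off-target
uptake, and spatially correlated reconstruction noise. Passing tests show
the estimators and the pipeline are correct and well-calibrated under the
stated model, not that they are robust to everything real data contains.

## Pipeline and determinism

The pipeline consumes a cohort (simulated in memory or a NIfTI + TSV
manifest on disk), optionally applies PVC (both corrected and uncorrected
outcome sets are then produced and never mixed), samples all regions,
computes SUV for every region, SUVR against the configured reference
(cerebellar grey by default; all eight candidate references can be compared
in one pass because SUVR is rebuilt from the SUV table), and DVR/R1 for
target regions whenever the schedule supports dynamic modeling (first frame
within 2 min, ≥12 frames, ≥3 frames past t*). Failed kinetic fits produce
NaN rows plus a machine-readable error log; they never abort a cohort.
Reports carry per-region/outcome T-RT% (mean ± SD), ICC with CI and band,
Bland–Altman bias and limits, and Wilcoxon p. Fixed row order, column order
and float formatting make rerunning a given config + seed byte-identical.
All randomness flows from explicit seeds through `numpy.random.SeedSequence`.

## Problem sizes used in the shipped analyses

The test suite and the acceptance script run: a 12-point (R1 × BP) recovery
grid for SRTM and MRTM2; 100 noisy replicates for MRTM2 robustness; 48³
phantoms for PVC recovery; 10,000 pairs for the T-RT% calibration; 1,000
7-subject replicates for ICC recovery (variance components σ_b = 0.15,
σ_w = 0.05, the high-reliability regime typical of reference regions); one
full 37-frame 7-subject oCN cohort through the complete dynamic pipeline;
and 10–20 window-only replicate cohorts for the extracerebral-contrast
property. Window-only cohorts simulate just the four late frames, which is
sufficient for every SUVR-based quantity and keeps replicate studies cheap.

## Known limitations

- The acquisition-break bridge is an assumption; alternative bridges change
  late integrals by well under 1% for washout-shaped curves but are not
  selectable.
- MRTM2 is fitted by ordinary weighted least squares; noise in ∫C_T induces
  the usual regression-dilution bias at high noise (the shipped check bounds
  the median bias at 5% frame CV).
- PVC assumes the label map tessellates the volume and the PSF is a known
  isotropic Gaussian; PSF mismatch degrades restoration gracefully but is
  not corrected for.
- The generator's group profiles are calibrated to published *ranges*, not
  to any subject-level data (none are available); distributional claims
  beyond those ranges should not be read into it.
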