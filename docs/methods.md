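# Methods

This note documents the models implemented in `gratiomap`, the numerical
choices behind them, what the synthetic phantom does and does not
emulate, and the known limitations. It states no result that the test
suite or `scripts/acceptance.py` does not itself compute.

## MTsat myelin mapping

The three FLASH volumes are modeled with the rational small-angle
spoiled-gradient-echo approximation

    S = A · α · R1 · TR / (R1 · TR + α²/2 + δ),

with δ = 0 for the PD- and T1-weighted acquisitions and δ the apparent
MT saturation for the MT-weighted one. The mapping equations for R1app,
Aapp and δapp are the exact algebraic inversion of this model, so on
noise-free data with homogeneous B1 the round trip is exact to machine
precision (the test suite asserts ≤ 1e-6). An important property used
throughout: δapp is invariant under any global rescaling of the three
signals, so arbitrary scanner units never matter.

Protocol defaults follow the emulated acquisition: PD/MT-weighted
TR 24 ms at 5°, T1-weighted TR 10 ms at 13°, flip angles accepted in
degrees at every interface and converted to radians internally (the
α²/2 term requires radians).

**B1 correction.** The double-angle method estimates the actual flip
angle as arccos(S₂α/(2Sα)) from acquisitions at 10° and 20°. At small
flip angles this arccos is numerically ill-conditioned — a 1% error on
the signal ratio moves the estimated flip by several degrees — so the
phantom models the B1 pair as what it physically is, a dedicated
high-SNR calibration acquisition (default SNR 500 versus 30 for the
imaging volumes), and the pipeline median-filters the resulting map
(kernel 3), exploiting the spatial smoothness of the transmit field.
δapp is then corrected with the empirical dilution form
δ·(1−C)/(1−C·B1), C = 0.4, from the MTsat literature; this is
approximate, and with the default ±5% B1 gradient it leaves a small
shared bias in MVF (visible as the fitted calibration factor landing
near 7.4–7.7 when the simulated ground-truth coupling is 8.0). The bias
is common to all subjects and cancels in group comparisons.

**MVF calibration.** MVF = c·δapp with a single scalar c, fitted by
bracketed root finding (brentq on c ∈ [1e-3, 100], xtol 1e-6) so that
the mean aggregate g-ratio over a designated calibration region equals
the 0.70 anchor. The ROI-mean g is strictly decreasing in c wherever
δ > 0 and Vic > 0, so the root is unique; if the target is outside the
attainable range (e.g. δ ≡ 0) the error message reports the attainable
g interval. MVF is clamped to [0, 1]; NaN (invalid) voxels propagate and
are excluded from every ROI mean, never zero-filled. The phantom
provides a homogeneous white-matter calibration block whose true g-ratio
is exactly 0.70 by construction (Vic solved from MVF and Viso), standing
in for the corpus-callosum calibration cohort of a real study.

## NODDI fitting

Three compartments on b0-normalized signals:

    S = (1−Viso)·[Vic·A_ic + (1−Vic)·A_ec] + Viso·exp(−b·d_iso)

* Intra-neurite: sticks with Watson-distributed orientations,
  A_ic = E[exp(−b·d∥(g·n)²)].
* Extra-neurite: Gaussian with tortuosity coupling d⊥ = d∥(1−Vic),
  dispersion-averaged axially/radially using E[cos²θ] of the Watson
  distribution.
* Free water: isotropic mono-exponential.

Fixed diffusivities d∥ = 1.7e−3 mm²/s and d_iso = 3.0e−3 mm²/s — the
standard brain parameterization, exposed in the options for
cord-specific overrides since no cord-specific values are established.

**Watson-stick kernel.** A_ic is evaluated by spherical (Funk–Hecke)
convolution in an even Legendre basis truncated at l = 20: the kernel
coefficients ∫exp(−x t²)P_l(t)dt by 64-point Gauss–Legendre quadrature
(exact at this smoothness), and the Watson coefficients E[P_l(cosθ)]
from the even moments of cosθ. The moments use the confluent
hypergeometric form M(j+½, j+3/2, κ)/(2j+1) for κ < 20 and a scaled
Dawson-function forward recursion (stable in that regime) above.
Truncation at l = 20 keeps the kernel within ~1e-9 of brute-force
spherical quadrature over the tested κ ∈ [0, 64] range and within 1e-3
of the exact stick limit even at κ = 10⁴. b = 0 coefficients are set
exactly so S(b=0) = 1 identically.

**Fitting.** Per voxel: signals normalized by the mean b=0 volume;
initialization by an 8×8×8 lattice search over (Vic, Viso, ODI) with the
direction seeded from a weighted log-linear tensor fit (used only for
initialization); refinement by Levenberg–Marquardt on transformed
coordinates — logit(Vic), logit(Viso), log κ, spherical angles — which
keeps the box constraints smooth without explicit bounds. LM was chosen
over a bounded trust-region method because the transformed problem is
unconstrained and LM's per-voxel overhead is several-fold lower, which
matters for the cohort simulations; tolerances are set tight
(1e-12) so noise-free recovery is exact to ~1e-9. The fit is fully
deterministic: no random numbers anywhere in initialization or
refinement. ODI = (2/π)·arctan(1/κ). Directions are reported in the
z ≥ 0 hemisphere (antipodal symmetry). Voxels with fitted Viso > 0.95
are flagged non-identifiable (Vic is meaningless in pure free water).

## g-ratio maps

AVF = (1−MVF)(1−Viso)·Vic and g = √(AVF/(MVF+AVF)), elementwise and
NaN-propagating; MVF+AVF = 0 yields NaN with a QC flag. For any valid
fraction triple, g ∈ [0, 1] and MVF + AVF ≤ 1 (property-tested). Because
cord-edge voxels in real data are dominated by partial volume and
registration error, ROI statistics by default erode the cord mask by one
in-plane voxel (configurable).

## Tract extraction and statistics

Per tract and side, metrics are summarized as the probability-weighted
mean Σwᵢmᵢ/Σwᵢ over analysis-level voxels with w > 0, excluding
NaN/QC-invalid voxels; the effective voxel count Σw is reported. The
atlas is assumed co-registered (the phantom emits it natively; real data
would be registered with external tools first — registration is out of
scope).

Group comparison: per tract × metric, one-way ANOVA over affected /
unaffected / control sides with Scheffé's post hoc test — the pairwise p
is the survival probability of F_pair/(k−1) under F(k−1, N−k) — at
α = 0.05 with no multiplicity correction across tracts or metrics,
matching the emulated study's reporting. For k = 2 the Scheffé p equals
the ANOVA p (verified numerically). Demographics: Pearson chi-square
without continuity correction for sex, Mann–Whitney U with tie-corrected
normal approximation for age. Clinical correlations use Spearman's rank
correlation, an interpretive choice: the disability score is ordinal.

## The synthetic phantom

Geometry: a straight cylindrical cord (fibers along z) of radius 5
voxels inside a CSF canal, on a default 24×24×8 grid at 1×1×4 mm; a
central gray-matter core (45% of the cord radius) and white matter
around it; left/right tract masks by angular sector (gracilis dorsal
medial, cuneatus dorsal lateral, lateral corticospinal tract lateral);
the probabilistic atlas is the lightly blurred binary mask (σ = 0.4
voxels), so left/right stay disjoint at p ≥ 0.5. A homogeneous
white-matter block in a grid corner serves as the calibration region.
One analysis slice stands in for the vertebral level above the
stenosis.

Tissue defaults (white matter): MVF 0.32, Vic 0.55, Viso 0.05, κ = 16,
R1 1.1 s⁻¹ — giving a true white-matter g-ratio of ≈ 0.725, inside the
histological 0.6–0.81 band. δ_true = MVF/8 (≈ 4% saturation in white
matter). Smooth ±3% spatial heterogeneity is applied inside the cord
(not in the calibration block, whose homogeneity makes the calibration
root exact).

Cohorts: default 20 patients (11 left-, 2 right-, 7 bilaterally
affected — so 27 affected and 13 unaffected sides) and 5 controls (10
normal sides). Pathology: affected-side Vic reduced by 15% in all three
tracts with MVF unchanged (axon loss, preserved myelin). Between-subject
biology: multiplicative jitter on baseline MVF and Vic with total SD 3%,
split evenly between a whole-subject factor and independent left/right
factors, so the two sides of one subject are correlated but not
identical. Noise: Rician (|signal + complex Gaussian|) at SNR 30
referenced to white-matter b=0/PD signal. All randomness derives from
one integer seed via `numpy.random.SeedSequence` spawning, so identical
specs reproduce byte-identical cohorts and per-subject streams are
independent.

What the phantom does **not** emulate — and hence what passing tests do
not show about real data: susceptibility distortion, motion, cord
curvature, CSF pulsation, partial-volume mixing at tissue boundaries,
imperfect registration (the atlas is exact by construction), crossing
fibers, or exchange/multi-compartment T1 effects on MTsat. The FLASH
forward model is the same rational approximation the inversion assumes,
which makes the inversion surface analytic; real FLASH signals deviate
from it at larger flip angles.

## Problem sizes and runtimes

The test suite's cohort experiments use a 24×24×4 grid with one analysis
slice and NODDI fitting restricted to cord voxels at that level (~80
voxels/subject, ~9 ms/voxel), so a 25-subject cohort runs in ~20 s and
the 20-replicate cohort experiment in ~6–7 min. These sizes are the
package's demonstration scale; every pipeline stage is resolution-
agnostic and accepts full-size volumes.

## Known limitations

* The NODDI parameterization is the brain-optimized one; cord-specific
  diffusivities may differ.
* The B1 dilution correction is empirical and first-order; residual MVF
  bias of a few percent remains under inhomogeneous B1 (shared across
  groups).
* The Rician noise floor biases Vic slightly upward at b = 2000 near the
  floor; no noise-floor subtraction is applied by default (an option
  exists in the fit only as future work — the current release relies on
  the floor being equal across groups).
* Sides of one subject are treated as independent observations in the
  ANOVA, as in the emulated study design; the per-side jitter structure
  makes this approximately valid in simulation, but it remains a
  simplification.
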