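# Methods

## Signal model

One MP2RAGE cycle of length `tr_mp2rage` consists of an inversion pulse
(efficiency `inv_eff`, default 1.0), a relaxation gap TA, a turbo-GRE block
of `n_exc` excitations at flip angle α₁ spaced `tr_gre`, a gap TB, a second
block at α₂, and a final gap TC. With linear phase encoding the k-space
centre of each block coincides with its middle excitation, i.e. with TI₁
and TI₂; the reported signal is sin(α)·Mz just before that excitation.

Every stage acts affinely on the longitudinal magnetization,
Mz → A·Mz + B: an excitation scales by cos α, relaxation over t maps
Mz → Mz·e^(−t/T1) + M0·(1 − e^(−t/T1)), and a block of n
excitation/relaxation cycles composes in closed form through the geometric
series of r = cos α · e^(−tr_gre/T1). The periodic steady state is the
fixed point Mz\* = B_cycle/(1 − A_cycle) of the whole-cycle composition.
An independent oracle (`bloch_signals`) steps Mz through the inversion,
every one of the 2·n_exc pulses and every gap until successive cycles agree
to 1e−14·M0; closed form and stepper agree to better than 1e−8·M0 over
T1 ∈ [0.3, 5] s and B1 scales 0.8–1.2 (they agree to machine precision;
the tested bound is deliberately loose).

Assumptions: signals are real-valued (magnitude with sign); TE/T2\* decay
and proton-density weighting are not modelled because the UNI ratio cancels
them — that cancellation is the reason MP2RAGE T1 maps are considered
"pure" T1. The transmit-field scale multiplies both excitation flip angles
but not the inversion, which is assumed adiabatic. The inversion efficiency
default of 1.0 affects absolute calibration only; all recovery claims in
this package are self-consistent (simulate and reconstruct with the same
protocol object), and no absolute calibration against scanner data is
claimed.

## Lookup inversion

UNI(T1) is tabulated on a 1 ms grid over 0.3–5.0 s and restricted to its
largest strictly monotone branch (for the default protocol: strictly
decreasing from 0.3 s to ≈4.23 s). The 1 ms step is an order of magnitude
below the smallest tissue effect of interest (the −4 ms NAWM shift).
Inversion is linear interpolation; UNI values outside the branch range are
clamped to the branch edge and flagged, and flagged voxels are excluded
(never imputed) downstream. Because CSF must reconstruct inside the branch,
the phantom's default CSF T1 is 4.0 s — a value chosen for numerical
placement within the branch rather than as a physiological claim; CSF is
never an analysis ROI here.

## Phantom

Geometry is a concentric-shell head: CSF rim (outer radius 0.45·N voxels),
cortical-GM ribbon (0.40·N), WM core (0.33·N), with non-overlapping
spherical lesions sampled uniformly inside the core (bounded rejection
sampling; placement failure raises rather than silently overlapping). A
configurable fraction of lesions is labelled enhancing; EL ⊆ WML holds by
construction. Default tissue medians are the 7 T cohort values listed in
the README. Per-voxel T1 is drawn Gaussian around the tissue centre with
configurable spread, truncated positive (default spread 0: the uniform case
makes recovery exact and residual errors attributable to the pipeline).

The gadolinium effect is static — one post-contrast time point, as in an
acquisition ≈10 min after injection — and either a direct per-tissue ΔT1
shift or the relaxivity relation 1/T1_post = 1/T1_pre + r1·C. The realized
per-voxel shift field is stored, so generated truth is recoverable to
machine precision regardless of spread. There is no within-lesion spatial
structure beyond the per-voxel spread; real lesions show scattered,
heterogeneous ΔT1, so passing recovery tests here demonstrates pipeline
correctness, not robustness to lesion texture.

Noise: i.i.d. complex Gaussian of standard deviation `noise_sigma` (in m0
units) is added to both GRE readouts; magnitudes are then exactly Rician
(background mean σ·√(π/2)), and the UNI ratio is computed from the complex
signals as a phase-sensitive reconstruction would. SNR is defined on the
second-inversion readout of a T1 = 1.3 s (white-matter) voxel:
`sigma_for_snr(protocol, 30)` returns the σ giving INV2 SNR 30, ≈0.0017·m0
for the default protocol. This is the conventional image-SNR meaning;
defining σ relative to m0 itself would conflate the magnetization scale
with the much smaller readout signal (≈0.05·m0 at 5°). Noise and
misalignment are also the mechanism by which real ΔT1 maps acquire a small
proportion of positive voxels in shortening-only tissue, which the phantom
reproduces.

B1⁺ inhomogeneity is modelled as a linear flip-angle scale gradient along
the last axis (optional, off by default); pre/post misalignment as a 6-DOF
rigid transform of the post acquisition about the volume centre, resampled
trilinearly.

## Pipeline

Brain masking thresholds the background-suppressed T1-weighted product
inv2·(UNI + 0.5) at 5 % (configurable) of its 99th-percentile robust
maximum. Registration is rigid (6-DOF) — appropriate for same-session
pre/post brain MRI — using SimpleITK's correlation metric with a 4×/2×/1×
multi-resolution schedule; a known simulated misalignment can instead be
inverted exactly. On the default phantom a 2-voxel shift is recovered to
&lt;0.01 voxel and a 0.5-voxel subvoxel shift to &lt;0.2 voxel. The ΔT1
convention is post − pre, so gadolinium shortening is negative.

## ROI and group statistics

Per-subject metrics use the sample (n−1) variance, linear-interpolation
quartiles, and Pearson (non-excess) kurtosis; quartile method and kurtosis
convention are arguments because both conventions vary across software and
affect small-n values. The kurtosis default follows the observation that
cohort lesion kurtosis medians sit near 5–6, i.e. on the normal=3 scale.
Group summaries always aggregate per-subject medians (median-of-medians),
never pooled voxels; pooled voxel vectors exist separately for voxel-wise
correlation and KDE figures (Gaussian kernel, Silverman bandwidth).

Rank tests switch at combined n = 12 between exact enumeration (midranks;
two-sided p = min(1, 2·min(lower tail, upper tail)), hence p = 1 for
identical samples) and tie-corrected, continuity-corrected normal
approximations (scipy). Under null simulations the Mann-Whitney test
rejects at 5.0 % ± 2 % over 2000 replicates. Partial correlation is
residual-based (rank-transform first for the Spearman flavour) with a
t-reference on n − k − 2 degrees of freedom. The logistic treatment model
is a maximum-likelihood fit with Wald p-values; non-convergence and
separation (|β| &gt; 1000) are flagged and coefficients withheld.
Benjamini-Hochberg is the statsmodels step-up implementation. Note that BH
is *not* idempotent in general (re-adjusting [0.03, 0.03, 0.04] yields
[0.04, 0.04, 0.04]); the package asserts monotonicity and order
preservation instead.

## Simulated cohort

Subject-level NEL ΔT1 centres follow an additive model: baseline −0.105 s
(treated, relapsing-remitting, low disability) plus −0.040 s for
progressive phenotype, −0.030 s if untreated, −0.035 s for above-median
EDSS, with between-subject SD 0.055 s. The additive effects are smaller
than the observed marginal group differences (≈−0.04 to −0.07 s) because
the groups overlap: progressive subjects are more often untreated and more
disabled, and the marginal contrasts of the generated cohort land near
those observed values. Demographics (age, sex ratio, EDSS grids, treated
fractions per phenotype, symptom duration, cognitive/motor scores) follow
the published cohort composition of 47 subjects with 13 progressive. One
master seed fans out per-subject seeds that drive both covariate draws and
that subject's phantom, so a cohort is fully reproducible from one integer.

## Problem sizes and numerical choices

Recovery analyses use 64³ phantoms (≈170k brain voxels, ~1 s per phase on
one CPU), registration and workflow tests 48³, and the 100-phantom mask
census 32³ — sizes chosen so the full suite exercises every path in well
under a minute of simulation time while keeping ≥100 voxels in the smallest
ROI. Degenerate inputs are contracts, not accidents: empty ROIs,
constant-value ROIs, both-zero UNI ratios, all-tied paired differences,
single-class logistic outcomes and out-of-branch UNI values each have a
defined error or flag behaviour, tested.

## Known limitations

Anatomy is schematic (no cortical folding, no lesion texture); absolute T1
calibration against any scanner implementation is out of scope (inversion
efficiency and vendor lookup details unknowable from the outside); B1⁺
correction via a measured map is not implemented (the B1 field here is a
stressor, not a correction input); no pharmacokinetics — gadolinium is a
single static shift; and clinical effect sizes on real patients are not
reproducible from simulation, so cohort-level tests assert directions and
significance structure, not published effect magnitudes.
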