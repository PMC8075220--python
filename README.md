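# deltat1

Quantitative MP2RAGE ΔT1 mapping of gadolinium-induced T1 shortening in
brain white-matter lesions — a simulation and analysis package for the
7 T imaging surrogate of blood–brain-barrier (BBB) leakage.

## The problem

Gadolinium enhancement marks acute BBB breakdown in multiple sclerosis
lesions, but most lesions do not enhance visibly even though their BBB is
often still abnormal. Because gadolinium shortens T1 in proportion to its
tissue concentration, a *quantitative* pre/post-contrast T1 difference —
the ΔT1 map, ΔT1 = T1(post) − T1(pre), negative where gadolinium
accumulates — can reveal subtle leakage in non-enhancing lesions (NELs)
that qualitative images miss.

MP2RAGE is the natural sequence for this: one acquisition yields two
inversion-time GRE readouts, GRE(TI₁) and GRE(TI₂), whose combination

UNI = Re(S₁·S₂\*) / (|S₁|² + |S₂|²)  ∈ [−0.5, +0.5]

cancels proton density, T2\* and receive-field bias, leaving a value that is
monotone in T1 for a given protocol. Inverting a simulated UNI(T1) lookup
table voxelwise gives the quantitative T1 map.

This package implements the whole chain as a tested library:

- **Signal model** (`deltat1.signal`, `deltat1.lookup`): periodic
  steady-state MP2RAGE closed form (inversion efficiency, turbo-GRE blocks,
  free relaxation gaps), an independent discrete Bloch-stepping oracle, the
  UNI combination, and lookup-table T1 estimation on a 1 ms grid.
- **Digital phantom** (`deltat1.phantom`): concentric-shell brain with
  spherical WM lesions (enhancing subset), per-tissue true T1 fields,
  direct or relaxivity-based gadolinium (1/T1_post = 1/T1_pre + r1·C),
  Rician magnitude noise, optional B1⁺ gradient and rigid pre/post
  misalignment. Exact ground truth for every downstream stage.
- **Pipeline** (`deltat1.pipeline`, `deltat1.volume`): T1-map
  reconstruction with QC flags, 6-DOF rigid registration (NCC,
  multi-resolution), ΔT1 subtraction, and lesion/tissue mask algebra
  (NEL = WML∖EL, NAWM = cerebral WM∖WML).
- **Statistics** (`deltat1.roi`, `deltat1.stats`, `deltat1.cohort`):
  per-subject ROI distribution metrics (median, variance, IQR, Pearson
  kurtosis), pooled voxel vectors and KDE summaries, paired t / Wilcoxon,
  Mann-Whitney U with exact small-sample enumeration, Spearman/Pearson and
  partial correlation, a logistic treatment model, Benjamini-Hochberg FDR,
  and a simulated clinical cohort with configurable group effects.

## Worked example

`examples/02_phantom_recovery.py` builds a noiseless 64³ phantom whose
tissues carry cohort-median 7 T values, forward-simulates both MP2RAGE
acquisitions, reconstructs T1 maps, and subtracts:

```
tissue  n_vox  true pre  recon pre  true dT1  recon dT1
nawm    38972     1.300     1.3000    -0.004    -0.0040
nel       383     1.912     1.9120    -0.134    -0.1340
el        101     2.430     2.4300    -1.100    -1.1000
cgm     30864     1.898     1.8980    -0.096    -0.0960
```

Each row compares configured ground truth (seconds) with the median of the
reconstructed map inside that tissue mask: the signal model, lookup
inversion, subtraction and mask algebra recover the truth to within one
lookup grid step. The other examples demonstrate the signal model against
its Bloch oracle (`01`), SNR-30 noise and registration robustness (`03`),
the cohort statistics (`04`), and the end-to-end run with its report
bundle (`05`).

A thin CLI mirrors the stages:

```bash
delta-t1 simulate --out out/sim --shape 48 --lesions 3 --seed 1
delta-t1 reconstruct --inv2 out/sim/inv2_pre.nii.gz --uni out/sim/uni_pre.nii.gz --out out/t1_pre.nii.gz
delta-t1 run-all --out out/demo --seed 1 --subjects 3
```

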