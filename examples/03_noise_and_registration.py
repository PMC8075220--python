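"""Robustness: Rician noise at SNR 30 and a 2-voxel pre/post misalignment.

First recovers the NEL median ΔT1 from a noisy but aligned phantom, then
repeats with the post-contrast acquisition rigidly misaligned and corrected
by NCC-based rigid registration.
"""

import numpy as np

from deltat1 import (
    PhantomConfig,
    SequenceProtocol,
    apply_gadolinium,
    build_lookup,
    build_phantom,
    compute_delta_t1,
    default_tissues,
    reconstruct_t1_map,
    register_post_to_pre,
    sigma_for_snr,
    simulate_acquisition,
)

protocol = SequenceProtocol()
lookup = build_lookup(protocol)
sigma = sigma_for_snr(protocol, snr=30.0)
print(f"noise sigma for INV2 SNR 30: {sigma:.5f} (fraction of m0)")
TRUTH = -0.134  # configured NEL delta-T1, seconds


def nel_delta_median(misalignment, register):
    config = PhantomConfig(
        shape=(64, 64, 64), lesion_count=5, lesion_radius_range=(3, 4),
        seed=3, noise_sigma=sigma, misalignment=misalignment,
    )
    gt = apply_gadolinium(build_phantom(config, default_tissues()))
    inv2_pre, uni_pre = simulate_acquisition(gt, protocol, phase="pre")
    inv2_post, uni_post = simulate_acquisition(gt, protocol, phase="post")
    transform = None
    if register:
        reg, [uni_post] = register_post_to_pre(
            inv2_post, inv2_pre, mode="estimate_rigid", extra=[uni_post]
        )
        inv2_post, transform = reg.aligned, reg.transform
    pre = reconstruct_t1_map(inv2_pre, uni_pre, protocol, lookup)
    post = reconstruct_t1_map(inv2_post, uni_post, protocol, lookup)
    delta = compute_delta_t1(pre.t1, post.t1, pre.qc_exclude, post.qc_exclude)
    return np.nanmedian(delta.data[gt.masks["nel"]]), transform


aligned, _ = nel_delta_median(None, register=False)
print(f"\naligned, SNR 30    : NEL median dT1 = {aligned:+.4f} s "
      f"(truth {TRUTH:+.3f}, error {abs(aligned - TRUTH) * 1000:.1f} ms)")

shifted, transform = nel_delta_median((2.0, 0.0, -1.0, 0, 0, 0), register=True)
print(f"misaligned+register: NEL median dT1 = {shifted:+.4f} s "
      f"(error {abs(shifted - TRUTH) * 1000:.1f} ms)")
print(f"recovered translation (truth [2, 0, -1] vox): "
      f"{np.round(transform.translation, 3)}")
print("\nThe subject-median statistic is robust to magnitude noise, and rigid")
print("registration removes the misalignment bias to the aligned-case level.")
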