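"""Phantom generator: geometry, mask algebra, gadolinium model, noise."""

import numpy as np
import pytest
from scipy import ndimage

from deltat1.exceptions import ConfigurationError, DomainError
from deltat1.phantom import (
    LABELS,
    PhantomConfig,
    TissueSpec,
    apply_gadolinium,
    build_phantom,
    default_tissues,
    sigma_for_snr,
    simulate_acquisition,
)


def test_no_lesions_means_empty_wml_and_full_nawm():
    gt = build_phantom(PhantomConfig(lesion_count=0, seed=3), default_tissues())
    assert not gt.masks["wml"].any()
    np.testing.assert_array_equal(gt.masks["nawm"], gt.masks["cerebral_wm"])


def test_requested_lesion_count_appears_as_connected_components():
    config = PhantomConfig(lesion_count=5, lesion_radius_range=(3, 3), seed=1)
    gt = build_phantom(config, default_tissues())
    _, n_components = ndimage.label(gt.masks["wml"])
    assert n_components == 5


def test_same_seed_bit_identical_different_seed_not():
    config = PhantomConfig(lesion_count=4, seed=7)
    a = build_phantom(config, default_tissues())
    b = build_phantom(config, default_tissues())
    np.testing.assert_array_equal(a.label_volume, b.label_volume)
    np.testing.assert_array_equal(a.true_t1_pre.data, b.true_t1_pre.data)
    c = build_phantom(PhantomConfig(lesion_count=4, seed=8), default_tissues())
    assert not np.array_equal(a.label_volume, c.label_volume)


def test_el_subset_of_wml_and_masks_disjoint_from_background():
    gt = build_phantom(
        PhantomConfig(lesion_count=5, el_fraction=0.4, seed=2), default_tissues()
    )
    assert not (gt.masks["el"] & ~gt.masks["wml"]).any()
    background = gt.label_volume == LABELS["BG"]
    for mask in gt.masks.as_dict().values():
        assert not (mask & background).any()


def test_direct_gadolinium_shift_arithmetic():
    # Cohort-median NEL values: pre 1.912 s shifted by -0.134 s -> 1.778 s.
    gt = build_phantom(
        PhantomConfig(lesion_count=3, seed=4), default_tissues(nel_delta=-0.134)
    )
    gt = apply_gadolinium(gt, mode="direct")
    nel = gt.masks["nel"]
    assert np.allclose(gt.true_t1_post.data[nel], 1.912 - 0.134)
    assert np.allclose(gt.true_delta_t1[nel], -0.134)


def test_relaxivity_mode_adds_to_relaxation_rate():
    tissues = [
        TissueSpec("CSF", 4.0),
        TissueSpec("CGM", 1.898),
        TissueSpec("NAWM", 2.0, r1=5.0, conc=0.02),  # 1/2 + 0.1 = 0.6 s^-1
    ]
    gt = apply_gadolinium(
        build_phantom(PhantomConfig(lesion_count=0, seed=5), tissues),
        tissues,
        mode="relaxivity",
    )
    nawm = gt.masks["nawm"]
    assert np.allclose(gt.true_t1_post.data[nawm], 1.0 / 0.6)


def test_zero_concentration_leaves_t1_unchanged():
    tissues = default_tissues()
    gt = apply_gadolinium(
        build_phantom(PhantomConfig(lesion_count=2, seed=6), tissues),
        tissues,
        mode="relaxivity",  # all default specs have conc = 0
    )
    np.testing.assert_allclose(gt.true_t1_post.data, gt.true_t1_pre.data)
    assert np.allclose(gt.true_delta_t1, 0.0)


def test_configured_delta_exactly_recoverable_with_spread():
    tissues = default_tissues(t1_spread=0.05, delta_spread=0.02)
    gt = apply_gadolinium(build_phantom(PhantomConfig(lesion_count=3, seed=9), tissues))
    np.testing.assert_allclose(
        gt.true_t1_post.data - gt.true_t1_pre.data, gt.true_delta_t1, atol=1e-14
    )


def test_excessive_shift_rejected():
    gt = build_phantom(
        PhantomConfig(lesion_count=2, seed=1), default_tissues(nel_delta=-5.0)
    )
    with pytest.raises(DomainError):
        apply_gadolinium(gt)


def test_noiseless_acquisition_matches_direct_simulation(protocol):
    from deltat1.signal import SignalPair, simulate_signals, uni_from_signals

    gt = build_phantom(PhantomConfig(lesion_count=2, seed=3), default_tissues())
    _, uni = simulate_acquisition(gt, protocol, phase="pre")
    nawm = gt.masks["nawm"]
    expected = uni_from_signals(simulate_signals(protocol, 1.300))
    assert np.allclose(uni.data[nawm], expected)


def test_background_magnitude_has_rician_zero_signal_mean(protocol):
    sigma = 0.002
    config = PhantomConfig(lesion_count=0, seed=11, noise_sigma=sigma)
    gt = build_phantom(config, default_tissues())
    inv2, _ = simulate_acquisition(gt, protocol, config, phase="pre")
    background = inv2.data[~gt.brain]
    assert background.size >= 10_000
    expected = sigma * np.sqrt(np.pi / 2)
    assert np.mean(background) == pytest.approx(expected, rel=0.02)


def test_constant_unit_b1_field_equals_no_b1_field(protocol):
    base = PhantomConfig(lesion_count=2, seed=3)
    with_field = PhantomConfig(lesion_count=2, seed=3, b1_field=(1.0, 1.0))
    gt_a = build_phantom(base, default_tissues())
    gt_b = build_phantom(with_field, default_tissues())
    inv2_a, uni_a = simulate_acquisition(gt_a, protocol, base, phase="pre")
    inv2_b, uni_b = simulate_acquisition(gt_b, protocol, with_field, phase="pre")
    np.testing.assert_array_equal(inv2_a.data, inv2_b.data)
    np.testing.assert_array_equal(uni_a.data, uni_b.data)


def test_post_phase_requires_gadolinium(protocol):
    gt = build_phantom(PhantomConfig(lesion_count=0, seed=1), default_tissues())
    with pytest.raises(ConfigurationError):
        simulate_acquisition(gt, protocol, phase="post")


def test_sigma_for_snr_matches_reference_signal(protocol):
    from deltat1.signal import simulate_signals

    sigma = sigma_for_snr(protocol, snr=30.0)
    assert abs(simulate_signals(protocol, 1.3).s2) / sigma == pytest.approx(30.0)


def test_invalid_configs_rejected():
    with pytest.raises(ConfigurationError):
        PhantomConfig(el_fraction=1.5)
    with pytest.raises(ConfigurationError):
        PhantomConfig(lesion_radius_range=(0.0, 2.0))
    with pytest.raises(ConfigurationError):
        build_phantom(PhantomConfig(), [TissueSpec("NAWM", 1.3)])  # missing CSF/CGM
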