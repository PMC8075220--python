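"""MP2RAGE signal model: closed form vs Bloch stepper, UNI combination."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from deltat1.exceptions import ConfigurationError, DomainError
from deltat1.protocol import SequenceProtocol
from deltat1.signal import (
    SignalPair,
    bloch_signals,
    denoised_t1w,
    simulate_signals,
    uni_from_signals,
)
from deltat1.volume import Volume


@pytest.mark.parametrize("t1", [0.3, 0.9, 1.3, 1.912, 2.43, 3.7, 5.0])
@pytest.mark.parametrize("b1", [0.8, 1.0, 1.2])
def test_closed_form_matches_bloch_stepper(protocol, t1, b1):
    closed = simulate_signals(protocol, t1, b1_scale=b1)
    stepped = bloch_signals(protocol, t1, b1_scale=b1)
    assert abs(closed.s1 - stepped.s1) <= 1e-8
    assert abs(closed.s2 - stepped.s2) <= 1e-8


def test_zero_flip_angle_gives_zero_signal(protocol):
    pair = simulate_signals(protocol, 1.3, b1_scale=0.0)
    assert pair.s1 == 0.0 and pair.s2 == 0.0


def test_full_relaxation_limit_reaches_equilibrium_signal(protocol):
    # With T1 << tr_gre the magnetization recovers fully before every pulse.
    pair = simulate_signals(protocol, 1e-6)
    expected = np.sin(np.radians(5.0))
    assert pair.s1 == pytest.approx(expected, abs=1e-6)
    assert pair.s2 == pytest.approx(expected, abs=1e-6)


def test_m0_scales_signals_linearly(protocol):
    one = simulate_signals(protocol, 1.3, m0=1.0)
    two = simulate_signals(protocol, 1.3, m0=2.0)
    assert two.s1 == pytest.approx(2 * one.s1)
    assert two.s2 == pytest.approx(2 * one.s2)


def test_nonpositive_t1_rejected(protocol):
    with pytest.raises(DomainError):
        simulate_signals(protocol, -1.0)
    with pytest.raises(DomainError):
        bloch_signals(protocol, 0.0)


def test_invalid_protocol_timing_rejected():
    with pytest.raises(ConfigurationError):
        SequenceProtocol(ti1=3.0, ti2=1.0)
    with pytest.raises(ConfigurationError):
        SequenceProtocol(ti1=0.5)  # block 1 does not fit before ti1


@pytest.mark.parametrize(
    "s1, s2, expected",
    [(1.0, 1.0, 0.5), (1.0, -1.0, -0.5), (0.0, 1.0, 0.0)],
)
def test_uni_boundary_cases(s1, s2, expected):
    assert uni_from_signals(SignalPair(s1, s2)) == pytest.approx(expected)


def test_uni_undefined_for_double_zero():
    with pytest.raises(DomainError):
        uni_from_signals(SignalPair(0.0, 0.0))
    assert uni_from_signals(SignalPair(0.0, 0.0), zero_division="zero") == 0.0


@settings(max_examples=200, deadline=None)
@given(
    s1=st.floats(-1e6, 1e6, allow_nan=False),
    s2=st.floats(-1e6, 1e6, allow_nan=False),
)
def test_uni_always_bounded(s1, s2):
    if s1 == 0 and s2 == 0:
        return
    uni = uni_from_signals(SignalPair(s1, s2))
    assert -0.5 <= uni <= 0.5


def test_denoised_t1w_suppresses_background():
    shape = (4, 4, 4)
    inv2 = Volume(np.full(shape, 2.0), units="signal")
    uni = Volume(np.zeros(shape))
    out = denoised_t1w(inv2, uni)
    assert np.allclose(out.data, 1.0)
    # uni = -0.5 everywhere cancels regardless of inv2
    assert np.allclose(denoised_t1w(inv2, Volume(np.full(shape, -0.5))).data, 0.0)
    assert np.allclose(
        denoised_t1w(Volume(np.zeros(shape), units="signal"), uni).data, 0.0
    )
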