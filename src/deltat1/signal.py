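"""MP2RAGE steady-state signal model.

One MP2RAGE cycle is: inversion (efficiency ``inv_eff``) -> free relaxation
TA -> turbo-GRE block 1 (``n_exc`` excitations at ``alpha1``, spacing
``tr_gre``) -> free relaxation TB -> block 2 at ``alpha2`` -> free relaxation
TC -> next inversion.  Under linear phase encoding the k-space centre of each
block is acquired at the middle excitation, i.e. at TI1 and TI2; the model
reports sin(alpha) times the longitudinal magnetization just before that
excitation.

Every stage maps Mz affinely, Mz -> A*Mz + B: an excitation scales by
cos(alpha), a relaxation gap of duration t maps Mz -> Mz*exp(-t/T1) +
M0*(1 - exp(-t/T1)), and a block of n excitation/relaxation cycles composes
to a closed geometric-series form.  The periodic steady state is the fixed
point Mz = B_cycle / (1 - A_cycle) of the whole-cycle composition.
:func:`simulate_signals` evaluates this closed form; :func:`bloch_signals`
is an independent discrete stepper that advances Mz through every one of the
2 x n_exc pulses and relaxation gaps until the cycle converges, used as a
numerical oracle for the closed form.

TE/T2* decay and proton-density weighting are deliberately not modelled:
the UNI ratio cancels them, which is exactly why the MP2RAGE T1 map is
insensitive to them.  Signals are real-valued (magnitude with sign).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, DomainError
from .protocol import SequenceProtocol
from .volume import Volume

__all__ = [
    "SignalPair",
    "simulate_signals",
    "bloch_signals",
    "uni_from_signals",
    "denoised_t1w",
]


@dataclass
class SignalPair:
    """Centre-of-k-space GRE signals of the two inversion-time readouts.

    ``s1`` and ``s2`` are in the same arbitrary units as the equilibrium
    magnetization scale ``m0``; they may be scalars or arrays.
    """

    s1: np.ndarray | float
    s2: np.ndarray | float
    m0: np.ndarray | float = 1.0


def _relax(a, b, e, m0):
    """Compose a free-relaxation gap (decay factor e) onto Mz -> a*Mz + b."""
    return a * e, b * e + m0 * (1.0 - e)


def _block(a, b, cos_alpha, e1, k, m0):
    """Compose k excitation+relaxation cycles of a GRE block.

    One cycle maps Mz -> r*Mz + m0*(1-e1) with r = cos(alpha)*e1; k cycles
    give r^k and the geometric sum (1-r^k)/(1-r).
    """
    r = cos_alpha * e1
    rk = r**k
    regular = np.abs(1.0 - r) > 1e-15
    geo = np.where(regular, (1.0 - rk) / np.where(regular, 1.0 - r, 1.0), float(k))
    return a * rk, b * rk + m0 * (1.0 - e1) * geo


def simulate_signals(
    protocol: SequenceProtocol,
    t1,
    b1_scale=1.0,
    m0=1.0,
) -> SignalPair:
    """Closed-form periodic steady-state MP2RAGE signals.

    Parameters
    ----------
    protocol:
        Sequence timing and flip angles.
    t1:
        Longitudinal relaxation time in seconds (> 0); scalar or array.
    b1_scale:
        Transmit-field scale applied to both excitation flip angles
        (>= 0); scalar or array broadcastable against ``t1``.  The inversion
        is assumed adiabatic and is not scaled.
    m0:
        Equilibrium magnetization scale (arbitrary units).

    Returns
    -------
    SignalPair
        ``s1`` and ``s2``, each sin(alpha_i) * Mz at the block centre.
    """
    t1 = np.asarray(t1, dtype=float)
    b1 = np.asarray(b1_scale, dtype=float)
    if np.any(t1 <= 0):
        raise DomainError("t1 must be positive")
    if np.any(b1 < 0):
        raise DomainError("b1_scale must be non-negative")
    m0 = np.asarray(m0, dtype=float)

    a1 = np.radians(protocol.alpha1) * b1
    a2 = np.radians(protocol.alpha2) * b1
    cos1, sin1 = np.cos(a1), np.sin(a1)
    cos2, sin2 = np.cos(a2), np.sin(a2)
    n = protocol.n_exc
    e1 = np.exp(-protocol.tr_gre / t1)
    ea = np.exp(-protocol.ta / t1)
    eb = np.exp(-protocol.tb / t1)
    ec = np.exp(-protocol.tc / t1)

    # Whole-cycle composition starting just before the inversion.
    a, b = -protocol.inv_eff, 0.0
    a, b = _relax(a, b, ea, m0)
    a, b = _block(a, b, cos1, e1, n, m0)
    a, b = _relax(a, b, eb, m0)
    a, b = _block(a, b, cos2, e1, n, m0)
    a, b = _relax(a, b, ec, m0)
    mz_ss = b / (1.0 - a)

    # Propagate the steady state to the centre of each block.
    a, b = -protocol.inv_eff, 0.0
    a, b = _relax(a, b, ea, m0)
    a, b = _block(a, b, cos1, e1, n // 2, m0)
    s1 = sin1 * (a * mz_ss + b)
    a, b = _block(a, b, cos1, e1, n - n // 2, m0)
    a, b = _relax(a, b, eb, m0)
    a, b = _block(a, b, cos2, e1, n // 2, m0)
    s2 = sin2 * (a * mz_ss + b)
    return SignalPair(s1=s1, s2=s2, m0=m0)


def bloch_signals(
    protocol: SequenceProtocol,
    t1: float,
    b1_scale: float = 1.0,
    m0: float = 1.0,
    max_cycles: int = 200,
    tol: float = 1e-14,
) -> SignalPair:
    """Discrete Bloch-stepping oracle for :func:`simulate_signals`.

    Advances Mz pulse by pulse (inversion, each of the 2 x n_exc excitations,
    every relaxation gap) for whole cycles until the pre-inversion Mz changes
    by less than ``tol * m0`` between cycles.  Scalar inputs only; this
    exists as an independent numerical check, not a production path.
    """
    if t1 <= 0:
        raise DomainError("t1 must be positive")
    cos1 = np.cos(np.radians(protocol.alpha1) * b1_scale)
    sin1 = np.sin(np.radians(protocol.alpha1) * b1_scale)
    cos2 = np.cos(np.radians(protocol.alpha2) * b1_scale)
    sin2 = np.sin(np.radians(protocol.alpha2) * b1_scale)

    def relax(mz: float, t: float) -> float:
        e = np.exp(-t / t1)
        return mz * e + m0 * (1.0 - e)

    n = protocol.n_exc
    mz = m0
    s1 = s2 = 0.0
    for _ in range(max_cycles):
        mz_start = mz
        mz = -protocol.inv_eff * mz
        mz = relax(mz, protocol.ta)
        for k in range(n):
            if k == n // 2:
                s1 = sin1 * mz
            mz = relax(cos1 * mz, protocol.tr_gre)
        mz = relax(mz, protocol.tb)
        for k in range(n):
            if k == n // 2:
                s2 = sin2 * mz
            mz = relax(cos2 * mz, protocol.tr_gre)
        mz = relax(mz, protocol.tc)
        if abs(mz - mz_start) < tol * abs(m0):
            break
    return SignalPair(s1=s1, s2=s2, m0=m0)


def uni_from_signals(pair: SignalPair, zero_division: str = "raise"):
    """MP2RAGE uniform (UNI) combination Re(S1 S2*) / (|S1|^2 + |S2|^2).

    Bounded in [-0.5, +0.5] for any signal pair.  Works on real or complex
    scalars/arrays.  Where both signals are zero the ratio is undefined:
    with ``zero_division="raise"`` a :class:`DomainError` is raised, with
    ``"zero"`` those entries are set to 0 (useful for background voxels).
    """
    s1 = np.asarray(pair.s1)
    s2 = np.asarray(pair.s2)
    # Scale by the larger magnitude first: the ratio is scale-invariant and
    # this keeps squared magnitudes of subnormal signals from underflowing.
    scale = np.maximum(np.abs(s1), np.abs(s2))
    safe = np.where(scale == 0, 1.0, scale)
    s1 = s1 / safe
    s2 = s2 / safe
    num = np.real(s1 * np.conj(s2))
    den = np.abs(s1) ** 2 + np.abs(s2) ** 2
    undefined = den == 0
    if np.any(undefined):
        if zero_division == "raise":
            raise DomainError("UNI undefined where both signals are zero")
        if zero_division != "zero":
            raise ConfigurationError("zero_division must be 'raise' or 'zero'")
    with np.errstate(invalid="ignore", divide="ignore"):
        uni = np.where(undefined, 0.0, num / np.where(undefined, 1.0, den))
    if uni.ndim == 0:
        return float(uni)
    return uni


def denoised_t1w(inv2: Volume, uni: Volume) -> Volume:
    """Background-suppressed T1-weighted image: inv2 * (uni + 0.5).

    In background the UNI image converges to -0.5 (pure noise ratio) and the
    second-inversion magnitude to noise, so the product suppresses the salt-
    and-pepper background of the raw UNI image while keeping tissue contrast.
    Used for brain masking in reconstruction.
    """
    inv2.require_same_grid(uni)
    return Volume(inv2.data * (uni.data + 0.5), inv2.affine, units="signal")
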