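"""Digital brain phantom with white-matter lesions and a gadolinium effect.

The phantom is a concentric-shell head model: a CSF rim, a cortical-gray-
matter ribbon, and a white-matter core containing non-overlapping spherical
lesions, a configurable fraction of which are "enhancing".  It is not meant
to be anatomically realistic -- its job is to provide exact ground truth
(label map, true pre/post T1 fields, masks, applied misalignment) for every
downstream stage: forward MP2RAGE simulation, T1-map reconstruction,
registration, ΔT1 subtraction, and ROI statistics.

The gadolinium effect is static (one post-contrast time point, matching an
acquisition ~10 min after injection) and is applied either as a direct
per-tissue T1 shift or through the relaxivity relation
``1/T1_post = 1/T1_pre + r1 * C``.

Forward acquisition adds complex Gaussian noise to the two GRE readouts, so
their magnitudes are Rician -- the noise family of magnitude MRI, and the
reason real ΔT1 maps contain a small proportion of positive voxels even
where gadolinium only shortens T1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ConfigurationError, DomainError, PlacementError
from .protocol import SequenceProtocol
from .rigid import RigidTransform
from .signal import SignalPair, simulate_signals, uni_from_signals
from .volume import MaskSet, Volume

__all__ = [
    "TissueSpec",
    "PhantomConfig",
    "GroundTruth",
    "LABELS",
    "build_phantom",
    "apply_gadolinium",
    "simulate_acquisition",
    "default_tissues",
    "sigma_for_snr",
]

# Label-volume codes.
LABELS = {"BG": 0, "CSF": 1, "CGM": 2, "NAWM": 3, "NEL": 4, "EL": 5}

# Seed offsets so that the T1 draw, the gadolinium draw, and each acquisition
# phase consume independent but reproducible streams fanned out from one seed.
_SEED_T1 = 11
_SEED_GAD = 23
_SEED_ACQ = {"pre": 31, "post": 47}


@dataclass(frozen=True)
class TissueSpec:
    """Ground-truth T1 behaviour of one tissue compartment.

    ``t1_pre_center``/``t1_pre_spread`` parameterize the per-voxel
    pre-contrast T1 draw (Gaussian, truncated positive).  The gadolinium
    effect is either a direct shift (``delta_t1_center`` +- spread, seconds)
    or, in relaxivity mode, ``r1`` (s^-1 mM^-1) times concentration ``conc``
    (mM) added to the relaxation rate.
    """

    label: str
    t1_pre_center: float
    t1_pre_spread: float = 0.0
    delta_t1_center: float = 0.0
    delta_t1_spread: float = 0.0
    r1: float = 0.0
    conc: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in LABELS or self.label == "BG":
            raise ConfigurationError(
                f"tissue label must be one of {sorted(set(LABELS) - {'BG'})}, got {self.label!r}"
            )
        if self.t1_pre_center <= 0:
            raise DomainError("t1_pre_center must be positive")
        if self.r1 < 0 or self.conc < 0:
            raise DomainError("r1 and conc must be non-negative")


def default_tissues(
    nel_delta: float = -0.134,
    el_delta: float = -1.100,
    nawm_delta: float = 0.0,
    cgm_delta: float = -0.096,
    t1_spread: float = 0.0,
    delta_spread: float = 0.0,
) -> list[TissueSpec]:
    """Tissue table with cohort-median 7 T pre-contrast T1 values.

    Pre-contrast centres: NAWM 1.300 s, cGM 1.898 s, NEL 1.912 s, EL 2.430 s,
    CSF 4.0 s.  Default ΔT1 shifts are the cohort-median lesion/cortex values
    (NEL -0.134 s, EL -1.100 s, cGM -0.096 s) with NAWM defaulting to a null
    shift; all are overridable per call.
    """
    return [
        TissueSpec("CSF", 4.0, t1_spread),
        TissueSpec("CGM", 1.898, t1_spread, cgm_delta, delta_spread),
        TissueSpec("NAWM", 1.300, t1_spread, nawm_delta, delta_spread),
        TissueSpec("NEL", 1.912, t1_spread, nel_delta, delta_spread),
        TissueSpec("EL", 2.430, t1_spread, el_delta, delta_spread),
    ]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, lesion load, noise, B1 field, and misalignment of one phantom.

    ``noise_sigma`` is the standard deviation of the complex Gaussian noise
    added to each GRE readout, as a fraction of the equilibrium
    magnetization m0.  ``b1_field`` is ``None`` (uniform transmit) or
    ``(min, max)`` for a linear gradient of the flip-angle scale along the
    last axis.  ``misalignment`` is ``None`` or a 6-tuple
    (t0, t1, t2 voxels, r0, r1, r2 degrees) applied to the post-contrast
    acquisition.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 0.7
    lesion_count: int = 5
    lesion_radius_range: tuple[float, float] = (2.5, 4.0)
    el_fraction: float = 0.0
    seed: int = 0
    noise_sigma: float = 0.0
    b1_field: tuple[float, float] | None = None
    misalignment: tuple[float, float, float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ConfigurationError("shape must be 3D with at least 8 voxels per axis")
        if not (0.0 <= self.el_fraction <= 1.0):
            raise ConfigurationError("el_fraction must lie in [0, 1]")
        if self.lesion_count < 0:
            raise ConfigurationError("lesion_count must be non-negative")
        lo, hi = self.lesion_radius_range
        if not (0 < lo <= hi):
            raise ConfigurationError("lesion_radius_range must satisfy 0 < lo <= hi")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size] * 3 + [1.0])
        aff[:3, 3] = -self.voxel_size * (np.asarray(self.shape) - 1) / 2.0
        return aff

    @property
    def misalignment_transform(self) -> RigidTransform:
        if self.misalignment is None:
            return RigidTransform.identity()
        t = self.misalignment
        return RigidTransform.from_params(
            translation_vox=t[:3],
            rotation_deg=t[3:],
            center_vox=(np.asarray(self.shape, float) - 1) / 2.0,
        )


@dataclass
class GroundTruth:
    """Phantom ground truth: labels, true T1 fields, masks, and geometry."""

    label_volume: np.ndarray
    true_t1_pre: Volume
    masks: MaskSet
    config: PhantomConfig
    tissues: list[TissueSpec] = field(default_factory=list)
    true_t1_post: Volume | None = None
    true_delta_t1: np.ndarray | None = None
    applied_misalignment: RigidTransform = field(default_factory=RigidTransform.identity)

    @property
    def affine(self) -> np.ndarray:
        return self.true_t1_pre.affine

    @property
    def brain(self) -> np.ndarray:
        return self.label_volume != LABELS["BG"]


def _shell_labels(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Concentric-shell label map (CSF rim, cGM ribbon, WM core) and radius."""
    grid = np.indices(shape, dtype=float)
    center = (np.asarray(shape, float) - 1) / 2.0
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grid, center)))
    n = min(shape)
    r_brain = 0.45 * n
    r_gm_outer = 0.40 * n
    r_wm = 0.33 * n
    labels = np.zeros(shape, dtype=np.int16)
    labels[r <= r_brain] = LABELS["CSF"]
    labels[r <= r_gm_outer] = LABELS["CGM"]
    labels[r <= r_wm] = LABELS["NAWM"]
    return labels, r


def _place_lesions(
    config: PhantomConfig, r_wm: float, rng: np.random.Generator
) -> list[tuple[np.ndarray, float]]:
    """Sample non-overlapping lesion spheres wholly inside the WM core."""
    center = (np.asarray(config.shape, float) - 1) / 2.0
    placed: list[tuple[np.ndarray, float]] = []
    lo, hi = config.lesion_radius_range
    max_tries = 2000
    for _ in range(config.lesion_count):
        radius = float(rng.uniform(lo, hi))
        margin = r_wm - radius - 1.0
        if margin <= 0:
            raise PlacementError("lesion radius does not fit inside the WM core")
        for _ in range(max_tries):
            # Uniform in the admissible sphere via rejection from the cube.
            offset = rng.uniform(-margin, margin, size=3)
            if np.linalg.norm(offset) > margin:
                continue
            pos = center + offset
            if all(
                np.linalg.norm(pos - c) > radius + rr + 1.0 for c, rr in placed
            ):
                placed.append((pos, radius))
                break
        else:
            raise PlacementError(
                f"could not place lesion {len(placed) + 1}/{config.lesion_count} "
                f"without overlap after {max_tries} tries"
            )
    return placed


def _truncated_normal(
    rng: np.random.Generator, center: float, spread: float, size: int
) -> np.ndarray:
    """Gaussian draw truncated to positive values (resampled, then clipped)."""
    values = rng.normal(center, spread, size=size) if spread > 0 else np.full(size, center)
    for _ in range(10):
        bad = values <= 0
        if not bad.any():
            break
        values[bad] = rng.normal(center, spread, size=int(bad.sum()))
    return np.clip(values, 1e-3, None)


def build_phantom(config: PhantomConfig, tissues: list[TissueSpec]) -> GroundTruth:
    """Build the labelled phantom and its ground-truth pre-contrast T1 field.

    Deterministic for a given ``config.seed``.  Requires tissue specs for at
    least NAWM, CGM, and CSF; NEL/EL specs are required when lesions are
    requested.
    """
    spec_by_label = {t.label: t for t in tissues}
    for required in ("NAWM", "CGM", "CSF"):
        if required not in spec_by_label:
            raise ConfigurationError(f"missing tissue spec for {required}")
    rng = np.random.default_rng(config.seed + _SEED_T1)

    labels, _ = _shell_labels(config.shape)
    n = min(config.shape)
    if config.lesion_count > 0:
        if "NEL" not in spec_by_label:
            raise ConfigurationError("lesions requested but no NEL tissue spec given")
        n_el = int(round(config.el_fraction * config.lesion_count))
        if n_el > 0 and "EL" not in spec_by_label:
            raise ConfigurationError("enhancing lesions requested but no EL spec given")
        lesions = _place_lesions(config, r_wm=0.33 * n, rng=rng)
        grid = np.indices(config.shape, dtype=float)
        for i, (pos, radius) in enumerate(lesions):
            dist2 = sum((g - p) ** 2 for g, p in zip(grid, pos))
            inside = dist2 <= radius**2
            labels[inside] = LABELS["EL"] if i < n_el else LABELS["NEL"]

    t1_pre = np.zeros(config.shape, dtype=float)
    for label_name, code in LABELS.items():
        if label_name == "BG":
            continue
        region = labels == code
        count = int(region.sum())
        if count == 0:
            continue
        spec = spec_by_label.get(label_name)
        if spec is None:
            raise ConfigurationError(f"phantom contains {label_name} but no spec given")
        t1_pre[region] = _truncated_normal(
            rng, spec.t1_pre_center, spec.t1_pre_spread, count
        )

    wml = (labels == LABELS["NEL"]) | (labels == LABELS["EL"])
    el = labels == LABELS["EL"]
    cerebral_wm = wml | (labels == LABELS["NAWM"])
    masks = MaskSet(
        wml=wml,
        el=el,
        nel=wml & ~el,
        nawm=labels == LABELS["NAWM"],
        cgm=labels == LABELS["CGM"],
        cerebral_wm=cerebral_wm,
    )
    return GroundTruth(
        label_volume=labels,
        true_t1_pre=Volume(t1_pre, config.affine, units="s"),
        masks=masks,
        config=config,
        tissues=list(tissues),
        applied_misalignment=config.misalignment_transform,
    )


def apply_gadolinium(
    gt: GroundTruth, tissues: list[TissueSpec] | None = None, mode: str = "direct"
) -> GroundTruth:
    """Populate the post-contrast T1 field from the per-tissue gadolinium model.

    ``direct`` mode draws a per-voxel ΔT1 from each tissue's
    ``delta_t1_center`` +- ``delta_t1_spread`` and sets
    ``T1_post = T1_pre + ΔT1``; ``relaxivity`` mode adds ``r1 * conc`` to the
    relaxation rate.  The realized per-voxel ΔT1 field is stored so the
    generator's truth is exactly recoverable.
    """
    if mode not in ("direct", "relaxivity"):
        raise ConfigurationError("mode must be 'direct' or 'relaxivity'")
    tissues = list(tissues) if tissues is not None else gt.tissues
    spec_by_label = {t.label: t for t in tissues}
    rng = np.random.default_rng(gt.config.seed + _SEED_GAD)

    t1_pre = gt.true_t1_pre.data
    delta = np.zeros_like(t1_pre)
    for label_name, code in LABELS.items():
        if label_name == "BG":
            continue
        region = gt.label_volume == code
        count = int(region.sum())
        if count == 0 or label_name not in spec_by_label:
            continue
        spec = spec_by_label[label_name]
        if mode == "direct":
            if spec.delta_t1_spread > 0:
                delta[region] = rng.normal(
                    spec.delta_t1_center, spec.delta_t1_spread, size=count
                )
            else:
                delta[region] = spec.delta_t1_center
        else:
            rate = 1.0 / t1_pre[region] + spec.r1 * spec.conc
            delta[region] = 1.0 / rate - t1_pre[region]

    t1_post = t1_pre + delta
    if np.any(t1_post[gt.brain] <= 0):
        raise DomainError("gadolinium shift drives post-contrast T1 non-positive")
    return replace(
        gt,
        tissues=tissues,
        true_t1_post=Volume(t1_post, gt.affine, units="s"),
        true_delta_t1=delta,
    )


def _b1_map(config: PhantomConfig) -> np.ndarray | float:
    if config.b1_field is None:
        return 1.0
    lo, hi = config.b1_field
    ramp = np.linspace(lo, hi, config.shape[2])
    return np.broadcast_to(ramp[None, None, :], config.shape)


def sigma_for_snr(
    protocol: SequenceProtocol, snr: float, t1_ref: float = 1.3
) -> float:
    """Noise sigma (fraction of m0) giving a target SNR on the INV2 readout.

    SNR is defined as the noiseless second-inversion signal magnitude of a
    reference tissue (default white matter, T1 = 1.3 s) divided by the
    per-channel Gaussian noise standard deviation.
    """
    if snr <= 0:
        raise DomainError("snr must be positive")
    pair = simulate_signals(protocol, t1_ref)
    return float(abs(pair.s2) / snr)


def simulate_acquisition(
    gt: GroundTruth,
    protocol: SequenceProtocol,
    config: PhantomConfig | None = None,
    phase: str = "pre",
) -> tuple[Volume, Volume]:
    """Forward-simulate one MP2RAGE acquisition of the phantom.

    Returns ``(inv2, uni)``: the second-inversion magnitude image and the
    UNI ratio image.  Gaussian noise of scale ``noise_sigma`` (in m0 units)
    is added to the real and imaginary channel of each GRE readout, so the
    magnitudes are Rician; the UNI combination uses the complex signals, as
    a phase-sensitive reconstruction would.  The post-phase volumes are
    resampled by the configured rigid misalignment (trilinear).
    """
    config = config or gt.config
    if phase not in _SEED_ACQ:
        raise ConfigurationError("phase must be 'pre' or 'post'")
    if phase == "pre":
        t1_vol = gt.true_t1_pre
    else:
        if gt.true_t1_post is None:
            raise ConfigurationError(
                "post-phase acquisition requested but apply_gadolinium was not run"
            )
        t1_vol = gt.true_t1_post

    brain = gt.brain
    b1 = _b1_map(config)
    t1 = np.where(brain, t1_vol.data, 1.0)  # placeholder T1 in background
    pair = simulate_signals(protocol, t1, b1_scale=b1)
    m0 = brain.astype(float)
    s1 = np.where(brain, pair.s1, 0.0) * 1.0
    s2 = np.where(brain, pair.s2, 0.0) * 1.0

    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed + _SEED_ACQ[phase])
        sigma = config.noise_sigma
        noise = rng.standard_normal((4,) + tuple(config.shape)) * sigma
        c1 = s1 * m0 + noise[0] + 1j * noise[1]
        c2 = s2 * m0 + noise[2] + 1j * noise[3]
    else:
        c1 = s1 * m0 + 0j
        c2 = s2 * m0 + 0j

    uni = uni_from_signals(SignalPair(s1=c1, s2=c2), zero_division="zero")
    inv2 = np.abs(c2)

    if phase == "post" and not gt.applied_misalignment.is_identity:
        uni = gt.applied_misalignment.apply_to(uni, order=1, cval=0.0)
        inv2 = gt.applied_misalignment.apply_to(inv2, order=1, cval=0.0)

    affine = gt.affine
    return Volume(inv2, affine, units="signal"), Volume(uni, affine, units="dimensionless")
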