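"""MR acoustic radiation force imaging (MR-ARFI) displacement mapping.

Focused ultrasound displaces tissue by micrometers at the acoustic focus.
With a bipolar motion-encoding gradient, that displacement accumulates MR
phase; acquiring twice with opposite gradient polarity and taking the complex
phase difference ΔΦ isolates the displacement term from static phase:

    D = ΔΦ / (2 γ G τ)

with γ the proton gyromagnetic ratio (γ/2π = 42.58 MHz/T), G the gradient
magnitude (T/m) and τ the duration of each gradient lobe (s). D is the
average displacement in meters over the encoding period.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GAMMA_PROTON_RAD_PER_S_PER_T",
    "EncodingParams",
    "ARFIPair",
    "DisplacementMap",
    "MaxDisplacement",
    "phase_difference",
    "displacement_map",
    "max_displacement",
]

#: Proton gyromagnetic ratio in rad s^-1 T^-1 (gamma / 2 pi = 42.58 MHz/T).
GAMMA_PROTON_RAD_PER_S_PER_T = 2.0 * np.pi * 42.58e6


@dataclass(frozen=True)
class EncodingParams:
    """Motion-encoding-gradient parameters.

    ``tau_s`` has no universal default: displacement in meters is meaningless
    without the lobe duration actually used, so it must be supplied.
    """

    G_T_per_m: float = 0.04
    tau_s: float = None  # type: ignore[assignment]
    gamma_rad_per_s_per_T: float = GAMMA_PROTON_RAD_PER_S_PER_T
    polarity_labels: tuple[str, str] = ("plus", "minus")

    def validate(self) -> None:
        if self.tau_s is None:
            raise ValueError(
                "encoding lobe duration tau_s is required (no default exists)"
            )
        if self.G_T_per_m <= 0 or self.tau_s <= 0:
            raise ValueError("G and tau must be positive")
        if self.gamma_rad_per_s_per_T <= 0:
            raise ValueError("gamma must be positive")


@dataclass
class ARFIPair:
    """Two phase acquisitions (radians) with opposite encoding polarity."""

    phase_plus: np.ndarray
    phase_minus: np.ndarray
    encoding: EncodingParams

    def __post_init__(self) -> None:
        self.phase_plus = np.asarray(self.phase_plus, dtype=float)
        self.phase_minus = np.asarray(self.phase_minus, dtype=float)
        if self.phase_plus.shape != self.phase_minus.shape:
            raise ValueError("phase image geometries do not match")


@dataclass
class DisplacementMap:
    """Per-voxel displacement in meters, with the encoding that produced it."""

    D_m: np.ndarray
    encoding: EncodingParams

    @property
    def D_um(self) -> np.ndarray:
        return self.D_m * 1e6


@dataclass(frozen=True)
class MaxDisplacement:
    """Focal-spot maximum: value, voxel location and a detectability verdict
    (maximum must exceed ``k`` times the background noise SD)."""

    value_um: float
    index: tuple[int, ...]
    detectable: bool
    noise_sd_um: float


def phase_difference(pair: ARFIPair) -> np.ndarray:
    """Wrapped phase difference of the two acquisitions.

    Computed through the complex representation, ``angle(exp(i(Φ+ − Φ−)))``,
    so values near the ±π branch cut wrap correctly instead of jumping by 2π.
    """
    return np.angle(np.exp(1j * (pair.phase_plus - pair.phase_minus)))


def displacement_map(
    delta_phi: np.ndarray, encoding: EncodingParams
) -> DisplacementMap:
    """Convert a phase-difference map (radians) to displacement (meters):
    ``D = ΔΦ / (2 γ G τ)`` per voxel."""
    encoding.validate()
    delta_phi = np.asarray(delta_phi, dtype=float)
    D = delta_phi / (
        2.0 * encoding.gamma_rad_per_s_per_T * encoding.G_T_per_m * encoding.tau_s
    )
    return DisplacementMap(D_m=D, encoding=encoding)


def max_displacement(
    dmap: DisplacementMap,
    roi: np.ndarray | None = None,
    noise_sd_m: float | None = None,
    detect_k: float = 3.0,
) -> MaxDisplacement:
    """Maximum absolute displacement within an ROI and its voxel location.

    ``roi`` is a boolean mask (default: whole volume). The detectability
    check compares the maximum against ``detect_k`` times the background
    noise SD; if ``noise_sd_m`` is not given it is estimated robustly
    (1.4826 × median absolute deviation) from the voxels outside the ROI, or
    from the whole map when the ROI covers everything.
    """
    D = np.abs(dmap.D_m)
    if roi is None:
        roi = np.ones(D.shape, dtype=bool)
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != D.shape:
        raise ValueError("roi geometry does not match the displacement map")
    if not roi.any():
        raise ValueError("roi is empty")
    flat = np.where(roi, D, -np.inf)
    idx = np.unravel_index(np.argmax(flat), D.shape)
    value = D[idx]
    if noise_sd_m is None:
        background = dmap.D_m[~roi] if (~roi).any() else dmap.D_m[roi]
        med = np.median(background)
        noise_sd_m = 1.4826 * np.median(np.abs(background - med))
    detectable = bool(value > detect_k * noise_sd_m)
    return MaxDisplacement(
        value_um=float(value * 1e6),
        index=tuple(int(i) for i in idx),
        detectable=detectable,
        noise_sd_um=float(noise_sd_m * 1e6),
    )
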