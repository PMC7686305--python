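"""Core domain containers shared by all modules.

All times are expressed in milliseconds, flip angles in degrees, ADC in
10^-3 mm^2/s (the conventional prostate scale) and gadolinium concentration
in mmol/L.  Missing voxels in quantitative maps are NaN, never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TissueParams",
    "MRFSequenceParams",
    "ConventionalProtocol",
    "QuantitativeMap",
    "FitResult",
    "InvalidParameterError",
]

MISSING = np.nan


class InvalidParameterError(ValueError):
    """Raised when a physical parameter violates its domain."""


@dataclass(frozen=True)
class TissueParams:
    """Voxel-level tissue properties.

    Parameters
    ----------
    t1, t2 : float
        Longitudinal / transverse relaxation times, ms.  Must be positive.
        ``t2 > t1`` is physically unusual and triggers a warning but is
        accepted (calibration-phantom spheres may be configured freely).
    pd : float
        Proton density, arbitrary non-negative units.
    adc : float, optional
        Apparent diffusion coefficient, 10^-3 mm^2/s.
    off_resonance : float
        Off-resonance frequency, Hz.
    """

    t1: float
    t2: float
    pd: float = 1.0
    adc: float | None = None
    off_resonance: float = 0.0

    def __post_init__(self) -> None:
        if not (self.t1 > 0 and self.t2 > 0):
            raise InvalidParameterError(
                f"relaxation times must be positive (t1={self.t1}, t2={self.t2})"
            )
        if self.pd < 0:
            raise InvalidParameterError(f"proton density must be >= 0 (pd={self.pd})")
        if self.t2 > self.t1:
            warnings.warn(
                f"t2 ({self.t2} ms) exceeds t1 ({self.t1} ms); accepted but unusual",
                stacklevel=3,
            )
        if self.adc is not None and self.adc < 0:
            raise InvalidParameterError(f"adc must be >= 0 (adc={self.adc})")


@dataclass(frozen=True)
class MRFSequenceParams:
    """Inversion-prepared unbalanced SSFP (FISP) fingerprinting train.

    ``dephasing_per_tr`` is the net intravoxel gradient dephasing per TR in
    radians; any non-zero multiple of 2*pi yields the classic FISP regime in
    which the voxel-average echo is the F0 configuration state.
    """

    flip_angles_deg: tuple[float, ...]
    tr_ms: float = 10.0
    te_ms: float = 2.5
    inversion: bool = True
    inversion_delay_ms: float = 18.0
    dephasing_per_tr: float = 8.0 * np.pi
    rf_phase_deg: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        flips = tuple(float(a) for a in self.flip_angles_deg)
        object.__setattr__(self, "flip_angles_deg", flips)
        if len(flips) == 0:
            raise InvalidParameterError("flip-angle train must be non-empty")
        if not all(0.0 <= a <= 180.0 for a in flips):
            raise InvalidParameterError("flip angles must lie in [0, 180] degrees")
        if not (self.tr_ms > self.te_ms > 0):
            raise InvalidParameterError(
                f"need tr > te > 0 (tr={self.tr_ms}, te={self.te_ms})"
            )
        if self.rf_phase_deg is not None:
            phases = tuple(float(p) for p in self.rf_phase_deg)
            if len(phases) != len(flips):
                raise InvalidParameterError("rf_phase_deg length must match flip train")
            object.__setattr__(self, "rf_phase_deg", phases)

    @property
    def n_excitations(self) -> int:
        return len(self.flip_angles_deg)

    @property
    def train_duration_ms(self) -> float:
        """Total acquisition time of the train (one slice), ms."""
        return self.n_excitations * self.tr_ms

    def phases_rad(self) -> np.ndarray:
        if self.rf_phase_deg is None:
            return np.zeros(self.n_excitations)
        return np.deg2rad(np.asarray(self.rf_phase_deg))


_PROTOCOL_KINDS = ("IR_FSE", "VFA_SPGR", "MSE", "DWI")
_VARIED_PARAM = {"IR_FSE": "TI (ms)", "VFA_SPGR": "flip angle (deg)",
                 "MSE": "TE (ms)", "DWI": "b (s/mm^2)"}


@dataclass(frozen=True)
class ConventionalProtocol:
    """A conventional mapping protocol: one acquisition per sample point.

    ``sample_points`` holds the varied parameter: inversion times (ms) for
    IR_FSE, flip angles (deg) for VFA_SPGR, echo times (ms) for MSE, or
    b-values (s/mm^2) for DWI.
    """

    kind: str
    sample_points: tuple[float, ...]
    tr_ms: float | None = None
    te_ms: float | None = None
    seconds_per_point: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _PROTOCOL_KINDS:
            raise InvalidParameterError(
                f"unknown protocol kind {self.kind!r}; expected one of {_PROTOCOL_KINDS}"
            )
        pts = tuple(float(p) for p in self.sample_points)
        object.__setattr__(self, "sample_points", pts)
        if len(pts) < 3 and self.kind != "DWI":
            raise InvalidParameterError(f"{self.kind} needs >= 3 sample points")
        if len(pts) < 2:
            raise InvalidParameterError("need >= 2 sample points")
        if self.kind in ("IR_FSE", "MSE", "DWI"):
            if any(b <= a for a, b in zip(pts, pts[1:])):
                raise InvalidParameterError(
                    f"{_VARIED_PARAM[self.kind]} values must be strictly increasing"
                )
        else:  # VFA: positive and distinct
            if any(p <= 0 for p in pts) or len(set(pts)) != len(pts):
                raise InvalidParameterError("flip angles must be positive and distinct")

    @property
    def n_points(self) -> int:
        return len(self.sample_points)

    @property
    def total_acquisition_seconds(self) -> float | None:
        """Total scan time when per-point acquisition time is known."""
        if self.seconds_per_point is None:
            return None
        return self.seconds_per_point * self.n_points

    @property
    def varied_parameter(self) -> str:
        return _VARIED_PARAM[self.kind]


@dataclass
class QuantitativeMap:
    """A voxel grid of one physical parameter with units and phase tag."""

    data: np.ndarray
    kind: str  # e.g. "T1", "T2", "PD", "ADC", "score"
    units: str = "ms"
    phase: str = "pre"  # pre / post contrast
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.phase not in ("pre", "post"):
            raise InvalidParameterError(f"phase must be 'pre' or 'post', got {self.phase!r}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def masked_mean(self, mask: np.ndarray) -> float:
        vals = self.data[np.asarray(mask, bool)]
        vals = vals[np.isfinite(vals)]
        return float(np.mean(vals)) if vals.size else float("nan")

    def with_data(self, data: np.ndarray) -> "QuantitativeMap":
        out = QuantitativeMap(data=data, kind=self.kind, units=self.units,
                              phase=self.phase, affine=self.affine.copy())
        return out


@dataclass
class FitResult:
    """Outcome of a nonlinear least-squares relaxometry fit."""

    estimate: float
    scale: float
    residual_sse: float
    converged: bool
    n_points: int
    polarity_restored: bool = False
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.converged and not self.estimate > 0:
            raise InvalidParameterError("converged fit must have a positive estimate")
        if self.residual_sse < -1e-12:
            raise InvalidParameterError("residual SSE cannot be negative")


def derive_seed(seed: int, *indices: int) -> int:
    """Derive a reproducible sub-seed (splitmix64-style avalanche, < 2^31).

    Used to give each patient / stage its own stream so partial re-runs
    reproduce the full-run values.
    """
    mask = 2**64 - 1
    x = int(seed) & mask
    for idx in indices:
        x = (x + 0x9E3779B97F4A7C15 * (idx + 1)) & mask
        z = x
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        x = z ^ (z >> 31)
    return x % (2**31 - 1)


# convenient re-export for callers that tweak frozen dataclasses
clone = replace
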