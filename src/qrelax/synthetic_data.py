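"""Synthetic inputs: calibration phantom, virtual pelvis, contrast model.

Everything the pipelines consume is generated here, deterministically from
(spec, seed):

* a NIST-style calibration phantom (spheres with known T1/T2 on a grid);
* a schematic virtual pelvis per patient — ellipsoidal prostate with an
  inner transition zone (TZ), annular peripheral zone (PZ), muscle and fat
  patches, and ellipsoidal lesions — whose ROI-level parameter draws follow
  the bundled cohort summary distributions;
* a gadolinium contrast model (1/T_post = 1/T_pre + r * C) with per-ROI
  log-normal uptake concentrations;
* forward acquisition simulation with complex Gaussian noise and magnitude
  (Rician) detection.

Geometry is schematic by design: ROI statistics, not images, are the
product.  ROI-level draws dominate the variance; within-ROI voxel jitter is
fixed at 5% CV so across-ROI statistics mirror how the reference cohort's
CVs were computed (across ROI means).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import sequence_models as sm
from .reference_tables import MATCHED_SUBSETS, SUMMARY_TABLE
from .types import (
    ConventionalProtocol,
    InvalidParameterError,
    MRFSequenceParams,
    derive_seed,
)

__all__ = [
    "TissueClassSpec",
    "ContrastModel",
    "PhantomLayerSpec",
    "ParameterVolume",
    "default_tissue_specs",
    "default_phantom_spec",
    "make_phantom",
    "make_virtual_pelvis",
    "sample_class_roi_means",
    "apply_contrast",
    "simulate_acquisition",
    "WITHIN_ROI_CV",
]

# Within-ROI voxel jitter: small so ROI-level variance is dominated by
# between-ROI biology.
WITHIN_ROI_CV = 0.05

CLASS_NAMES = ("PZ_lesion", "TZ_lesion", "normal_PZ", "normal_TZ", "muscle", "fat")

_CLASS_TO_ROW = {
    "PZ_lesion": "PZ lesions",
    "TZ_lesion": "TZ lesions",
    "normal_PZ": "Normal PZ",
    "normal_TZ": "Normal TZ",
    "muscle": "Muscle",
    "fat": "Fat",
}

# Default per-class GBCA uptake (mean mmol/L, CV).  Derived by the
# delta-method calibration in scripts/calibrate_uptake.py so the simulated
# cohort's post-contrast means and CV pattern track the bundled summary
# tables (strong, highly variable uptake in TZ lesions and normal TZ; weak
# homogeneous uptake in muscle and normal PZ).
DEFAULT_UPTAKE = {
    "PZ_lesion": (0.235, 0.93),
    "TZ_lesion": (0.29, 2.0),
    "normal_PZ": (0.082, 0.33),
    "normal_TZ": (0.285, 1.5),
    "muscle": (0.036, 0.31),
    "fat": (0.145, 0.9),
}

# Normal-TZ ROI means are a two-component mixture conditioned on whether the
# patient hosts a TZ lesion (lesion hosts show longer, BPH-dominated T1).
# Components are expressed in standardised units of the class (mean, sd) so
# the pooled mixture reproduces the class distribution for any spec values,
# and setting sd = 0 collapses every draw to the class mean.
_NTZ_HOST_FRACTION = 9.0 / 14.0


def _ntz_mixture_components() -> tuple[tuple[float, float], tuple[float, float]]:
    m, s = SUMMARY_TABLE["Normal TZ"]["MRF_T1_pre"]
    mh, sh = MATCHED_SUBSETS["Normal TZ (matched)"]["MRF_T1_pre"]
    w = _NTZ_HOST_FRACTION
    m_nh = (m - w * mh) / (1.0 - w)
    var_nh = (s**2 - w * (sh**2 + (mh - m) ** 2)) / (1.0 - w) - (m_nh - m) ** 2
    if var_nh <= 0:  # pragma: no cover - guarded by bundled constants
        raise InvalidParameterError("inconsistent normal-TZ mixture constants")
    # standardized (offset/sd-ratio) form
    return ((mh - m) / s, sh / s), ((m_nh - m) / s, np.sqrt(var_nh) / s)


_NTZ_HOST_STD, _NTZ_NONHOST_STD = _ntz_mixture_components()

# Correlation between a lesion's ROI mean T1 and the host patient's
# normal-tissue ROI mean (shared patient-level physiology); marginals of
# both classes are preserved exactly.
LESION_NORMAL_RHO = 0.8


@dataclass(frozen=True)
class TissueClassSpec:
    """Truth distribution of one tissue class (ROI-level means)."""

    name: str
    t1_mean_ms: float
    t1_sd_ms: float
    t2_mean_ms: float
    t2_sd_ms: float
    adc_mean: float
    adc_sd: float
    gbca_uptake_mean: float = 0.0
    gbca_uptake_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in CLASS_NAMES:
            raise InvalidParameterError(f"unknown tissue class {self.name!r}")
        if min(self.t1_mean_ms, self.t2_mean_ms, self.adc_mean) <= 0:
            raise InvalidParameterError("class means must be positive")
        if min(self.t1_sd_ms, self.t2_sd_ms, self.adc_sd,
               self.gbca_uptake_mean, self.gbca_uptake_cv) < 0:
            raise InvalidParameterError("SDs, uptake mean and CV must be >= 0")


def default_tissue_specs() -> dict[str, TissueClassSpec]:
    """Class specs whose pre-contrast columns equal the bundled summary table."""
    specs = {}
    for name in CLASS_NAMES:
        row = SUMMARY_TABLE[_CLASS_TO_ROW[name]]
        (t1m, t1s), (t2m, t2s), (am, asd) = row["MRF_T1_pre"], row["MRF_T2_pre"], row["ADC_pre"]
        um, ucv = DEFAULT_UPTAKE[name]
        specs[name] = TissueClassSpec(
            name=name, t1_mean_ms=t1m, t1_sd_ms=t1s, t2_mean_ms=t2m, t2_sd_ms=t2s,
            adc_mean=am, adc_sd=asd, gbca_uptake_mean=um, gbca_uptake_cv=ucv,
        )
    return specs


@dataclass(frozen=True)
class ContrastModel:
    """Gadolinium relaxivities, L mmol^-1 s^-1 (gadobutrol-like at 3 T)."""

    r1: float = 5.0
    r2: float = 6.0

    def __post_init__(self) -> None:
        if not (self.r1 > 0 and self.r2 > 0):
            raise InvalidParameterError("relaxivities must be positive")
        if self.r2 < self.r1:
            raise InvalidParameterError("transverse relaxivity r2 must be >= r1")

    def shorten(self, t_ms: np.ndarray, relaxivity: float, c_mmol: np.ndarray) -> np.ndarray:
        """1/T_post = 1/T_pre + r * C, with T in ms and r in L/mmol/s."""
        return 1.0 / (1.0 / np.asarray(t_ms, float) + relaxivity * np.asarray(c_mmol, float) / 1000.0)


@dataclass(frozen=True)
class PhantomLayerSpec:
    """Sphere parameters and lattice geometry for one phantom layer."""

    layer: str  # "T1" or "T2"
    sphere_params: tuple[tuple[float, float, float], ...]  # (T1, T2, PD) each
    radius_vox: float = 3.5
    spacing_vox: float = 12.0

    def __post_init__(self) -> None:
        if self.layer not in ("T1", "T2"):
            raise InvalidParameterError("layer must be 'T1' or 'T2'")
        if len(self.sphere_params) < 2:
            raise InvalidParameterError("need >= 2 spheres")
        t_key = 0 if self.layer == "T1" else 1
        vals = [p[t_key] for p in self.sphere_params]
        if max(vals) / min(vals) < 10.0:
            raise InvalidParameterError(
                f"{self.layer} sphere values should span at least a decade"
            )


def default_phantom_spec(layer: str = "T1", n_spheres: int = 14) -> PhantomLayerSpec:
    """Log-spaced sphere parameters emulating a calibration phantom layer."""
    if layer == "T1":
        t1 = np.geomspace(100.0, 3000.0, n_spheres)
        t2 = np.geomspace(15.0, 450.0, n_spheres)
    else:
        t2 = np.geomspace(10.0, 700.0, n_spheres)
        t1 = np.clip(3.0 * t2 + 200.0, 300.0, 3500.0)
    params = tuple((float(a), float(b), 1.0) for a, b in zip(t1, t2))
    return PhantomLayerSpec(layer=layer, sphere_params=params)


@dataclass
class ParameterVolume:
    """Voxelwise truth parameters plus ROI labels and provenance.

    ``label_map`` assigns a unique positive integer to each ROI; 0 is
    background.  ``roi_table`` records every ROI's generating parameters
    (one row per ROI: label, tissue class, patient, T1/T2/ADC means, and —
    after contrast — the drawn concentration).
    """

    t1: np.ndarray
    t2: np.ndarray
    pd: np.ndarray
    adc: np.ndarray | None
    label_map: np.ndarray
    roi_table: pd.DataFrame
    phase: str = "pre"
    patient: int = 0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t1.shape

    @property
    def foreground(self) -> np.ndarray:
        return self.label_map > 0

    def roi_mask(self, label: int) -> np.ndarray:
        return self.label_map == label

    def roi_masks(self) -> dict[int, np.ndarray]:
        return {int(l): self.label_map == l for l in np.unique(self.label_map) if l > 0}


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

def make_phantom(
    spec: PhantomLayerSpec, grid_shape: tuple[int, int] = (64, 64), seed: int = 0
) -> tuple[ParameterVolume, dict[str, np.ndarray]]:
    """Lay the spheres on a lattice; returns the truth volume and per-sphere masks.

    Deterministic given (spec, seed); sphere interiors are uniform at the
    spec values so each sphere mean equals its spec entry exactly.
    """
    ny, nx = grid_shape
    n = len(spec.sphere_params)
    per_row = int(np.ceil(np.sqrt(n)))
    r, d = spec.radius_vox, spec.spacing_vox
    if 2 * r >= d:
        raise InvalidParameterError("spheres overlap: need spacing > 2 * radius")
    extent = (per_row - 1) * d + 2 * r
    if extent > min(grid_shape) - 2:
        raise InvalidParameterError(
            f"{n} spheres at spacing {d} do not fit in grid {grid_shape}"
        )
    y0 = (ny - (per_row - 1) * d) / 2.0
    x0 = (nx - (per_row - 1) * d) / 2.0

    t1 = np.zeros(grid_shape)
    t2 = np.zeros(grid_shape)
    pdv = np.zeros(grid_shape)
    labels = np.zeros(grid_shape, int)
    yy, xx = np.mgrid[0:ny, 0:nx]
    masks: dict[str, np.ndarray] = {}
    rows = []
    for i, (t1v, t2v, pdval) in enumerate(spec.sphere_params):
        cy = y0 + (i // per_row) * d
        cx = x0 + (i % per_row) * d
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        if np.any(labels[mask] != 0):
            raise InvalidParameterError(f"sphere {i} overlaps a previous sphere")
        labels[mask] = i + 1
        t1[mask], t2[mask], pdv[mask] = t1v, t2v, pdval
        masks[f"sphere_{i:02d}"] = mask
        rows.append({"label": i + 1, "roi": f"sphere_{i:02d}", "tissue_class": "phantom",
                     "patient": 0, "t1_ms": t1v, "t2_ms": t2v, "pd": pdval,
                     "adc": np.nan, "n_voxels": int(mask.sum())})
    vol = ParameterVolume(t1=t1, t2=t2, pd=pdv, adc=None, label_map=labels,
                          roi_table=pd.DataFrame(rows), phase="pre")
    return vol, masks


# ---------------------------------------------------------------------------
# virtual pelvis
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and SD."""
    if sd == 0:
        return np.log(mean), 0.0
    s2 = np.log(1.0 + (sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _draw_lognormal(rng: np.random.Generator, mean: float, sd: float, size=None):
    if mean == 0:
        return np.zeros(size) if size else 0.0
    mu, sigma = _lognormal_params(mean, sd)
    return rng.lognormal(mu, sigma, size=size)


def sample_class_roi_means(
    spec: TissueClassSpec,
    n: int,
    rng: np.random.Generator,
    tz_host: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw n ROI-level (T1, T2, ADC) means from a class distribution.

    T1 is normal (floored at 50 ms); T2 and ADC are log-normal matched to
    the class mean/SD so draws are positive with exact first two moments.
    For normal TZ the T1 draw is the host/non-host mixture; ``tz_host``
    fixes the component per draw (random 9/14 host fraction otherwise).
    """
    if spec.name == "normal_TZ":
        if tz_host is None:
            tz_host = rng.random(n) < _NTZ_HOST_FRACTION
        off = np.where(tz_host, _NTZ_HOST_STD[0], _NTZ_NONHOST_STD[0])
        ratio = np.where(tz_host, _NTZ_HOST_STD[1], _NTZ_NONHOST_STD[1])
        z = rng.standard_normal(n)
        t1 = spec.t1_mean_ms + spec.t1_sd_ms * (off + ratio * z)
    else:
        t1 = rng.normal(spec.t1_mean_ms, spec.t1_sd_ms, size=n)
    t1 = np.maximum(t1, 50.0)
    t2 = _draw_lognormal(rng, spec.t2_mean_ms, spec.t2_sd_ms, size=n)
    adc = _draw_lognormal(rng, spec.adc_mean, spec.adc_sd, size=n)
    return pd.DataFrame({"t1_ms": t1, "t2_ms": np.maximum(t2, 5.0),
                         "adc": np.maximum(adc, 0.01)})


def _correlated_lesion_t1(
    spec: TissueClassSpec,
    host_t1: float,
    host_mean: float,
    host_sd: float,
    rng: np.random.Generator,
    rho: float = LESION_NORMAL_RHO,
) -> float:
    """Lesion ROI mean T1 correlated with the host patient's normal tissue."""
    z_host = 0.0 if host_sd == 0 else (host_t1 - host_mean) / host_sd
    draw = spec.t1_mean_ms + spec.t1_sd_ms * (
        rho * z_host + np.sqrt(1.0 - rho**2) * rng.standard_normal()
    )
    return float(max(draw, 50.0))


def _ellipse(yy, xx, cy, cx, ry, rx):
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _pelvis_geometry(grid_shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Schematic single-slice pelvis ROI layout, scaled to the grid."""
    ny, nx = grid_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    s = min(ny, nx) / 48.0  # reference layout designed on a 48x48 grid
    cy, cx = 28 * s, nx / 2.0
    rois = {
        "fat": (yy >= 1) & (yy <= 1 + 3 * s) & (xx >= 6 * s) & (xx <= nx - 6 * s),
        "muscle": (yy >= 6 * s) & (yy <= 9 * s) & (xx >= 8 * s) & (xx <= nx - 8 * s),
    }
    tz = _ellipse(yy, xx, cy, cx, 8 * s, 7 * s)
    prostate = _ellipse(yy, xx, cy, cx, 14 * s, 12 * s)
    pz = prostate & ~_ellipse(yy, xx, cy, cx, 10 * s, 9 * s)
    rois["normal_TZ"] = _ellipse(yy, xx, cy - 2 * s, cx + 2.5 * s, 3.5 * s, 3.5 * s) & tz
    rois["normal_PZ"] = _ellipse(yy, xx, cy + 11 * s, cx, 2.5 * s, 6 * s) & pz
    rois["PZ_lesion"] = _ellipse(yy, xx, cy + 9.5 * s, cx - 8 * s, 2.6 * s, 2.6 * s) & pz
    rois["TZ_lesion"] = _ellipse(yy, xx, cy - 2 * s, cx - 4 * s, 2.6 * s, 2.6 * s) & tz
    # enforce disjoint ROIs (lesions take precedence over normal tissue)
    taken = np.zeros(grid_shape, bool)
    for name in ("PZ_lesion", "TZ_lesion", "normal_TZ", "normal_PZ", "muscle", "fat"):
        rois[name] = rois[name] & ~taken
        taken |= rois[name]
    return rois


# lesion hosting: 10 PZ and 9 TZ lesions over 14 patients
_PZ_HOSTS = tuple(range(10))
_TZ_HOSTS = tuple(range(5, 14))


def make_virtual_pelvis(
    specs: dict[str, TissueClassSpec] | None = None,
    n_patients: int = 14,
    grid_shape: tuple[int, int] = (48, 48),
    seed: int = 0,
    pz_hosts: tuple[int, ...] | None = None,
    tz_hosts: tuple[int, ...] | None = None,
) -> list[ParameterVolume]:
    """Generate the pre-contrast virtual cohort, one labelled slice per patient.

    Default cohort: 14 patients, 10 PZ + 9 TZ lesions; every patient carries
    normal-PZ, normal-TZ, muscle and fat ROIs.  ROI-level means are drawn
    from the class distributions (normal-TZ host mixture, lesion T1
    correlated with host normal tissue); voxels jitter at 5% CV.
    """
    if n_patients < 1:
        raise InvalidParameterError("need >= 1 patient")
    specs = specs if specs is not None else default_tissue_specs()
    if pz_hosts is None:
        pz_hosts = tuple(p for p in _PZ_HOSTS if p < n_patients)
    if tz_hosts is None:
        tz_hosts = tuple(p for p in _TZ_HOSTS if p < n_patients)
    geometry = _pelvis_geometry(grid_shape)
    for name, mask in geometry.items():
        if not mask.any():
            raise InvalidParameterError(f"ROI {name} does not fit in grid {grid_shape}")

    patients: list[ParameterVolume] = []
    for p in range(n_patients):
        rng = np.random.default_rng(derive_seed(seed, 101, p))
        t1 = np.zeros(grid_shape)
        t2 = np.zeros(grid_shape)
        adc = np.zeros(grid_shape)
        pdv = np.zeros(grid_shape)
        labels = np.zeros(grid_shape, int)
        rows = []

        # normal tissues first (lesions correlate with them)
        draws: dict[str, pd.Series] = {}
        for name in ("normal_PZ", "normal_TZ", "muscle", "fat"):
            host = np.array([p in tz_hosts]) if name == "normal_TZ" else None
            draws[name] = sample_class_roi_means(specs[name], 1, rng, tz_host=host).iloc[0]
        if p in pz_hosts:
            les = sample_class_roi_means(specs["PZ_lesion"], 1, rng).iloc[0].copy()
            les["t1_ms"] = _correlated_lesion_t1(
                specs["PZ_lesion"], draws["normal_PZ"]["t1_ms"],
                specs["normal_PZ"].t1_mean_ms, specs["normal_PZ"].t1_sd_ms, rng)
            draws["PZ_lesion"] = les
        if p in tz_hosts:
            les = sample_class_roi_means(specs["TZ_lesion"], 1, rng).iloc[0].copy()
            host_m = specs["normal_TZ"].t1_mean_ms + specs["normal_TZ"].t1_sd_ms * _NTZ_HOST_STD[0]
            host_s = specs["normal_TZ"].t1_sd_ms * _NTZ_HOST_STD[1]
            les["t1_ms"] = _correlated_lesion_t1(
                specs["TZ_lesion"], draws["normal_TZ"]["t1_ms"], host_m, host_s, rng)
            draws["TZ_lesion"] = les

        for label, (name, mean_row) in enumerate(draws.items(), start=1):
            mask = geometry[name]
            nvox = int(mask.sum())
            jitter = lambda m: np.maximum(  # noqa: E731 - local helper
                m * (1.0 + WITHIN_ROI_CV * rng.standard_normal(nvox)), m * 0.2)
            t1[mask] = jitter(mean_row["t1_ms"])
            t2[mask] = jitter(mean_row["t2_ms"])
            adc[mask] = jitter(mean_row["adc"])
            pdv[mask] = 1.0
            labels[mask] = label
            rows.append({"label": label, "roi": f"p{p:02d}_{name}", "tissue_class": name,
                         "patient": p, "t1_ms": float(mean_row["t1_ms"]),
                         "t2_ms": float(mean_row["t2_ms"]), "adc": float(mean_row["adc"]),
                         "pd": 1.0, "n_voxels": nvox, "c_mmol": 0.0})
        patients.append(ParameterVolume(
            t1=t1, t2=t2, pd=pdv, adc=adc, label_map=labels,
            roi_table=pd.DataFrame(rows), phase="pre", patient=p))
    return patients


# ---------------------------------------------------------------------------
# contrast
# ---------------------------------------------------------------------------

def apply_contrast(
    volume: ParameterVolume,
    specs: dict[str, TissueClassSpec] | None = None,
    model: ContrastModel = ContrastModel(),
    seed: int = 0,
) -> ParameterVolume:
    """Shorten T1 and T2 by a per-ROI gadolinium concentration draw.

    Each ROI draws one concentration from its class's log-normal uptake
    distribution; voxels within the ROI jitter at 5% CV.  T1 and T2 update
    by the relaxivity equations, so both strictly decrease wherever C > 0.
    """
    specs = specs if specs is not None else default_tissue_specs()
    rng = np.random.default_rng(derive_seed(seed, 202, volume.patient))
    t1 = volume.t1.copy()
    t2 = volume.t2.copy()
    table = volume.roi_table.copy()
    c_col = []
    for _, row in table.iterrows():
        cls = row["tissue_class"]
        if cls not in specs:  # phantom or unknown: no uptake
            c_col.append(0.0)
            continue
        spec = specs[cls]
        c_roi = float(_draw_lognormal(rng, spec.gbca_uptake_mean,
                                      spec.gbca_uptake_mean * spec.gbca_uptake_cv))
        mask = volume.label_map == row["label"]
        if c_roi > 0:
            c_vox = c_roi * np.maximum(
                1.0 + WITHIN_ROI_CV * rng.standard_normal(int(mask.sum())), 0.0)
            t1[mask] = model.shorten(t1[mask], model.r1, c_vox)
            t2[mask] = model.shorten(t2[mask], model.r2, c_vox)
        c_col.append(c_roi)
    table["c_mmol"] = c_col
    table["t1_post_ms"] = model.shorten(table["t1_ms"].to_numpy(), model.r1,
                                        np.asarray(c_col))
    table["t2_post_ms"] = model.shorten(table["t2_ms"].to_numpy(), model.r2,
                                        np.asarray(c_col))
    return ParameterVolume(t1=t1, t2=t2, pd=volume.pd.copy(),
                           adc=None if volume.adc is None else volume.adc.copy(),
                           label_map=volume.label_map.copy(), roi_table=table,
                           phase="post", patient=volume.patient,
                           affine=volume.affine.copy())


# ---------------------------------------------------------------------------
# acquisition simulation
# ---------------------------------------------------------------------------

def _forward_conventional(
    volume: ParameterVolume, protocol: ConventionalProtocol, mask: np.ndarray
) -> np.ndarray:
    pts = np.asarray(protocol.sample_points)
    out = np.zeros(volume.shape + (pts.size,))
    t1 = volume.t1[mask]
    t2 = volume.t2[mask]
    pdv = volume.pd[mask]
    if protocol.kind == "IR_FSE":
        sig = pdv[:, None] * (1 - 2 * np.exp(-pts[None, :] / t1[:, None])
                              + np.exp(-protocol.tr_ms / t1[:, None]))
    elif protocol.kind == "VFA_SPGR":
        a = np.deg2rad(pts)[None, :]
        e1 = np.exp(-protocol.tr_ms / t1[:, None])
        sig = pdv[:, None] * np.sin(a) * (1 - e1) / (1 - e1 * np.cos(a))
    elif protocol.kind == "MSE":
        sig = pdv[:, None] * np.exp(-pts[None, :] / t2[:, None])
    elif protocol.kind == "DWI":
        if volume.adc is None:
            raise InvalidParameterError("volume has no ADC; cannot simulate DWI")
        adc = volume.adc[mask]
        sig = pdv[:, None] * np.exp(-pts[None, :] * adc[:, None] * 1e-3)
    else:  # pragma: no cover
        raise InvalidParameterError(f"unknown protocol kind {protocol.kind}")
    out[mask] = sig
    return out


def simulate_acquisition(
    volume: ParameterVolume,
    protocol: ConventionalProtocol | MRFSequenceParams,
    snr: float | None = None,
    seed: int = 0,
    magnitude: bool = True,
    mask: np.ndarray | None = None,
    n_states: int = 40,
) -> np.ndarray:
    """Forward-simulate an acquisition of the truth volume, with noise.

    ``snr = None`` (or inf) is noiseless.  Otherwise complex Gaussian noise
    with sigma = mean foreground |signal| / snr is added and the magnitude
    taken (Rician statistics) unless ``magnitude=False`` (complex data).
    Deterministic given seed.  Voxels outside ``mask`` (default: foreground,
    i.e. pd > 0) stay zero to keep MRF simulation affordable.
    """
    if snr is not None and not snr > 0:
        raise InvalidParameterError("snr must be positive (or None for noiseless)")
    if mask is None:
        mask = volume.pd > 0
    if isinstance(protocol, MRFSequenceParams):
        flat_idx = np.flatnonzero(mask.ravel())
        sig = sm.epg_fingerprints(
            volume.t1.ravel()[flat_idx], volume.t2.ravel()[flat_idx], protocol,
            pd=volume.pd.ravel()[flat_idx], n_states=n_states)  # (N, M)
        stack = np.zeros(volume.shape + (protocol.n_excitations,))
        stack.reshape(-1, protocol.n_excitations)[flat_idx] = sig.T
    elif isinstance(protocol, ConventionalProtocol):
        stack = _forward_conventional(volume, protocol, mask)
    else:
        raise InvalidParameterError(f"unknown protocol type {type(protocol).__name__}")

    if snr is None or np.isinf(snr):
        return np.abs(stack) if magnitude else stack
    fg = np.abs(stack[mask])
    ref = float(fg.mean()) if fg.size else 1.0
    sigma = ref / snr
    rng = np.random.default_rng(derive_seed(seed, 303, volume.patient))
    noise = sigma * (rng.standard_normal(stack.shape)
                     + 1j * rng.standard_normal(stack.shape))
    noisy = stack + noise
    return np.abs(noisy) if magnitude else noisy
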