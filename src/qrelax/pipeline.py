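"""Orchestration: phantom-study and cohort-study pipelines, plus I/O glue.

The phantom pipeline validates fingerprinting against the conventional
gold standards on a synthetic calibration phantom: generate spheres,
simulate all four acquisitions, fit/match, then regress and Bland-Altman
the per-sphere values.  The cohort pipeline generates the virtual pelvis
cohort, acquires fingerprinting before and after contrast (plus the
pre-contrast conventional protocols), and produces the summary, CV and
contrast tables.

Outputs are deterministic per seed; every output directory carries a
manifest (config, seed, package version, config hash) and each expensive
stage persists its table so a re-run with the same manifest resumes from
the intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .mrf_dictionary import (
    DictionaryGrid,
    FingerprintDictionary,
    build_dictionary,
    cohort_grid,
    default_grid,
    match_volume,
)
from .parameter_fitting import fit_volume
from .roi_statistics import (
    BlandAltmanResult,
    Contrast,
    bland_altman,
    build_report,
    group_compare,
    linear_regression,
    replay_cv_table,
    roi_means,
    summarise_rois,
)
from .sequence_models import get_preset
from .synthetic_data import (
    ContrastModel,
    ParameterVolume,
    apply_contrast,
    default_phantom_spec,
    default_tissue_specs,
    make_phantom,
    make_virtual_pelvis,
    simulate_acquisition,
)
from .types import InvalidParameterError, MRFSequenceParams, QuantitativeMap

__all__ = [
    "RunConfig",
    "run_phantom_study",
    "run_cohort_study",
    "run_table_replay",
    "save_map",
    "load_map",
    "save_labels",
    "load_labels",
]

log = logging.getLogger(__name__)


def _phantom_fine_grid() -> DictionaryGrid:
    """T1-fine grid restricted to the phantom range (keeps the build fast)."""
    fine = default_grid()
    t2 = [v for v in fine.t2_values_ms if v <= 500 and (v < 100 or v % 10 == 0)]
    return DictionaryGrid(fine.t1_values_ms, tuple(t2))


_GRIDS = {"default": default_grid, "cohort": cohort_grid, "phantom_fine": _phantom_fine_grid}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (CLI flags > config file > defaults)."""

    mode: str = "phantom"
    seed: int = 0
    snr: float | None = 100.0
    dictionary_grid: str = "phantom_fine"
    mrf_preset: str = "mrf_default"
    n_states: int = 40
    n_patients: int = 14
    grid_shape: tuple[int, int] = (48, 48)
    phantom_grid_shape: tuple[int, int] = (64, 64)
    contrast_enabled: bool = True
    contrast_r1: float = 5.0
    contrast_r2: float = 6.0
    out_dir: str | None = None

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["phantom_grid_shape"] = list(self.phantom_grid_shape)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("grid_shape", "phantom_grid_shape"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_map(qmap: QuantitativeMap, path: str | Path) -> Path:
    """Write a quantitative map (or signal stack) as NIfTI with JSON sidecar."""
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(qmap.data, np.float64), qmap.affine)
    nib.save(img, path)
    sidecar = {"kind": qmap.kind, "units": qmap.units, "phase": qmap.phase}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def load_map(path: str | Path) -> QuantitativeMap:
    import nibabel as nib

    path = Path(path)
    try:
        img = nib.load(path)
    except Exception as exc:
        raise InvalidParameterError(f"cannot read NIfTI {path}: {exc}") from exc
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return QuantitativeMap(
        data=np.asarray(img.dataobj, float),
        kind=meta.get("kind", "unknown"),
        units=meta.get("units", ""),
        phase=meta.get("phase", "pre"),
        affine=np.asarray(img.affine),
    )


def save_labels(label_map: np.ndarray, roi_table: pd.DataFrame, path: str | Path) -> Path:
    import nibabel as nib

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(label_map, np.int16), np.eye(4)), path)
    roi_table.to_csv(Path(str(path) + ".csv"), index=False)
    return path


def load_labels(path: str | Path) -> tuple[np.ndarray, pd.DataFrame]:
    import nibabel as nib

    labels = np.asarray(nib.load(path).dataobj).astype(int)
    table = pd.read_csv(Path(str(path) + ".csv"))
    known = set(table["label"].astype(int)) | {0}
    present = set(np.unique(labels).tolist())
    unknown = sorted(present - known)
    if unknown:
        raise InvalidParameterError(f"label map contains unknown labels: {unknown}")
    return labels, table


# ---------------------------------------------------------------------------
# stage persistence
# ---------------------------------------------------------------------------

class _Stages:
    """Persist per-stage DataFrames so matching re-runs resume from disk."""

    def __init__(self, out_dir: Path | None, config: RunConfig):
        self.dir = out_dir
        self.hash = config.config_hash()
        if out_dir is not None:
            out_dir.mkdir(parents=True, exist_ok=True)
            manifest = out_dir / "manifest.json"
            if manifest.exists():
                old = json.loads(manifest.read_text())
                if old.get("config_hash") != self.hash:
                    log.info("config changed; discarding stale intermediates")
                    for stale in out_dir.glob("stage_*.csv"):
                        stale.unlink()
            manifest.write_text(json.dumps({
                "config": config.as_dict(), "config_hash": self.hash,
                "package_version": __version__,
                "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }, indent=1))

    def run(self, name: str, fn) -> pd.DataFrame:
        if self.dir is not None:
            path = self.dir / f"stage_{name}.csv"
            if path.exists():
                log.info("stage %s: resumed from %s", name, path)
                return pd.read_csv(path)
        t0 = time.time()
        df = fn()
        log.info("stage %s: %.1f s", name, time.time() - t0)
        if self.dir is not None:
            df.to_csv(self.dir / f"stage_{name}.csv", index=False)
        return df


# ---------------------------------------------------------------------------
# phantom study
# ---------------------------------------------------------------------------

def _phantom_measurements(config: RunConfig) -> pd.DataFrame:
    """Simulate, fit and match the phantom; one row per (sphere, method)."""
    volume, _ = make_phantom(default_phantom_spec("T1"),
                             grid_shape=config.phantom_grid_shape, seed=config.seed)
    mask = volume.foreground
    seq = get_preset(config.mrf_preset)
    assert isinstance(seq, MRFSequenceParams)

    rows = []

    def collect(qmap: QuantitativeMap, method: str) -> None:
        df = roi_means(qmap, volume.label_map, volume.roi_table)
        df["method"] = method
        rows.append(df)

    for preset_name, method in (("phantom_ir", "IR_T1"), ("phantom_vfa", "VFA_T1"),
                                ("phantom_mse", "MSE_T2")):
        protocol = get_preset(preset_name)
        stack = simulate_acquisition(volume, protocol, snr=config.snr,
                                     seed=config.seed, magnitude=True, mask=mask)
        qmap, _ = fit_volume(stack, protocol, mask=mask)
        collect(qmap, method)

    stack = simulate_acquisition(volume, seq, snr=config.snr, seed=config.seed,
                                 magnitude=False, mask=mask, n_states=config.n_states)
    grid = _GRIDS[config.dictionary_grid]()
    dictionary = build_dictionary(grid, seq, n_states=config.n_states)
    maps = match_volume(stack, dictionary, mask=mask)
    collect(maps["t1"], "MRF_T1")
    collect(maps["t2"], "MRF_T2")

    truth = volume.roi_table[["roi", "t1_ms", "t2_ms"]].rename(
        columns={"t1_ms": "truth_t1_ms", "t2_ms": "truth_t2_ms"})
    out = pd.concat(rows, ignore_index=True).merge(truth, on="roi")
    return out


def run_phantom_study(config: RunConfig) -> dict:
    """Phantom validation: regression + Bland-Altman of MRF vs gold standards."""
    if config.mode != "phantom":
        config = dataclasses.replace(config, mode="phantom")
    out_dir = Path(config.out_dir) if config.out_dir else None
    stages = _Stages(out_dir, config)
    meas = stages.run("phantom_measurements", lambda: _phantom_measurements(config))

    wide = meas.pivot_table(index="roi", columns="method", values="value")
    comparisons = {
        "MRF_vs_IR_T1": ("MRF_T1", "IR_T1"),
        "MRF_vs_VFA_T1": ("MRF_T1", "VFA_T1"),
        "MRF_vs_MSE_T2": ("MRF_T2", "MSE_T2"),
    }
    regressions: dict[str, dict] = {}
    agreement: dict[str, BlandAltmanResult] = {}
    figures = {}
    for name, (a_col, b_col) in comparisons.items():
        a = wide[a_col].to_numpy()
        b = wide[b_col].to_numpy()
        reg = linear_regression(b, a)  # gold standard on x, MRF on y
        regressions[name] = reg.__dict__
        agreement[name] = bland_altman(a, b)
        figures[name] = (b, a)

    results = {
        "config": config.as_dict(),
        "per_sphere": wide.reset_index(),
        "regressions": regressions,
        "bland_altman": {k: v.__dict__ for k, v in agreement.items()},
    }
    if out_dir is not None:
        summary = summarise_rois(
            meas.assign(tissue_class=meas["method"]), value_col="value")
        build_report({"phantom_by_method": summary}, out_dir,
                     bland_altman_results=agreement, figures=figures)
        wide.reset_index().to_csv(out_dir / "per_sphere_values.csv", index=False)
        (out_dir / "regressions.json").write_text(json.dumps(regressions, indent=1))
    return results


# ---------------------------------------------------------------------------
# cohort study
# ---------------------------------------------------------------------------

def _cohort_measurements(config: RunConfig) -> pd.DataFrame:
    """Per-ROI measured means for every patient, map kind and phase."""
    specs = default_tissue_specs()
    model = ContrastModel(r1=config.contrast_r1, r2=config.contrast_r2)
    seq = get_preset(config.mrf_preset)
    assert isinstance(seq, MRFSequenceParams)
    dictionary = build_dictionary(_GRIDS["cohort"](), seq, n_states=config.n_states)

    patients = make_virtual_pelvis(specs=specs, n_patients=config.n_patients,
                                   grid_shape=config.grid_shape, seed=config.seed)
    rows = []
    for pre in patients:
        log.info("cohort patient %d / %d", pre.patient + 1, config.n_patients)
        volumes = {"pre": pre}
        if config.contrast_enabled:
            volumes["post"] = apply_contrast(pre, specs=specs, model=model,
                                             seed=config.seed)
        else:
            volumes["post"] = dataclasses.replace(pre, phase="post")
        for phase, vol in volumes.items():
            maps = _mrf_maps(vol, seq, dictionary, config)
            for kind in ("t1", "t2"):
                qmap = maps[kind]
                qmap.phase = phase
                df = roi_means(qmap, vol.label_map, vol.roi_table)
                df["map_kind"] = f"MRF_{kind.upper()}"
                rows.append(df)
        # conventional mapping acquired pre-contrast only
        for preset_name, kind in (("invivo_vfa", "VFA_T1"), ("invivo_mse", "MSE_T2"),
                                  ("invivo_dwi", "ADC")):
            protocol = get_preset(preset_name)
            stack = simulate_acquisition(pre, protocol, snr=config.snr,
                                         seed=config.seed, magnitude=True)
            qmap, _ = fit_volume(stack, protocol, mask=pre.foreground)
            df = roi_means(qmap, pre.label_map, pre.roi_table)
            df["map_kind"] = kind
            rows.append(df)
    return pd.concat(rows, ignore_index=True)


def _mrf_maps(vol: ParameterVolume, seq: MRFSequenceParams,
              dictionary: FingerprintDictionary, config: RunConfig) -> dict:
    stack = simulate_acquisition(vol, seq, snr=config.snr, seed=config.seed,
                                 magnitude=False, mask=vol.foreground,
                                 n_states=config.n_states)
    return match_volume(stack, dictionary, mask=vol.foreground)


def _cohort_contrasts(meas: pd.DataFrame) -> list[Contrast]:
    """Planned lesion-vs-normal paired contrasts plus post-hoc pre/post."""
    t1 = meas[meas.map_kind == "MRF_T1"]

    def paired_values(cls_a: str, cls_b: str, phase: str) -> tuple[tuple, tuple]:
        a = t1[(t1.tissue_class == cls_a) & (t1.phase == phase)].set_index("patient")["value"]
        b = t1[(t1.tissue_class == cls_b) & (t1.phase == phase)].set_index("patient")["value"]
        common = a.index.intersection(b.index)
        return tuple(a.loc[common]), tuple(b.loc[common])

    contrasts = []
    for zone, lesion, normal in (("PZ", "PZ_lesion", "normal_PZ"),
                                 ("TZ", "TZ_lesion", "normal_TZ")):
        for phase in ("pre", "post"):
            x, y = paired_values(lesion, normal, phase)
            if len(x) < 3:  # small custom cohorts may lack lesions in a zone
                log.warning("skipping %s_%s contrast: only %d pairs", zone, phase, len(x))
                continue
            contrasts.append(Contrast(
                label=f"{zone}_lesion_vs_normal_{phase}", x=x, y=y,
                paired=True, planned=True))
    # post-hoc: contrast-induced shortening per tissue, adjusted as a family
    for cls in sorted(t1.tissue_class.unique()):
        pre_v = t1[(t1.tissue_class == cls) & (t1.phase == "pre")].set_index("patient")["value"]
        post_v = t1[(t1.tissue_class == cls) & (t1.phase == "post")].set_index("patient")["value"]
        common = pre_v.index.intersection(post_v.index)
        if common.size >= 3:
            contrasts.append(Contrast(
                label=f"{cls}_pre_vs_post", x=tuple(pre_v.loc[common]),
                y=tuple(post_v.loc[common]), paired=True, planned=False))
    return contrasts


def run_cohort_study(config: RunConfig) -> dict:
    """Virtual-cohort study: summary tables, CV tables, contrasts, figures."""
    if config.mode != "cohort":
        config = dataclasses.replace(config, mode="cohort")
    out_dir = Path(config.out_dir) if config.out_dir else None
    stages = _Stages(out_dir, config)
    meas = stages.run("cohort_measurements", lambda: _cohort_measurements(config))

    summaries: dict[str, pd.DataFrame] = {}
    for (kind, phase), grp in meas.groupby(["map_kind", "phase"]):
        if phase == "post" and not kind.startswith("MRF"):
            continue
        summaries[f"{kind}_{phase}"] = summarise_rois(grp)

    comparisons = group_compare(_cohort_contrasts(meas))

    t1_sum = {ph: summaries[f"MRF_T1_{ph}"].set_index("tissue_class") for ph in ("pre", "post")}
    if "TZ_lesion" in t1_sum["pre"].index:
        tz_cv_pre = float(t1_sum["pre"].loc["TZ_lesion", "cv_percent"])
        tz_cv_post = float(t1_sum["post"].loc["TZ_lesion", "cv_percent"])
    else:  # small custom cohorts may carry no TZ lesions
        tz_cv_pre = tz_cv_post = float("nan")
    headline = {
        "tz_lesion_cv_pre_percent": tz_cv_pre,
        "tz_lesion_cv_post_percent": tz_cv_post,
        "tz_lesion_cv_inflation_ratio": tz_cv_post / tz_cv_pre,
        "all_tissues_shortened": bool(
            (t1_sum["post"]["mean"] < t1_sum["pre"]["mean"]).all()),
        "p_values": {c.label: c.raw_p if c.planned else c.adjusted_p
                     for c in comparisons},
    }
    results = {"config": config.as_dict(), "measurements": meas,
               "summaries": summaries, "comparisons": comparisons,
               "headline": headline}
    if out_dir is not None:
        build_report(summaries, out_dir, comparisons=comparisons)
        (out_dir / "headline.json").write_text(json.dumps(headline, indent=1))
    return results


def run_table_replay(out_dir: str | Path | None = None) -> pd.DataFrame:
    """Recompute the CV table from the bundled summary constants (no simulation)."""
    table = replay_cv_table()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cv_replay.csv", index=False)
    return table
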