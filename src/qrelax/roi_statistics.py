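"""ROI-level statistics: CV, regression, Bland-Altman, adjusted contrasts.

The statistical layer mirrors a typical quantitative-imaging validation
study: per-ROI means are the unit of analysis; heterogeneity is the
coefficient of variation across ROI means (CV < 25% deemed acceptable);
method agreement uses ordinary least squares and Bland-Altman limits of
agreement; group contrasts use Shapiro-Wilk-annotated t-tests with
Holm-Sidak adjustment of non-planned comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .reference_tables import (
    CV_REPLAY_EXCLUSIONS,
    PUBLISHED_CV_TABLE,
    SUMMARY_COLUMNS,
    SUMMARY_TABLE,
    TISSUES,
)
from .types import InvalidParameterError, QuantitativeMap

__all__ = [
    "CV_ACCEPTABLE_PERCENT",
    "compute_cv",
    "roi_means",
    "summarise_rois",
    "BlandAltmanResult",
    "bland_altman",
    "RegressionResult",
    "linear_regression",
    "Contrast",
    "ComparisonResult",
    "group_compare",
    "holm_sidak",
    "replay_cv_table",
    "build_report",
]

CV_ACCEPTABLE_PERCENT = 25.0


def compute_cv(mean: float, sd: float) -> tuple[float, bool]:
    """Coefficient of variation, percent, with the < 25% acceptability flag."""
    if not mean > 0:
        raise InvalidParameterError(f"CV requires a positive mean, got {mean}")
    if sd < 0:
        raise InvalidParameterError(f"SD must be >= 0, got {sd}")
    cv = 100.0 * sd / mean
    return cv, cv < CV_ACCEPTABLE_PERCENT


# ---------------------------------------------------------------------------
# ROI summaries
# ---------------------------------------------------------------------------

def roi_means(
    qmap: QuantitativeMap, label_map: np.ndarray, roi_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-ROI means of one map: one row per ROI with provenance columns."""
    if qmap.shape != np.asarray(label_map).shape:
        raise InvalidParameterError("label map geometry does not match the map")
    rows = []
    for _, roi in roi_table.iterrows():
        mask = label_map == roi["label"]
        val = qmap.masked_mean(mask)
        rows.append({"roi": roi["roi"], "tissue_class": roi["tissue_class"],
                     "patient": roi.get("patient", 0), "value": val,
                     "map_kind": qmap.kind, "phase": qmap.phase,
                     "n_voxels": int(mask.sum())})
    return pd.DataFrame(rows)


def summarise_rois(measurements: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Across-ROI summary per tissue class: mean, SD, n, CV.

    ``measurements`` needs one row per ROI with columns ``tissue_class`` and
    the value column (per-ROI means pooled across patients, as in a cohort
    table).  A lesion aggregate row ("all_lesions") is added when lesion
    classes are present.  Empty/NaN ROIs are excluded with a count; a
    single-ROI class reports SD 0 with an ``n=1`` flag.
    """
    df = measurements.dropna(subset=[value_col]).copy()
    if df.empty:
        raise InvalidParameterError("no valid ROI measurements to summarise")
    lesions = df[df["tissue_class"].isin(["PZ_lesion", "TZ_lesion"])].copy()
    if not lesions.empty:
        lesions["tissue_class"] = "all_lesions"
        df = pd.concat([lesions, df], ignore_index=True)
    out = []
    for cls, grp in df.groupby("tissue_class", sort=False):
        vals = grp[value_col].to_numpy()
        mean = float(np.mean(vals))
        sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
        cv, ok = compute_cv(mean, sd) if mean > 0 else (np.nan, False)
        out.append({"tissue_class": cls, "mean": mean, "sd": sd,
                    "n": int(vals.size), "cv_percent": cv,
                    "cv_acceptable": ok,
                    "flags": "n=1" if vals.size == 1 else ""})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n_pairs: int
    n_outside_loa: int


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement of paired measurements.

    bias = mean(a - b); 95% limits of agreement = bias +/- 1.96 * SD of the
    differences (sample SD, n-1).  Pairs with a missing member are dropped.
    """
    a = np.asarray(a, float).ravel()
    b = np.asarray(b, float).ravel()
    if a.size != b.size:
        raise InvalidParameterError("paired inputs must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise InvalidParameterError("need >= 2 complete pairs")
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    outside = int(np.sum((d < lo) | (d > hi)))
    return BlandAltmanResult(bias=bias, loa_low=lo, loa_high=hi, sd_diff=sd,
                             n_pairs=int(a.size), n_outside_loa=outside)


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def linear_regression(x, y) -> RegressionResult:
    """Ordinary least squares y ~ x; R^2 is the squared Pearson correlation."""
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise InvalidParameterError("need >= 3 points for a regression")
    if np.ptp(x) == 0:
        raise InvalidParameterError("x has zero variance; slope undefined")
    res = stats.linregress(x, y)
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue**2), p_value=float(res.pvalue),
                            n=int(x.size))


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    adj = multipletests(p, alpha=0.05, method="holm-sidak")[1]
    return np.asarray(adj)


@dataclass(frozen=True)
class Contrast:
    """One comparison: two samples, paired flag, planned (unadjusted) flag."""

    label: str
    x: tuple[float, ...]
    y: tuple[float, ...]
    paired: bool = True
    planned: bool = False


@dataclass(frozen=True)
class ComparisonResult:
    label: str
    statistic: float
    raw_p: float
    adjusted_p: float
    test_used: str
    planned: bool
    normality_p: tuple[float, float]
    normality_ok: bool


def group_compare(contrasts: list[Contrast], alpha: float = 0.05) -> list[ComparisonResult]:
    """Run the requested t-tests with normality annotation and adjustment.

    Shapiro-Wilk p-values are recorded per group (paired contrasts test the
    differences); t-tests are reported regardless, with a non-normality
    flag rather than a switch to nonparametrics.  Planned contrasts keep
    their raw p; all other contrasts are Holm-Sidak adjusted as one family.
    Listwise deletion for paired data.
    """
    prepared = []
    for c in contrasts:
        x = np.asarray(c.x, float)
        y = np.asarray(c.y, float)
        if c.paired:
            if x.size != y.size:
                raise InvalidParameterError(f"{c.label}: paired groups differ in length")
            ok = np.isfinite(x) & np.isfinite(y)
            x, y = x[ok], y[ok]
        else:
            x, y = x[np.isfinite(x)], y[np.isfinite(y)]
        if min(x.size, y.size) < 3:
            raise InvalidParameterError(f"{c.label}: need n >= 3 per group")
        if c.paired:
            diffs = x - y
            sw = stats.shapiro(diffs).pvalue if np.ptp(diffs) > 0 else 1.0
            norm_p = (float(sw), float(sw))
            if np.ptp(diffs) == 0:
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_rel(x, y)
            test = "paired_t"
        else:
            norm_p = tuple(
                float(stats.shapiro(g).pvalue) if np.ptp(g) > 0 else 1.0 for g in (x, y)
            )
            if np.ptp(np.concatenate([x, y])) == 0:
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_ind(x, y)
            test = "unpaired_t"
        prepared.append((c, float(t_stat), float(p), test, norm_p))

    post_hoc_idx = [i for i, (c, *_) in enumerate(prepared) if not c.planned]
    adj = holm_sidak([prepared[i][2] for i in post_hoc_idx])
    adj_map = dict(zip(post_hoc_idx, adj))
    results = []
    for i, (c, t_stat, p, test, norm_p) in enumerate(prepared):
        results.append(ComparisonResult(
            label=c.label, statistic=t_stat, raw_p=p,
            adjusted_p=float(adj_map.get(i, p)), test_used=test, planned=c.planned,
            normality_p=norm_p, normality_ok=all(q >= alpha for q in norm_p),
        ))
    return results


# ---------------------------------------------------------------------------
# published-table replay and report
# ---------------------------------------------------------------------------

def replay_cv_table() -> pd.DataFrame:
    """Recompute the CV table from the bundled summary means and SDs.

    Returns one row per (tissue, column) with the recomputed CV, the
    published CV, their difference, and whether the cell is one of the two
    documented inconsistencies excluded from comparisons.
    """
    rows = []
    for tissue in TISSUES:
        for col in SUMMARY_COLUMNS:
            mean, sd = SUMMARY_TABLE[tissue][col]
            cv, ok = compute_cv(mean, sd)
            published = PUBLISHED_CV_TABLE[tissue][col]
            rows.append({
                "tissue": tissue, "column": col, "mean": mean, "sd": sd,
                "cv_percent": round(cv, 1), "published_cv_percent": published,
                "abs_difference": round(abs(round(cv, 1) - published), 10),
                "cv_acceptable": ok,
                "excluded": (tissue, col) in CV_REPLAY_EXCLUSIONS,
            })
    return pd.DataFrame(rows)


def build_report(
    summary_tables: dict[str, pd.DataFrame],
    out_dir: str | Path,
    comparisons: list[ComparisonResult] | None = None,
    bland_altman_results: dict[str, BlandAltmanResult] | None = None,
    figures: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> dict[str, Path]:
    """Persist summary/CV tables as CSV and agreement figures as vector PDF.

    ``summary_tables`` maps a name (e.g. "T1_pre") to a summarise_rois
    table.  Deterministic: equal inputs yield byte-identical CSVs.
    """
    if not summary_tables:
        raise InvalidParameterError("empty report: no summary tables provided")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    for name, table in summary_tables.items():
        path = out / f"summary_{name}.csv"
        table.to_csv(path, index=False, float_format="%.6g")
        written[f"summary_{name}"] = path

    cv_wide = []
    for name, table in summary_tables.items():
        row = table.set_index("tissue_class")["cv_percent"].rename(name)
        cv_wide.append(row)
    cv_table = pd.concat(cv_wide, axis=1)
    path = out / "cv_table.csv"
    cv_table.to_csv(path, float_format="%.6g")
    written["cv_table"] = path

    if comparisons:
        comp = pd.DataFrame([c.__dict__ for c in comparisons])
        path = out / "comparisons.csv"
        comp.to_csv(path, index=False, float_format="%.6g")
        written["comparisons"] = path

    if bland_altman_results:
        ba = pd.DataFrame([{**{"comparison": k}, **r.__dict__}
                           for k, r in bland_altman_results.items()])
        path = out / "bland_altman.csv"
        ba.to_csv(path, index=False, float_format="%.6g")
        written["bland_altman"] = path

    if figures:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for name, (a, b) in figures.items():
            fig, axes = plt.subplots(1, 2, figsize=(9, 4))
            res = linear_regression(a, b)
            axes[0].scatter(a, b, s=18)
            xs = np.linspace(np.nanmin(a), np.nanmax(a), 50)
            axes[0].plot(xs, res.slope * xs + res.intercept, "k-")
            axes[0].set_title(f"{name}: slope={res.slope:.3f}, R2={res.r_squared:.3f}")
            ba_res = bland_altman(a, b)
            mean_ab = (np.asarray(a) + np.asarray(b)) / 2
            axes[1].scatter(mean_ab, np.asarray(a) - np.asarray(b), s=18)
            for yv, style in ((ba_res.bias, "k-"), (ba_res.loa_low, "k:"),
                              (ba_res.loa_high, "k:")):
                axes[1].axhline(yv, ls=style[1:], color="k")
            axes[1].set_title(f"bias={ba_res.bias:.1f}, "
                              f"LOA=[{ba_res.loa_low:.1f}, {ba_res.loa_high:.1f}]")
            fig.tight_layout()
            path = out / f"agreement_{name}.pdf"
            fig.savefig(path)
            plt.close(fig)
            written[f"figure_{name}"] = path
    return written
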