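"""Nonlinear least-squares relaxometry: T1 (IR, VFA), T2 (MSE), ADC (DWI).

Each fitter uses a closed-form linearisation as a deterministic initial
estimate (null-point heuristic for IR, DESPOT1 line for VFA, log-linear
slope for MSE/ADC) followed by bounded trust-region least squares on the
full signal model.  No random restarts; non-convergence is reported in the
result, never raised.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy.optimize import least_squares

from .types import ConventionalProtocol, FitResult, InvalidParameterError, QuantitativeMap

__all__ = ["fit_ir_t1", "fit_vfa_t1", "fit_mse_t2", "fit_adc", "fit_volume"]

log = logging.getLogger(__name__)

# physical bounds, wide enough for every tissue of interest
T1_BOUNDS = (10.0, 10_000.0)
T2_BOUNDS = (1.0, 3_000.0)
ADC_BOUNDS = (0.01, 4.0)  # 10^-3 mm^2/s
_LS_KW = dict(method="trf", ftol=1e-10, xtol=1e-12, gtol=1e-12, max_nfev=200 * 4)


def _failed(n_points: int, sse: float = np.inf, flags: tuple[str, ...] = ()) -> FitResult:
    return FitResult(estimate=np.nan, scale=np.nan, residual_sse=max(sse, 0.0),
                     converged=False, n_points=n_points, flags=flags)


def _as_signals(signals, n_expected: int) -> np.ndarray:
    s = np.asarray(signals, float).ravel()
    if s.size != n_expected:
        raise InvalidParameterError(
            f"got {s.size} signals for {n_expected} protocol sample points"
        )
    return s


def fit_ir_t1(signals, protocol: ConventionalProtocol) -> FitResult:
    """Fit T1 to magnitude inversion-recovery data with polarity restoration.

    Magnitude data lose the sign of the recovery curve; every candidate
    null position is tried (signs flipped for points before it), each
    candidate is fitted with the signed three-term IR model, and the lowest
    SSE wins.  ``polarity_restored`` records whether any sign was flipped.
    """
    if protocol.kind != "IR_FSE":
        raise InvalidParameterError(f"expected IR_FSE protocol, got {protocol.kind}")
    ti = np.asarray(protocol.sample_points)
    tr = protocol.tr_ms
    s = _as_signals(signals, ti.size)
    if s.size < 3:
        raise InvalidParameterError("need >= 3 inversion times")
    smax = float(np.max(np.abs(s)))
    if smax == 0:
        return _failed(s.size, flags=("all-zero input",))

    def model(params: np.ndarray) -> np.ndarray:
        a, t1 = params
        return a * (1.0 - 2.0 * np.exp(-ti / t1) + np.exp(-tr / t1))

    best: FitResult | None = None
    for null_idx in range(s.size + 1):
        signed = s.copy()
        signed[:null_idx] *= -1.0
        # null-point heuristic: TI at the sign change estimates T1 ln 2
        ti_null = ti[null_idx - 1] if 0 < null_idx <= s.size else ti[0]
        t1_init = np.clip(ti_null / np.log(2.0), *T1_BOUNDS)
        try:
            res = least_squares(
                lambda p: model(p) - signed,
                x0=[smax, t1_init],
                bounds=([0.0, T1_BOUNDS[0]], [np.inf, T1_BOUNDS[1]]),
                **_LS_KW,
            )
        except Exception:  # pragma: no cover - optimizer robustness
            continue
        sse = float(2.0 * res.cost)
        fit = FitResult(
            estimate=float(res.x[1]) if res.success and res.x[0] > 0 else np.nan,
            scale=float(res.x[0]),
            residual_sse=sse,
            converged=bool(res.success and res.x[0] > 0),
            n_points=s.size,
            polarity_restored=null_idx > 0,
        )
        if not fit.converged:
            continue
        if best is None or fit.residual_sse < best.residual_sse:
            best = fit
    return best if best is not None else _failed(s.size, flags=("no candidate converged",))


def fit_vfa_t1(signals, protocol: ConventionalProtocol) -> FitResult:
    """Fit T1 to variable-flip-angle SPGR data.

    Initialised from the DESPOT1 linearisation S/sin(a) = E1 * S/tan(a) + c
    (slope = E1 = e^{-TR/T1}), then refined by bounded least squares on the
    full SPGR model.  A linearised slope outside (0, 1) is flagged as
    non-convergent.
    """
    if protocol.kind != "VFA_SPGR":
        raise InvalidParameterError(f"expected VFA_SPGR protocol, got {protocol.kind}")
    alpha = np.deg2rad(np.asarray(protocol.sample_points))
    tr = protocol.tr_ms
    s = _as_signals(signals, alpha.size)
    if s.size < 3:
        raise InvalidParameterError("need >= 3 flip angles")
    if np.max(np.abs(s)) == 0:
        return _failed(s.size, flags=("all-zero input",))

    y = s / np.sin(alpha)
    x = s / np.tan(alpha)
    slope, intercept = np.polyfit(x, y, 1)
    if not (0.0 < slope < 1.0):
        return _failed(s.size, flags=(f"DESPOT1 slope {slope:.3f} outside (0, 1)",))
    t1_init = float(np.clip(-tr / np.log(slope), *T1_BOUNDS))
    pd_init = max(float(intercept / (1.0 - slope)), np.max(s))

    def resid(params: np.ndarray) -> np.ndarray:
        pd, t1 = params
        e1 = np.exp(-tr / t1)
        return pd * np.sin(alpha) * (1 - e1) / (1 - e1 * np.cos(alpha)) - s

    res = least_squares(resid, x0=[pd_init, t1_init],
                        bounds=([0.0, T1_BOUNDS[0]], [np.inf, T1_BOUNDS[1]]), **_LS_KW)
    return FitResult(
        estimate=float(res.x[1]),
        scale=float(res.x[0]),
        residual_sse=float(2.0 * res.cost),
        converged=bool(res.success),
        n_points=s.size,
    )


def _monoexp_fit(
    x: np.ndarray, s: np.ndarray, rate_bounds: tuple[float, float],
    extrapolation_limit: float | None = None,
) -> tuple[float, float, float, bool, tuple[str, ...]]:
    """Shared log-linear init + NLLS refinement for S0 * exp(-rate * x).

    Returns (rate, scale, sse, converged, flags).  ``rate_bounds`` bound the
    decay rate 1/T2 or ADC-like constant in the same units as 1/x.
    """
    flags: list[str] = []
    pos = s > 0
    if not np.all(pos):
        warnings.warn("non-positive signals dropped from log-linear decay fit",
                      stacklevel=3)
        flags.append("non-positive signals dropped")
    x_use, s_use = x[pos], s[pos]
    if x_use.size < 2 or (extrapolation_limit is not None and x_use.size < 3):
        raise InvalidParameterError("too few positive signals for a decay fit")
    coeffs = np.polyfit(x_use, np.log(s_use), 1)
    rate_init = float(np.clip(-coeffs[0], *rate_bounds))
    s0_init = float(np.exp(coeffs[1]))

    def resid(params: np.ndarray) -> np.ndarray:
        s0, rate = params
        return s0 * np.exp(-rate * x_use) - s_use

    res = least_squares(resid, x0=[s0_init, rate_init],
                        bounds=([0.0, rate_bounds[0]], [np.inf, rate_bounds[1]]),
                        **_LS_KW)
    return (float(res.x[1]), float(res.x[0]), float(2.0 * res.cost),
            bool(res.success), tuple(flags))


def fit_mse_t2(signals, protocol: ConventionalProtocol) -> FitResult:
    """Fit T2 to multi-echo spin-echo magnitudes.

    All echoes are used, including the first.  When the estimate exceeds
    four times the longest TE the result is flagged: the decay is then
    barely sampled and the value is an extrapolation.
    """
    if protocol.kind != "MSE":
        raise InvalidParameterError(f"expected MSE protocol, got {protocol.kind}")
    te = np.asarray(protocol.sample_points)
    s = _as_signals(signals, te.size)
    if np.max(np.abs(s)) == 0:
        return _failed(s.size, flags=("all-zero input",))
    rate_bounds = (1.0 / T2_BOUNDS[1], 1.0 / T2_BOUNDS[0])
    try:
        rate, scale, sse, ok, flags = _monoexp_fit(te, s, rate_bounds,
                                                   extrapolation_limit=4.0)
    except InvalidParameterError:
        raise
    t2 = 1.0 / rate
    if t2 > 4.0 * te.max():
        flags = flags + (f"T2 {t2:.0f} ms exceeds 4x longest TE {te.max():.1f} ms: "
                         "extrapolated beyond the sampled decay",)
    return FitResult(estimate=t2 if ok else np.nan, scale=scale, residual_sse=sse,
                     converged=ok, n_points=s.size, flags=flags)


def fit_adc(signals, protocol: ConventionalProtocol) -> FitResult:
    """Fit ADC (10^-3 mm^2/s) by log-linear least squares over b-values."""
    if protocol.kind != "DWI":
        raise InvalidParameterError(f"expected DWI protocol, got {protocol.kind}")
    b = np.asarray(protocol.sample_points)
    s = _as_signals(signals, b.size)
    if np.max(np.abs(s)) == 0:
        return _failed(s.size, flags=("all-zero input",))
    pos = s > 0
    if pos.sum() < 2:
        raise InvalidParameterError("need >= 2 positive signals for an ADC fit")
    flags: tuple[str, ...] = ()
    if not np.all(pos):
        warnings.warn("non-positive signals dropped from ADC fit", stacklevel=2)
        flags = ("non-positive signals dropped",)
    coeffs = np.polyfit(b[pos], np.log(s[pos]), 1)
    adc = float(np.clip(-coeffs[0] * 1e3, *ADC_BOUNDS))  # 1/(s/mm^2) -> 1e-3 mm^2/s
    sse = float(np.sum((np.exp(np.polyval(coeffs, b[pos])) - s[pos]) ** 2))
    return FitResult(estimate=adc, scale=float(np.exp(coeffs[1])), residual_sse=sse,
                     converged=True, n_points=s.size, flags=flags)


_FITTERS = {"IR_FSE": fit_ir_t1, "VFA_SPGR": fit_vfa_t1, "MSE": fit_mse_t2, "DWI": fit_adc}
_MAP_KIND = {"IR_FSE": ("T1", "ms"), "VFA_SPGR": ("T1", "ms"),
             "MSE": ("T2", "ms"), "DWI": ("ADC", "1e-3 mm^2/s")}


def fit_volume(
    volume: np.ndarray,
    protocol: ConventionalProtocol,
    mask: np.ndarray | None = None,
) -> tuple[QuantitativeMap, QuantitativeMap]:
    """Voxelwise fitting; returns the parameter map and a convergence map.

    ``volume`` has one signal per protocol sample point on the last axis;
    masked-out voxels are NaN in the output.
    """
    volume = np.asarray(volume, float)
    if volume.shape[-1] != protocol.n_points:
        raise InvalidParameterError(
            f"volume last axis {volume.shape[-1]} != protocol points {protocol.n_points}"
        )
    spatial = volume.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, bool)
    elif np.asarray(mask).shape != spatial:
        raise InvalidParameterError("mask shape does not match volume")
    fitter = _FITTERS[protocol.kind]
    flat = volume.reshape(-1, protocol.n_points)
    sel = np.flatnonzero(np.asarray(mask, bool).ravel())
    est = np.full(flat.shape[0], np.nan)
    ok = np.full(flat.shape[0], np.nan)
    log.info("fitting %d voxels with %s", sel.size, protocol.kind)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in sel:
            r = fitter(flat[i], protocol)
            est[i] = r.estimate if r.converged else np.nan
            ok[i] = float(r.converged)
    kind, units = _MAP_KIND[protocol.kind]
    return (
        QuantitativeMap(est.reshape(spatial), kind=kind, units=units),
        QuantitativeMap(ok.reshape(spatial), kind="converged", units=""),
    )
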