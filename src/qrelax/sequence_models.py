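"""Forward signal models for every acquisition in the pipeline.

Closed-form steady-state models (inversion recovery, spoiled gradient echo,
multi-echo spin echo, diffusion decay) plus an extended-phase-graph (EPG)
simulator of the inversion-prepared FISP fingerprinting train and a slow
isochromat Bloch simulator used as its independent oracle.

The FISP train imposes a net intravoxel dephasing of 8*pi per TR, so the
voxel-averaged echo is exactly the F0 configuration state; the EPG engine
computes it in O(N * K) for K retained configuration orders.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from .types import (
    ConventionalProtocol,
    InvalidParameterError,
    MRFSequenceParams,
    TissueParams,
)

__all__ = [
    "ir_signal",
    "ir_signal_signed",
    "spgr_signal",
    "mse_signal",
    "dwi_signal",
    "epg_fingerprint",
    "epg_fingerprints",
    "bloch_isochromat_fingerprint",
    "protocol_presets",
    "load_flip_angles",
    "default_flip_train",
    "make_default_flip_train",
]


# ---------------------------------------------------------------------------
# closed-form models
# ---------------------------------------------------------------------------

def _check_times(**kwargs: float) -> None:
    for name, val in kwargs.items():
        if not val > 0:
            raise InvalidParameterError(f"{name} must be positive, got {val}")


def ir_signal_signed(tissue: TissueParams, ti_ms: float, tr_ms: float) -> float:
    """Signed inversion-recovery signal PD*(1 - 2 e^{-TI/T1} + e^{-TR/T1})."""
    _check_times(ti_ms=ti_ms, tr_ms=tr_ms)
    if ti_ms >= tr_ms:
        raise InvalidParameterError(f"require TI < TR (TI={ti_ms}, TR={tr_ms})")
    t1 = tissue.t1
    return tissue.pd * (1.0 - 2.0 * np.exp(-ti_ms / t1) + np.exp(-tr_ms / t1))


def ir_signal(tissue: TissueParams, ti_ms: float, tr_ms: float) -> float:
    """Magnitude inversion-recovery signal.

    S(TI) = PD * |1 - 2 e^{-TI/T1} + e^{-TR/T1}|.  Nulls at TI = T1 ln 2
    when TR >> T1 and approaches PD as TI grows.
    """
    return abs(ir_signal_signed(tissue, ti_ms, tr_ms))


def spgr_signal(tissue: TissueParams, flip_deg: float, tr_ms: float) -> float:
    """Steady-state spoiled gradient echo (SPGR / FLASH) magnitude.

    S = PD sin(a) (1 - E1) / (1 - E1 cos(a)), E1 = e^{-TR/T1}; maximal at
    the Ernst angle arccos(E1).
    """
    _check_times(tr_ms=tr_ms)
    if not (0.0 <= flip_deg <= 90.0):
        raise InvalidParameterError(f"flip angle must be in [0, 90] deg, got {flip_deg}")
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / tissue.t1)
    return tissue.pd * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def mse_signal(tissue: TissueParams, te_ms: float) -> float:
    """Monoexponential spin-echo decay S = PD e^{-TE/T2}."""
    _check_times(te_ms=te_ms)
    return tissue.pd * np.exp(-te_ms / tissue.t2)


def dwi_signal(tissue: TissueParams, b_value: float) -> float:
    """Monoexponential diffusion decay S = S0 e^{-b * ADC}.

    ``b_value`` in s/mm^2, ADC in 10^-3 mm^2/s, so the exponent is
    b * adc / 1000.
    """
    if b_value < 0:
        raise InvalidParameterError(f"b-value must be >= 0, got {b_value}")
    if tissue.adc is None:
        raise InvalidParameterError("tissue has no ADC; cannot evaluate diffusion decay")
    return tissue.pd * np.exp(-b_value * tissue.adc * 1e-3)


# ---------------------------------------------------------------------------
# EPG engine
# ---------------------------------------------------------------------------

def _epg_rf_matrix(alpha_rad: float, phi_rad: float) -> np.ndarray:
    """Mixing matrix acting on (F+_k, F-_k, Z_k) for every order k."""
    a2 = alpha_rad / 2.0
    c2, s2 = np.cos(a2) ** 2, np.sin(a2) ** 2
    sa, ca = np.sin(alpha_rad), np.cos(alpha_rad)
    ep = np.exp(1j * phi_rad)
    return np.array(
        [
            [c2, ep * ep * s2, -1j * ep * sa],
            [np.conj(ep * ep) * s2, c2, 1j * np.conj(ep) * sa],
            [-0.5j * np.conj(ep) * sa, 0.5j * ep * sa, ca],
        ],
        dtype=complex,
    )


def _epg_rf_matrix_real(alpha_rad: float) -> np.ndarray:
    """Real mixing matrix for zero RF phase.

    With phi = 0, no off-resonance and a real initial Z, the transverse
    states stay purely imaginary: writing F+ = i a, F- = i b, Z = z the
    update is real in (a, b, z).  Conjugation maps a <-> -b.
    """
    a2 = alpha_rad / 2.0
    c2, s2 = np.cos(a2) ** 2, np.sin(a2) ** 2
    sa, ca = np.sin(alpha_rad), np.cos(alpha_rad)
    return np.array(
        [
            [c2, s2, -sa],
            [s2, c2, sa],
            [0.5 * sa, -0.5 * sa, ca],
        ]
    )


def epg_fingerprints(
    t1_ms: np.ndarray,
    t2_ms: np.ndarray,
    seq: MRFSequenceParams,
    pd: np.ndarray | float = 1.0,
    off_resonance_hz: np.ndarray | float = 0.0,
    n_states: int = 40,
) -> np.ndarray:
    """Simulate fingerprints for many (T1, T2) pairs at once.

    Parameters
    ----------
    t1_ms, t2_ms : array of shape (P,)
        Relaxation times of each simulated voxel / dictionary entry.
    pd : scalar or array (P,)
        Proton density scale.
    n_states : int
        Retained EPG configuration orders K.  K = 40 keeps the truncation
        error below 1e-6 relative to K = 100 on the default train.

    Returns
    -------
    ndarray, shape (N, P)
        One sample per excitation: the F0 state at the echo time (T2 decay
        over TE applied).  float64 for the pure-FISP zero-phase case,
        complex128 otherwise.
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, float))
    t2 = np.atleast_1d(np.asarray(t2_ms, float))
    if t1.shape != t2.shape:
        raise InvalidParameterError("t1 and t2 arrays must have equal shape")
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise InvalidParameterError("relaxation times must be positive")
    P = t1.size
    pd_arr = np.broadcast_to(np.asarray(pd, float), (P,)).astype(float)
    offres = np.broadcast_to(np.asarray(off_resonance_hz, float), (P,)).astype(float)

    flips = np.deg2rad(np.asarray(seq.flip_angles_deg))
    phases = seq.phases_rad()
    n_exc = seq.n_excitations
    K = int(n_states)
    if K < 2:
        raise InvalidParameterError("need at least 2 EPG states")

    te, tr = seq.te_ms, seq.tr_ms
    e1_te, e2_te = np.exp(-te / t1), np.exp(-te / t2)
    e1_rem, e2_rem = np.exp(-(tr - te) / t1), np.exp(-(tr - te) / t2)

    real_path = bool(np.all(phases == 0.0) and np.all(offres == 0.0))

    if real_path:
        # rows of S: a (=Im F+), b (=Im F-), z; purely real arithmetic
        S = np.zeros((3, K, P))
        S[2, 0, :] = pd_arr
        if seq.inversion:
            S[2] *= -1.0
            d = seq.inversion_delay_ms
            S[2] *= np.exp(-d / t1)
            S[2, 0, :] += pd_arr * (1.0 - np.exp(-d / t1))
        out = np.empty((n_exc, P))
        flat = S.reshape(3, K * P)
        for n in range(n_exc):
            R = _epg_rf_matrix_real(flips[n])
            flat[:] = R @ flat
            # echo: -i * F+_0 * e^{-TE/T2} -> real value a0 * E2(TE)
            out[n] = S[0, 0, :] * e2_te
            # relax over TE then TR-TE, recovery into Z0
            S[0] *= e2_te * e2_rem
            S[1] *= e2_te * e2_rem
            S[2] *= e1_te * e1_rem
            S[2, 0, :] += pd_arr * (1.0 - e1_te * e1_rem)
            # gradient shift: F+ up, F- down, conj coupling a0 = -b0
            S[0, 1:, :] = S[0, :-1, :]
            S[1, :-1, :] = S[1, 1:, :]
            S[1, -1, :] = 0.0
            S[0, 0, :] = -S[1, 0, :]
        return out[:, 0] if np.isscalar(t1_ms) else out

    # complex path (RF phase cycling and/or off-resonance)
    S = np.zeros((3, K, P), complex)
    S[2, 0, :] = pd_arr
    if seq.inversion:
        S[2] *= -1.0
        d = seq.inversion_delay_ms
        S[2] *= np.exp(-d / t1)
        S[2, 0, :] += pd_arr * (1.0 - np.exp(-d / t1))
    out = np.empty((n_exc, P), complex)
    flat = S.reshape(3, K * P)
    ph_te = np.exp(-2j * np.pi * offres * te * 1e-3)
    ph_rem = np.exp(-2j * np.pi * offres * (tr - te) * 1e-3)
    for n in range(n_exc):
        R = _epg_rf_matrix(flips[n], phases[n])
        flat[:] = R @ flat
        out[n] = -1j * S[0, 0, :] * e2_te * ph_te * np.exp(-1j * phases[n])
        S[0] *= e2_te * e2_rem * ph_te * ph_rem
        S[1] *= e2_te * e2_rem * np.conj(ph_te * ph_rem)
        S[2] *= e1_te * e1_rem
        S[2, 0, :] += pd_arr * (1.0 - e1_te * e1_rem)
        S[0, 1:, :] = S[0, :-1, :]
        S[1, :-1, :] = S[1, 1:, :]
        S[1, -1, :] = 0.0
        S[0, 0, :] = np.conj(S[1, 0, :])
    return out[:, 0] if np.isscalar(t1_ms) else out


def epg_fingerprint(
    tissue: TissueParams, seq: MRFSequenceParams, n_states: int = 40
) -> np.ndarray:
    """Fingerprint of a single tissue: the F0 echo train, length N."""
    sig = epg_fingerprints(
        np.array([tissue.t1]),
        np.array([tissue.t2]),
        seq,
        pd=tissue.pd,
        off_resonance_hz=tissue.off_resonance,
        n_states=n_states,
    )
    return sig[:, 0]


# ---------------------------------------------------------------------------
# isochromat Bloch oracle
# ---------------------------------------------------------------------------

def bloch_isochromat_fingerprint(
    tissue: TissueParams, seq: MRFSequenceParams, n_isochromats: int = 200
) -> np.ndarray:
    """Brute-force voxel-average fingerprint from explicit Bloch spins.

    A uniform fan of isochromats spans the per-TR gradient dephasing; each
    spin undergoes the RF rotation, relaxes to TE (echo recorded as the mean
    transverse magnetisation), then relaxes over TR-TE while accruing its
    gradient phase.  Converges to the EPG F0 signal as the fan is refined.
    Deliberately simple and slow; used to validate ``epg_fingerprint``.

    When the per-TR dephasing is an integer number m of full 2*pi cycles
    (here m = 4), a fan whose size shares a factor with m aliases high
    configuration orders back into the echo; the fan size is therefore
    rounded up to the next integer coprime with m, so the first aliased
    order is the fan size itself.
    """
    if n_isochromats < 50:
        raise InvalidParameterError("need >= 50 isochromats for a meaningful average")
    S = int(n_isochromats)
    cycles = seq.dephasing_per_tr / (2.0 * np.pi)
    if abs(cycles - round(cycles)) < 1e-9 and round(cycles) != 0:
        m = abs(int(round(cycles)))
        while np.gcd(m, S) != 1:
            S += 1
    u = (np.arange(S) + 0.5) / S
    grad_phase = seq.dephasing_per_tr * u  # per-TR phase of each spin, rad

    flips = np.deg2rad(np.asarray(seq.flip_angles_deg))
    phases = seq.phases_rad()
    t1, t2, pd = tissue.t1, tissue.t2, tissue.pd
    te, tr = seq.te_ms, seq.tr_ms
    e1_te, e2_te = np.exp(-te / t1), np.exp(-te / t2)
    e1_rem, e2_rem = np.exp(-(tr - te) / t1), np.exp(-(tr - te) / t2)
    w_te = 2 * np.pi * tissue.off_resonance * te * 1e-3
    w_rem = 2 * np.pi * tissue.off_resonance * (tr - te) * 1e-3

    mx = np.zeros(S)
    my = np.zeros(S)
    mz = np.full(S, pd)
    if seq.inversion:
        mz = -mz
        d = seq.inversion_delay_ms
        mz = mz * np.exp(-d / t1) + pd * (1.0 - np.exp(-d / t1))

    out = np.empty(seq.n_excitations, complex)
    for n in range(seq.n_excitations):
        a, phi = flips[n], phases[n]
        # rotate by a about an axis at angle phi in the transverse plane
        ca, sa = np.cos(a), np.sin(a)
        cp, sp = np.cos(phi), np.sin(phi)
        # Rz(phi) Rx(a) Rz(-phi)
        mx2 = (cp * cp + sp * sp * ca) * mx + cp * sp * (1 - ca) * my + sp * sa * mz
        my2 = cp * sp * (1 - ca) * mx + (sp * sp + cp * cp * ca) * my - cp * sa * mz
        mz2 = -sp * sa * mx + cp * sa * my + ca * mz
        mx, my, mz = mx2, my2, mz2
        # to echo: relax + off-resonance precession (no gradient moment at TE)
        c, s = np.cos(-w_te), np.sin(-w_te)
        mx, my = e2_te * (c * mx - s * my), e2_te * (s * mx + c * my)
        mz = mz * e1_te + pd * (1.0 - e1_te)
        out[n] = -1j * np.mean(mx + 1j * my) * np.exp(-1j * phi)
        # remainder of TR: relax + gradient dephasing per spin
        th = grad_phase - w_rem
        c, s = np.cos(th), np.sin(th)
        mx, my = e2_rem * (c * mx - s * my), e2_rem * (s * mx + c * my)
        mz = mz * e1_rem + pd * (1.0 - e1_rem)
    return out


# ---------------------------------------------------------------------------
# flip-angle train and protocol presets
# ---------------------------------------------------------------------------

def make_default_flip_train(
    n: int = 979,
    peaks_deg: tuple[float, ...] = (60.0, 45.0, 70.0, 50.0, 65.0),
    baseline_deg: float = 10.0,
    perturbation_deg: float = 1.0,
    seed: int = 7,
) -> np.ndarray:
    """Synthesize a fingerprinting flip-angle train.

    Repeated half-sinusoid lobes (one per peak) riding on a small baseline,
    with a fixed-seed pseudo-random perturbation to break periodicity.  This
    is a configurable stand-in train: published lists can be substituted via
    a plain-text file (one angle per line, '#' comments).
    """
    n_lobes = len(peaks_deg)
    bounds = np.linspace(0, n, n_lobes + 1).astype(int)
    rng = np.random.default_rng(seed)
    angles = np.empty(n)
    for j in range(n_lobes):
        lo, hi = bounds[j], bounds[j + 1]
        L = hi - lo
        t = (np.arange(L) + 0.5) / L
        angles[lo:hi] = baseline_deg + (peaks_deg[j] - baseline_deg) * np.sin(np.pi * t)
    angles += rng.normal(0.0, perturbation_deg, size=n)
    return np.clip(angles, 0.0, 90.0)


def load_flip_angles(path) -> np.ndarray:
    """Load a flip-angle train: one angle in degrees per line, '#' comments."""
    angles = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                angles.append(float(line))
    if not angles:
        raise InvalidParameterError(f"no flip angles found in {path}")
    return np.asarray(angles)


def default_flip_train() -> np.ndarray:
    """The packaged 979-angle default train."""
    ref = resources.files("qrelax.data").joinpath("mrf_flip_angles.txt")
    with resources.as_file(ref) as path:
        return load_flip_angles(path)


def protocol_presets() -> dict[str, ConventionalProtocol | MRFSequenceParams]:
    """Named acquisition presets used throughout the pipelines.

    Conventional presets carry the exact published sample-point lists;
    ``mrf_default`` is the 979-excitation inversion-prepared FISP train
    (TR 10 ms, TE 2.5 ms, 8*pi dephasing per TR; 9.79 s per slice).
    """
    return {
        "phantom_ir": ConventionalProtocol(
            kind="IR_FSE",
            sample_points=(50, 100, 200, 400, 800, 1600, 2400),
            tr_ms=8000.0,
            te_ms=13.0,
        ),
        "phantom_vfa": ConventionalProtocol(
            kind="VFA_SPGR",
            sample_points=(2, 5, 8, 12, 15, 18, 22, 26),
            tr_ms=10.0,
            te_ms=1.6,
        ),
        "phantom_mse": ConventionalProtocol(
            kind="MSE",
            sample_points=(8.2, 16.3, 24.5, 32.6, 40.8, 49.0, 57.1, 65.3),
            tr_ms=600.0,
        ),
        "invivo_vfa": ConventionalProtocol(
            kind="VFA_SPGR",
            sample_points=(2, 5, 12, 20, 32),
            tr_ms=15.0,
            te_ms=2.0,
            seconds_per_point=52.0,
        ),
        "invivo_mse": ConventionalProtocol(
            kind="MSE",
            sample_points=(8.5, 16.9, 25.4, 42.3, 50.8, 59.2, 67.7),
            tr_ms=2600.0,
        ),
        "invivo_dwi": ConventionalProtocol(
            kind="DWI",
            sample_points=(150, 750, 1400),
        ),
        "mrf_default": MRFSequenceParams(
            flip_angles_deg=tuple(default_flip_train()),
            tr_ms=10.0,
            te_ms=2.5,
            inversion=True,
            inversion_delay_ms=18.0,
            dephasing_per_tr=8.0 * np.pi,
        ),
    }


def get_preset(name: str) -> ConventionalProtocol | MRFSequenceParams:
    presets = protocol_presets()
    if name not in presets:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]
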