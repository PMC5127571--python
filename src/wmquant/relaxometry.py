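"""Relaxometry: myelin water fraction, magnetization transfer ratio, R2*.

The myelin water fraction (MWF) is estimated from a 32-echo CPMG train by
regularized non-negative least squares against an extended-phase-graph
(EPG) decay basis, which models the stimulated echoes produced by
refocusing pulses below 180 deg.  The T2 spectrum is resolved on 32
logarithmically spaced T2 values and the MWF is the spectral amplitude
fraction below a 30 ms cutoff (the short-T2 myelin-water pool at 3 T).

Regularisation follows the chi-square-ratio convention: a minimum-energy
(Tikhonov) penalty whose weight is chosen by bisection so that the misfit
equals 1.01 times the unregularised minimum.

The refocusing flip angle is handled in two steps across a voxel set:
first it is fitted freely per voxel; then each voxel's flip is fixed to
the measured B1 map rescaled by a single global factor that matches the
median fitted flip, and the spectra are refitted.  The anchoring makes the
result invariant to a global multiplicative miscalibration of the B1 map.

MTR and R2* are computed here as well: MTR = 100 (non-MT - MT)/non-MT, and
R2* by Levenberg-Marquardt fitting of the *squared* mono-exponential decay
to the squared magnitudes, which down-weights low-signal time points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, nnls

from .epg import cpmg_echo_train

__all__ = [
    "EchoTrain",
    "T2Spectrum",
    "MwfResult",
    "default_t2_grid",
    "epg_decay_basis",
    "fit_t2_spectrum",
    "mwf_from_spectrum",
    "fit_mwf_two_step",
    "compute_mtr",
    "fit_r2star",
]

log = logging.getLogger(__name__)

MWF_CUTOFF_MS = 30.0
T1_DEFAULT_MS = 1000.0


def default_t2_grid(n: int = 32, t2_min: float = 10.0, t2_max: float = 2000.0) -> np.ndarray:
    """32 logarithmically spaced T2 values (ms), 10 ms to 2 s."""
    return np.geomspace(t2_min, t2_max, n)


@dataclass(frozen=True)
class EchoTrain:
    """One voxel's CPMG echo amplitudes at strictly increasing echo times (ms)."""

    echo_times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, float)
        amp = np.asarray(self.amplitudes, float)
        if te.shape != amp.shape or te.ndim != 1:
            raise ValueError("echo_times and amplitudes must be 1-D and equal length")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        object.__setattr__(self, "echo_times", te)
        object.__setattr__(self, "amplitudes", amp)

    @property
    def echo_spacing(self) -> float:
        return float(self.echo_times[0])


@dataclass(frozen=True)
class T2Spectrum:
    """Non-negative amplitude distribution over a logarithmic T2 grid."""

    t2_grid: np.ndarray
    amplitudes: np.ndarray
    flip_angle: float
    chi2_ratio: float  # achieved chi^2 over unregularised minimum
    valid: bool = True

    @property
    def total_signal(self) -> float:
        return float(self.amplitudes.sum())


@dataclass(frozen=True)
class MwfResult:
    mwf: float
    cutoff: float
    total_signal: float
    flip_angle: float
    valid: bool = True

    def as_scalars(self) -> dict[str, float]:
        return {"mwf": self.mwf}


def epg_decay_basis(
    flip_deg: float,
    t2_grid: np.ndarray,
    t1: float,
    echo_times: np.ndarray,
) -> np.ndarray:
    """EPG echo-amplitude basis, one column per T2 grid value.

    ``echo_times`` must form the arithmetic CPMG sequence (k * esp).  At a
    180 deg flip each column is exactly exp(-TE/T2).
    """
    te = np.asarray(echo_times, float)
    esp = te[0]
    if np.max(np.abs(np.diff(te) - esp)) > 1e-9 * esp:
        raise ValueError("echo times must be an arithmetic CPMG sequence")
    t2_grid = np.asarray(t2_grid, float)
    if t1 <= 0:
        raise ValueError("T1 must be positive")
    # T1 < T2 is unphysical for tissue but the EPG recursion stays well
    # defined; the long tail of the default grid (up to 2 s) intentionally
    # exceeds the nominal T1 so CSF-like components remain representable.
    return cpmg_echo_train(flip_deg, t2_grid, t1, esp, len(te))


def _nnls_chi2(basis: np.ndarray, y: np.ndarray, mu: float) -> tuple[np.ndarray, float]:
    """NNLS of [basis; mu I] against [y; 0]; returns (amplitudes, misfit chi^2)."""
    if mu > 0:
        A = np.vstack([basis, mu * np.eye(basis.shape[1])])
        rhs = np.concatenate([y, np.zeros(basis.shape[1])])
    else:
        A, rhs = basis, y
    amps, _ = nnls(A, rhs)
    resid = basis @ amps - y
    return amps, float(resid @ resid)


def fit_t2_spectrum(
    train: EchoTrain,
    flip_angle: float | None = None,
    chi2_factor: float = 1.01,
    t2_grid: np.ndarray | None = None,
    t1: float = T1_DEFAULT_MS,
    flip_bounds: tuple[float, float] = (90.0, 180.0),
    flip_tol: float = 0.1,
) -> T2Spectrum:
    """Regularized NNLS T2 spectrum of one echo train.

    ``flip_angle=None`` searches the refocusing flip over ``flip_bounds``
    by golden section (tolerance ``flip_tol`` deg), minimising the
    unregularised misfit.  The Tikhonov weight is then set by bisection so
    that chi^2 = ``chi2_factor`` x chi^2_min to 0.05% relative.
    """
    if chi2_factor < 1.0:
        raise ValueError("chi2_factor must be >= 1")
    if t2_grid is None:
        t2_grid = default_t2_grid()
    y = train.amplitudes
    if np.all(y == 0):
        return T2Spectrum(
            t2_grid, np.zeros_like(t2_grid), np.nan, 1.0, valid=False
        )

    if flip_angle is None:
        flip_angle = _golden_flip_search(train, t2_grid, t1, flip_bounds, flip_tol)
    basis = epg_decay_basis(flip_angle, t2_grid, t1, train.echo_times)

    amps0, chi2_min = _nnls_chi2(basis, y, 0.0)
    if chi2_factor == 1.0 or chi2_min <= 0.0:
        return T2Spectrum(t2_grid, amps0, flip_angle, 1.0, valid=True)
    target = chi2_factor * chi2_min

    # bracket: grow mu until chi^2 overshoots the target
    mu_lo, mu_hi = 0.0, 1e-6 * float(np.linalg.norm(y))
    for _ in range(80):
        _, chi2_hi = _nnls_chi2(basis, y, mu_hi)
        if chi2_hi >= target:
            break
        mu_lo = mu_hi
        mu_hi *= 4.0
    amps, chi2 = amps0, chi2_min
    for _ in range(100):
        mu_mid = 0.5 * (mu_lo + mu_hi)
        amps, chi2 = _nnls_chi2(basis, y, mu_mid)
        if abs(chi2 / target - 1.0) < 5e-4:
            break
        if chi2 < target:
            mu_lo = mu_mid
        else:
            mu_hi = mu_mid
    return T2Spectrum(t2_grid, amps, flip_angle, chi2 / chi2_min, valid=True)


def _golden_flip_search(
    train: EchoTrain,
    t2_grid: np.ndarray,
    t1: float,
    bounds: tuple[float, float],
    tol: float,
) -> float:
    """Golden-section minimisation of the NNLS misfit over the flip angle."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0

    def misfit(alpha: float) -> float:
        basis = epg_decay_basis(alpha, t2_grid, t1, train.echo_times)
        return _nnls_chi2(basis, train.amplitudes, 0.0)[1]

    a, b = bounds
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = misfit(c), misfit(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = misfit(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = misfit(d)
    return 0.5 * (a + b)


def mwf_from_spectrum(spectrum: T2Spectrum, cutoff: float = MWF_CUTOFF_MS) -> MwfResult:
    """Myelin water fraction: spectral amplitude below ``cutoff`` over total."""
    total = spectrum.total_signal
    if total <= 0:
        return MwfResult(np.nan, cutoff, 0.0, spectrum.flip_angle, valid=False)
    short = float(spectrum.amplitudes[spectrum.t2_grid < cutoff].sum())
    return MwfResult(short / total, cutoff, total, spectrum.flip_angle, spectrum.valid)


def fit_mwf_two_step(
    trains: np.ndarray,
    echo_times: np.ndarray,
    b1_map: np.ndarray | None = None,
    cutoff: float = MWF_CUTOFF_MS,
    chi2_factor: float = 1.01,
    t2_grid: np.ndarray | None = None,
    t1: float = T1_DEFAULT_MS,
) -> list[MwfResult]:
    """Two-step flip-anchored MWF over a voxel set.

    Step 1 fits every voxel with a free flip angle; step 2 fixes each
    voxel's flip to ``b1_map * c`` where the global scalar ``c`` makes the
    median of those flips equal the step-1 median, then refits with the
    chi^2-ratio regularisation and derives the MWF.  With fewer than 3
    voxels the rescaling is skipped and step-1 flips are used as-is.

    Parameters
    ----------
    trains : ndarray, shape (n_voxels, n_echoes)
    echo_times : ndarray, shape (n_echoes,)
    b1_map : ndarray, shape (n_voxels,), relative flip scaling (1 = nominal)
    """
    trains = np.atleast_2d(np.asarray(trains, float))
    n_vox = trains.shape[0]
    if b1_map is None:
        b1_map = np.ones(n_vox)
    b1_map = np.asarray(b1_map, float).ravel()
    if np.any(b1_map <= 0):
        raise ValueError("B1 map must be positive")
    if b1_map.shape[0] != n_vox:
        raise ValueError("B1 map length does not match number of voxels")

    flips1 = np.empty(n_vox)
    for i in range(n_vox):
        et = EchoTrain(echo_times, trains[i])
        if np.all(trains[i] == 0):
            flips1[i] = np.nan
            continue
        spec = fit_t2_spectrum(et, flip_angle=None, chi2_factor=1.0, t2_grid=t2_grid, t1=t1)
        flips1[i] = spec.flip_angle

    finite = np.isfinite(flips1)
    if finite.sum() < 3:
        log.warning("fewer than 3 usable voxels: B1 rescaling skipped")
        flips2 = flips1
    else:
        median1 = float(np.median(flips1[finite]))
        scale = median1 / float(np.median(b1_map[finite]))
        flips2 = np.clip(b1_map * scale, 1.0, 180.0)

    results: list[MwfResult] = []
    for i in range(n_vox):
        if not np.isfinite(flips1[i]):
            results.append(MwfResult(np.nan, cutoff, 0.0, np.nan, valid=False))
            continue
        et = EchoTrain(echo_times, trains[i])
        spec = fit_t2_spectrum(
            et, flip_angle=float(flips2[i]), chi2_factor=chi2_factor,
            t2_grid=t2_grid, t1=t1,
        )
        results.append(mwf_from_spectrum(spec, cutoff))
    return results


def compute_mtr(non_mt, mt):
    """Magnetization transfer ratio in percent: 100 (non-MT - MT)/non-MT.

    Voxels with non-positive non-MT signal are returned as NaN.
    """
    non_mt = np.asarray(non_mt, float)
    mt = np.asarray(mt, float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mtr = 100.0 * (non_mt - mt) / non_mt
    return np.where(non_mt > 0, mtr, np.nan)


def fit_r2star(
    magnitudes: np.ndarray, echo_times_ms: np.ndarray
) -> float:
    """R2* (1/s) from multi-echo gradient-echo magnitudes.

    Levenberg-Marquardt fit of the squared mono-exponential
    (S0 exp(-R2* TE))^2 to the squared magnitudes; squaring de-emphasises
    low-signal late echoes.  Initialised from a log-linear two-point
    estimate.  Returns NaN on non-convergence.
    """
    y = np.asarray(magnitudes, float)
    te_s = np.asarray(echo_times_ms, float) / 1000.0
    if y.shape[0] < 3:
        raise ValueError("at least 3 echoes are required")
    if np.any(y < 0):
        raise ValueError("magnitudes must be non-negative")
    pos = y > 0
    if pos.sum() < 2:
        return np.nan
    i0, i1 = np.flatnonzero(pos)[[0, -1]]
    if i0 == i1:
        return np.nan
    r0 = max(np.log(y[i0] / y[i1]) / (te_s[i1] - te_s[i0]), 0.0)
    s00 = y[i0] * np.exp(r0 * te_s[i0])

    def residuals(p):
        s0, r2s = p
        return (s0 * np.exp(-r2s * te_s)) ** 2 - y**2

    res = least_squares(residuals, [s00, r0], method="lm", xtol=1e-14, ftol=1e-14)
    if not res.success:
        log.warning("R2* fit did not converge")
        return np.nan
    return float(abs(res.x[1]))
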