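"""Voxel-wise diffusion model fitting: DTI, constrained DKI, and NODDI.

Three models of increasing complexity are fitted to two-shell
diffusion-weighted data:

* **DTI** -- ordinary log-linear least squares of the single-tensor model,
  restricted to b=0 plus the low (b = 700 s/mm**2) shell for comparability
  with classic DTI studies.
* **DKI** -- linear least squares of the cumulant expansion
  ln S = ln S0 - b D(n) + (1/6) b^2 V(n), with V(n) = MD^2 W(n) the quartic
  kurtosis form, subject to per-direction constraints that stabilise the
  fit against noise: apparent diffusivity d(n) >= 0.1 um^2/ms and apparent
  kurtosis 0 <= K_app(n) <= 3 / (b_max d(n)).  In this parametrisation all
  three constraints are linear in the unknowns, so the problem is a
  quadratic program solved exactly (no linearisation step is needed).
* **NODDI** -- the three-compartment Watson stick/zeppelin/ball model with
  fixed intrinsic diffusivities, fitted by a coarse grid search followed
  by bounded local least squares.

Scalar maps: MD, FA, axial/radial eigenvalues (DTI); MK/RK/AK, computed as
numerical spherical averages of K_app (DKI); ICVF, ODI, ISO (NODDI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize

from .gradients import GradientTable, fibonacci_sphere
from .phantom import D_ISO_DEFAULT, D_PAR_DEFAULT
from .watson import kappa_from_odi, odi_from_kappa, watson_stick_attenuation, watson_tau

__all__ = [
    "TensorFit",
    "KurtosisFit",
    "NoddiFit",
    "fit_dti",
    "fit_dki",
    "fit_noddi",
    "map_volume",
]

log = logging.getLogger(__name__)

#: Lower bound on apparent diffusivity in the constrained DKI fit (um^2/ms).
D_MIN = 0.1

# quartic monomial exponents and multinomial multiplicities for the 15
# unique elements of a fully symmetric rank-4 tensor in 3 dimensions
_QUARTIC_IDX = [
    (4, 0, 0), (0, 4, 0), (0, 0, 4),
    (3, 1, 0), (3, 0, 1), (1, 3, 0), (0, 3, 1), (1, 0, 3), (0, 1, 3),
    (2, 2, 0), (2, 0, 2), (0, 2, 2),
    (2, 1, 1), (1, 2, 1), (1, 1, 2),
]
_QUARTIC_MULT = np.array(
    [1, 1, 1, 4, 4, 4, 4, 4, 4, 6, 6, 6, 12, 12, 12], dtype=float
)


def _d_design(dirs: np.ndarray) -> np.ndarray:
    """(N, 6) rows mapping [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz] -> d(n)."""
    x, y, z = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    return np.column_stack([x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z])


def _v_design(dirs: np.ndarray) -> np.ndarray:
    """(N, 15) rows mapping the unique quartic coefficients -> V(n)."""
    x, y, z = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    cols = [
        x ** i * y ** j * z ** k for (i, j, k) in _QUARTIC_IDX
    ]
    return np.column_stack(cols) * _QUARTIC_MULT[None, :]


def _tensor_from_6(d6: np.ndarray) -> np.ndarray:
    dxx, dyy, dzz, dxy, dxz, dyz = d6
    return np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])


def _fa_from_eigenvalues(lam: np.ndarray) -> float:
    denom = np.sum(lam**2)
    if denom <= 0:
        return 0.0  # all-zero tensor: anisotropy defined as 0
    mean = lam.mean()
    fa = np.sqrt(1.5 * np.sum((lam - mean) ** 2) / denom)
    return float(min(fa, 1.0))


# ---------------------------------------------------------------------------
# DTI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TensorFit:
    """Log-linear single-tensor fit (eigenvalues sorted descending)."""

    log_s0: float
    d_tensor: np.ndarray  # 3x3, um^2/ms
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, matching eigenvalue order
    valid: bool = True

    @property
    def md(self) -> float:
        return float(self.eigenvalues.mean())

    @property
    def fa(self) -> float:
        return _fa_from_eigenvalues(self.eigenvalues)

    @property
    def axial(self) -> float:
        return float(self.eigenvalues[0])

    @property
    def radial(self) -> float:
        return float(self.eigenvalues[1:].mean())

    @property
    def principal_direction(self) -> np.ndarray:
        return self.eigenvectors[:, 0]

    def as_scalars(self) -> dict[str, float]:
        return {
            "md": self.md,
            "fa": self.fa,
            "lambda_par": self.axial,
            "lambda_perp": self.radial,
        }


def _invalid_tensor_fit() -> TensorFit:
    nan3 = np.full(3, np.nan)
    return TensorFit(np.nan, np.full((3, 3), np.nan), nan3, np.full((3, 3), np.nan), False)


def fit_dti(signal: np.ndarray, gtab_low: GradientTable) -> TensorFit:
    """Ordinary log-linear least-squares tensor fit on the low shell.

    ``gtab_low`` must contain b=0 plus a single non-zero shell and at least
    7 measurements.  Non-positive signals flag the voxel invalid (NaN maps)
    rather than raising.
    """
    signal = np.asarray(signal, float)
    if len(gtab_low.shells()) != 1:
        raise ValueError(
            "DTI fit expects b=0 plus exactly one shell; pass gtab.low_shell()"
        )
    if len(gtab_low) < 7:
        raise ValueError("at least 7 measurements are required for the tensor fit")
    if signal.shape[0] != len(gtab_low):
        raise ValueError("signal length does not match gradient table")
    if np.any(signal <= 0) or not np.all(np.isfinite(signal)):
        return _invalid_tensor_fit()
    A = np.column_stack(
        [np.ones(len(gtab_low)), -gtab_low.bvals_ms[:, None] * _d_design(gtab_low.bvecs)]
    )
    x, *_ = np.linalg.lstsq(A, np.log(signal), rcond=None)
    D = _tensor_from_6(x[1:])
    lam, vec = np.linalg.eigh(D)
    order = np.argsort(lam)[::-1]  # stable descending sort
    return TensorFit(float(x[0]), D, lam[order], vec[:, order])


# ---------------------------------------------------------------------------
# DKI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KurtosisFit:
    """Constrained kurtosis-tensor fit.

    ``v_coeffs`` are the 15 unique coefficients of V = MD^2 W; the
    dimensionless kurtosis tensor W follows as V / MD^2.  MK/RK/AK are
    numerical directional averages of K_app(n) = V(n) / d(n)^2.
    """

    log_s0: float
    d_tensor: np.ndarray
    v_coeffs: np.ndarray
    mk: float
    rk: float
    ak: float
    constrained: bool = False  # True when the QP (not plain LLS) was used
    valid: bool = True

    @property
    def w_coeffs(self) -> np.ndarray:
        md = float(np.trace(self.d_tensor)) / 3.0
        return self.v_coeffs / md**2

    def d_app(self, dirs: np.ndarray) -> np.ndarray:
        return _d_design(dirs) @ self.d_tensor[[0, 1, 2, 0, 0, 1], [0, 1, 2, 1, 2, 2]]

    def k_app(self, dirs: np.ndarray) -> np.ndarray:
        d = self.d_app(dirs)
        return _v_design(dirs) @ self.v_coeffs / np.maximum(d, 1e-12) ** 2

    def as_scalars(self) -> dict[str, float]:
        md = float(np.trace(self.d_tensor)) / 3.0
        return {"md": md, "mk": self.mk, "rk": self.rk, "ak": self.ak}


_MK_DIRS = fibonacci_sphere(10000)
_MK_D = _d_design(_MK_DIRS)
_MK_V = _v_design(_MK_DIRS)


def _kurtosis_summaries(d6: np.ndarray, v15: np.ndarray) -> tuple[float, float, float]:
    """MK (10k-direction spherical mean), RK (great-circle mean), AK."""
    d_app = _MK_D @ d6
    k_app = (_MK_V @ v15) / np.maximum(d_app, 1e-12) ** 2
    mk = float(k_app.mean())
    D = _tensor_from_6(d6)
    lam, vec = np.linalg.eigh(D)
    e1, e2, e3 = vec[:, 2], vec[:, 1], vec[:, 0]  # descending
    psi = np.linspace(0.0, 2.0 * np.pi, 256, endpoint=False)
    circle = np.outer(np.cos(psi), e2) + np.outer(np.sin(psi), e3)
    d_c = _d_design(circle) @ d6
    k_c = (_v_design(circle) @ v15) / np.maximum(d_c, 1e-12) ** 2
    rk = float(k_c.mean())
    ax = e1[None, :]
    d_a = float((_d_design(ax) @ d6)[0])
    ak = float((_v_design(ax) @ v15)[0] / max(d_a, 1e-12) ** 2)
    return mk, rk, ak


def fit_dki(signal: np.ndarray, gtab: GradientTable) -> KurtosisFit:
    """Constrained linear least-squares kurtosis fit on both shells.

    Minimises ||A x - ln S||^2 over x = (ln S0, D, V) subject to, for every
    acquired direction n:  d(n) >= 0.1 um^2/ms,  V(n) >= 0  and
    V(n) <= (3 / b_max) d(n)  (the kurtosis cap K_app <= 3/(b_max d)).
    All constraints are linear in x, so the active-set solution is exact.
    The unconstrained solution is returned directly when it is feasible;
    if the QP solver fails the unconstrained estimate is returned with the
    voxel flagged invalid.
    """
    signal = np.asarray(signal, float)
    if len(gtab.shells()) < 2:
        raise ValueError("DKI requires at least two non-zero shells")
    if len(gtab) < 22:
        raise ValueError("at least 22 measurements are required for the kurtosis fit")
    if signal.shape[0] != len(gtab):
        raise ValueError("signal length does not match gradient table")
    if np.any(signal <= 0) or not np.all(np.isfinite(signal)):
        nan6 = np.full(6, np.nan)
        return KurtosisFit(
            np.nan, np.full((3, 3), np.nan), np.full(15, np.nan),
            np.nan, np.nan, np.nan, False, False,
        )
    b = gtab.bvals_ms
    A = np.column_stack(
        [
            np.ones(len(gtab)),
            -b[:, None] * _d_design(gtab.bvecs),
            (b[:, None] ** 2 / 6.0) * _v_design(gtab.bvecs),
        ]
    )
    y = np.log(signal)
    x0, *_ = np.linalg.lstsq(A, y, rcond=None)

    dirs = gtab.bvecs[gtab.dwi_mask]
    Dd = _d_design(dirs)
    Vd = _v_design(dirs)
    b_max = b.max()
    zeros6, zeros15 = np.zeros((len(dirs), 1)), np.zeros((len(dirs), 15))
    # G x >= h, stacked: diffusivity floor, kurtosis >= 0, kurtosis cap
    G = np.vstack(
        [
            np.hstack([zeros6, Dd, zeros15]),
            np.hstack([zeros6, np.zeros_like(Dd), Vd]),
            np.hstack([zeros6, (3.0 / b_max) * Dd, -Vd]),
        ]
    )
    h = np.concatenate([np.full(len(dirs), D_MIN), np.zeros(2 * len(dirs))])

    x, constrained, valid = x0, False, True
    if np.any(G @ x0 - h < -1e-10):
        res = minimize(
            lambda z: 0.5 * np.sum((A @ z - y) ** 2),
            x0,
            jac=lambda z: A.T @ (A @ z - y),
            method="SLSQP",
            constraints=[{"type": "ineq", "fun": lambda z: G @ z - h, "jac": lambda z: G}],
            options={"maxiter": 500, "ftol": 1e-12},
        )
        if res.success:
            x, constrained = res.x, True
        else:  # infeasible/failed: keep unconstrained estimate, flag voxel
            log.warning("constrained DKI solve failed: %s", res.message)
            valid = False
    mk, rk, ak = _kurtosis_summaries(x[1:7], x[7:])
    return KurtosisFit(
        float(x[0]), _tensor_from_6(x[1:7]), x[7:], mk, rk, ak, constrained, valid
    )


# ---------------------------------------------------------------------------
# NODDI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoddiFit:
    """Three-compartment neurite model fit."""

    icvf: float
    odi: float
    iso_fraction: float
    kappa: float
    mean_orientation: np.ndarray
    fit_residual: float  # sum of squared signal residuals
    valid: bool = True

    def as_scalars(self) -> dict[str, float]:
        return {"icvf": self.icvf, "odi": self.odi, "iso": self.iso_fraction}


def _noddi_attenuation(
    b_ms: np.ndarray,
    cos_beta: np.ndarray,
    icvf: float,
    odi: float,
    iso: float,
    d_par: float,
    d_iso: float,
) -> np.ndarray:
    kappa = kappa_from_odi(odi)
    a_ic = watson_stick_attenuation(b_ms * d_par, cos_beta, kappa)
    tau = watson_tau(kappa)
    d_perp0 = d_par * (1.0 - icvf)
    d_par_ec = d_perp0 + (d_par - d_perp0) * tau
    d_perp_ec = d_perp0 + (d_par - d_perp0) * (1.0 - tau) / 2.0
    a_ec = np.exp(-b_ms * (d_perp_ec + (d_par_ec - d_perp_ec) * cos_beta**2))
    return (1.0 - iso) * (icvf * a_ic + (1.0 - icvf) * a_ec) + iso * np.exp(
        -b_ms * d_iso
    )


def _angles_from_vec(v: np.ndarray) -> tuple[float, float]:
    theta = float(np.arccos(np.clip(v[2], -1.0, 1.0)))
    phi = float(np.arctan2(v[1], v[0]))
    return theta, phi


_GRID_ICVF = np.array([0.2, 0.4, 0.55, 0.7, 0.85])
_GRID_ODI = np.array([0.03, 0.08, 0.15, 0.25, 0.4, 0.7])
_GRID_ISO = np.array([0.0, 0.05, 0.15, 0.35])


def fit_noddi(
    signal: np.ndarray,
    gtab: GradientTable,
    d_par: float = D_PAR_DEFAULT,
    d_iso: float = D_ISO_DEFAULT,
    max_nfev: int = 400,
) -> NoddiFit:
    """Grid-initialised bounded least-squares fit of the neurite model.

    S0 is taken as the mean b=0 signal; the mean orientation is initialised
    from the principal eigenvector of an internal log-linear tensor fit and
    optimised jointly with (ICVF, ODI, ISO).  A voxel that exhausts the
    iteration budget returns the best parameters found, flagged invalid.
    """
    signal = np.asarray(signal, float)
    if len(gtab.shells()) < 2:
        raise ValueError("NODDI requires two shells")
    if np.any(signal <= 0) or not np.all(np.isfinite(signal)):
        return NoddiFit(np.nan, np.nan, np.nan, np.nan, np.full(3, np.nan), np.nan, False)
    s0 = float(signal[gtab.b0_mask].mean())
    b = gtab.bvals_ms

    # orientation initialisation: quick unconstrained tensor on all data
    A = np.column_stack([np.ones(len(gtab)), -b[:, None] * _d_design(gtab.bvecs)])
    xt, *_ = np.linalg.lstsq(A, np.log(signal), rcond=None)
    lam, vec = np.linalg.eigh(_tensor_from_6(xt[1:]))
    mu0 = vec[:, np.argmax(lam)]
    cos0 = gtab.bvecs @ mu0

    best, best_sse = None, np.inf
    for icvf in _GRID_ICVF:
        for odi in _GRID_ODI:
            for iso in _GRID_ISO:
                model = s0 * _noddi_attenuation(b, cos0, icvf, odi, iso, d_par, d_iso)
                sse = float(np.sum((model - signal) ** 2))
                if sse < best_sse:
                    best, best_sse = (icvf, odi, iso), sse
    theta0, phi0 = _angles_from_vec(mu0)
    p0 = np.array([*best, theta0, phi0])

    def residuals(p: np.ndarray) -> np.ndarray:
        icvf, odi, iso, theta, phi = p
        mu = np.array(
            [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
        )
        att = _noddi_attenuation(b, gtab.bvecs @ mu, icvf, odi, iso, d_par, d_iso)
        return s0 * att - signal

    res = least_squares(
        residuals,
        p0,
        bounds=([0.0, 1e-3, 0.0, -np.inf, -np.inf], [1.0, 1.0, 1.0, np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=max_nfev,
    )
    icvf, odi, iso, theta, phi = res.x
    mu = np.array(
        [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
    )
    mu /= np.linalg.norm(mu)
    converged = res.status > 0
    if not converged:
        log.warning("NODDI fit did not converge; returning best-so-far")
    return NoddiFit(
        float(icvf),
        float(odi),
        float(iso),
        kappa_from_odi(float(odi)),
        mu,
        float(2.0 * res.cost),
        converged,
    )


# ---------------------------------------------------------------------------
# volume mapping
# ---------------------------------------------------------------------------

def map_volume(
    fitter,
    volume: np.ndarray,
    gtab: GradientTable | None,
    mask: np.ndarray,
    progress_every: int = 500,
    **kwargs,
) -> dict[str, np.ndarray]:
    """Apply a voxel fitter across a masked 4D volume.

    ``fitter(signal, gtab, **kwargs)`` (or ``fitter(signal, **kwargs)``
    when ``gtab`` is None) must return an object with ``as_scalars()``.
    Unmasked voxels are NaN in every output map.
    """
    volume = np.asarray(volume)
    mask = np.asarray(mask, bool)
    if mask.shape != volume.shape[:-1]:
        raise ValueError(
            f"mask shape {mask.shape} does not match volume {volume.shape[:-1]}"
        )
    maps: dict[str, np.ndarray] = {}
    idx = np.argwhere(mask)
    for count, ijk in enumerate(idx):
        sig = volume[tuple(ijk)]
        fit = fitter(sig, gtab, **kwargs) if gtab is not None else fitter(sig, **kwargs)
        for name, value in fit.as_scalars().items():
            if name not in maps:
                maps[name] = np.full(mask.shape, np.nan)
            maps[name][tuple(ijk)] = value
        if progress_every and (count + 1) % progress_every == 0:
            log.info("fitted %d / %d voxels", count + 1, len(idx))
    return maps
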