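"""Fibre-orientation dependence of susceptibility-related signals.

Myelinated axons behave as anisotropic cylindrical compartments: the
generalized Lorentzian (tensor) picture predicts that the local frequency
shift varies with sin^2 of the angle theta between the fibre axis and the
main field B0, while R2* picks up a sin^4 theta component.  This module
measures those dependences by regressing voxel values against sin^n theta,
with theta derived from the principal diffusion direction of each voxel.
Fibre orientation is axial (n and -n are the same fibre), so angles are
folded into [0, 90] degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = ["angle_to_b0", "fit_sine_power", "SinePowerFit", "orientation_report"]

#: Default main-field axis: the image third axis (+z).
B0_AXIS_DEFAULT = np.array([0.0, 0.0, 1.0])


def angle_to_b0(direction: np.ndarray, b0_axis: np.ndarray = B0_AXIS_DEFAULT) -> float:
    """Angle (degrees, folded to [0, 90]) between a fibre axis and B0.

    arccos of |direction . b0|: antipodal directions map to the same angle.
    """
    d = np.asarray(direction, float)
    b = np.asarray(b0_axis, float)
    nd, nb = np.linalg.norm(d), np.linalg.norm(b)
    if nd == 0 or nb == 0:
        raise ValueError("zero vector has no orientation")
    cosang = abs(float(d @ b)) / (nd * nb)
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


@dataclass(frozen=True)
class SinePowerFit:
    """Least-squares fit of v = baseline + amplitude * sin^n(theta)."""

    baseline: float
    amplitude: float
    exponent: float
    r_squared: float
    amplitude_stderr: float
    t_amplitude: float
    p_amplitude: float
    n_samples: int


def _check_samples(theta_deg: np.ndarray, values: np.ndarray) -> None:
    if theta_deg.shape != values.shape or theta_deg.ndim != 1:
        raise ValueError("theta and values must be 1-D arrays of equal length")
    if theta_deg.shape[0] < 5:
        raise ValueError("at least 5 samples are required")
    if np.ptp(theta_deg) < 45.0:
        raise ValueError(
            f"theta span {np.ptp(theta_deg):.1f} deg is degenerate (< 45 deg needed)"
        )


def fit_sine_power(
    theta_deg: np.ndarray,
    values: np.ndarray,
    exponent: float | str = "free",
) -> SinePowerFit:
    """Fit the orientation-dependence model to (theta, value) samples.

    With a fixed ``exponent`` n the model is linear in (baseline,
    amplitude) and solved exactly by simple linear regression on
    x = sin^n(theta); with ``exponent='free'`` n is optimised in [1, 8] by
    nonlinear least squares (multi-start at n = 2 and n = 4).  A constant
    input yields amplitude 0 with undefined (NaN) r^2 and p.
    """
    theta_deg = np.asarray(theta_deg, float)
    values = np.asarray(values, float)
    _check_samples(theta_deg, values)
    theta = np.deg2rad(theta_deg)

    if np.ptp(values) == 0.0:
        n = 2.0 if exponent == "free" else float(exponent)
        return SinePowerFit(
            float(values[0]), 0.0, n, np.nan, np.nan, np.nan, np.nan, len(values)
        )

    if exponent != "free":
        n = float(exponent)
        x = np.sin(theta) ** n
        lr = stats.linregress(x, values)
        t = lr.slope / lr.stderr if lr.stderr > 0 else np.nan
        return SinePowerFit(
            float(lr.intercept),
            float(lr.slope),
            n,
            float(lr.rvalue**2),
            float(lr.stderr),
            float(t),
            float(lr.pvalue),
            len(values),
        )

    def model(th, baseline, amplitude, n):
        return baseline + amplitude * np.sin(th) ** n

    best = None
    for n0 in (2.0, 4.0):
        try:
            popt, pcov = curve_fit(
                model,
                theta,
                values,
                p0=[values.min(), np.ptp(values), n0],
                bounds=([-np.inf, -np.inf, 1.0], [np.inf, np.inf, 8.0]),
                maxfev=10000,
            )
        except RuntimeError:
            continue
        sse = float(np.sum((model(theta, *popt) - values) ** 2))
        if best is None or sse < best[2]:
            best = (popt, pcov, sse)
    if best is None:
        raise RuntimeError("free-exponent fit failed to converge")
    popt, pcov, sse = best
    sst = float(np.sum((values - values.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    amp_se = float(np.sqrt(pcov[1, 1]))
    dof = len(values) - 3
    t = popt[1] / amp_se if amp_se > 0 else np.nan
    p = 2.0 * stats.t.sf(abs(t), dof) if np.isfinite(t) and dof > 0 else np.nan
    return SinePowerFit(
        float(popt[0]), float(popt[1]), float(popt[2]), r2, amp_se, float(t), p,
        len(values),
    )


def orientation_report(
    freq_map: np.ndarray | None,
    r2star_map: np.ndarray | None,
    dti_orientation_map: np.ndarray,
    mask: np.ndarray,
    b0_axis: np.ndarray = B0_AXIS_DEFAULT,
) -> pd.DataFrame:
    """Orientation-dependence regressions over the masked voxels.

    The frequency shift is tested against sin^2(theta) and R2* against
    sin^4(theta) (each also with a free exponent); the amplitude is tested
    against zero via its standard error (two-sided t).  Returns a table
    with one row per (map, fit-mode).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    dirs = np.asarray(dti_orientation_map, float)
    if dirs.shape[:-1] != mask.shape or dirs.shape[-1] != 3:
        raise ValueError("orientation map must be mask shape + (3,)")
    theta = np.array([angle_to_b0(d, b0_axis) for d in dirs[mask]])

    rows = []
    for name, vol, fixed_n in (
        ("frequency_shift", freq_map, 2.0),
        ("r2star", r2star_map, 4.0),
    ):
        if vol is None:
            continue
        vol = np.asarray(vol, float)
        if vol.shape != mask.shape:
            raise ValueError(f"{name} map shape {vol.shape} != mask {mask.shape}")
        vals = vol[mask]
        keep = np.isfinite(vals)
        for mode, exp in ((f"fixed_n{int(fixed_n)}", fixed_n), ("free_n", "free")):
            fit = fit_sine_power(theta[keep], vals[keep], exp)
            rows.append(
                {
                    "map": name,
                    "mode": mode,
                    "baseline": fit.baseline,
                    "amplitude": fit.amplitude,
                    "exponent": fit.exponent,
                    "r_squared": fit.r_squared,
                    "t_amplitude": fit.t_amplitude,
                    "p_amplitude": fit.p_amplitude,
                    "n_voxels": fit.n_samples,
                }
            )
    return pd.DataFrame(rows)
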