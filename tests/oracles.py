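"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles, sharing no
code path with the package: Bloch-style isochromat simulation of CPMG
trains (the stimulated-echo physics without any phase-graph bookkeeping),
dense two-dimensional spherical quadrature and rejection-sampled
Monte-Carlo averages for Watson-distribution integrals, and explicit
normal-equations regression.
"""

import numpy as np


def isochromat_cpmg(flip_deg, t2, t1, echo_spacing, n_echoes, n_iso=512):
    """CPMG echo magnitudes by brute-force isochromat simulation.

    ``n_iso`` isochromats with evenly spaced crusher-induced precession
    angles; 90deg(x) excitation, refocusing pulses of ``flip_deg`` about y.
    Exact (to float precision) once n_iso exceeds the number of populated
    dephasing orders.
    """
    alpha = np.deg2rad(flip_deg)
    ca, sa = np.cos(alpha), np.sin(alpha)
    # rotation about y by alpha
    Ry = np.array([[ca, 0.0, sa], [0.0, 1.0, 0.0], [-sa, 0.0, ca]])
    phis = 2.0 * np.pi * np.arange(n_iso) / n_iso  # per half interval
    cp, sp = np.cos(phis), np.sin(phis)
    e2 = np.exp(-echo_spacing / 2.0 / t2)
    e1 = np.exp(-echo_spacing / 2.0 / t1)

    # M[i] = (Mx, My, Mz); after ideal 90(x) pulse on equilibrium +z: M = (0,-1,0)
    M = np.tile(np.array([0.0, -1.0, 0.0]), (n_iso, 1))

    def half_interval(M):
        M = M.copy()
        M[:, 0] *= e2
        M[:, 1] *= e2
        M[:, 2] *= e1  # no regrowth: decay of excited magnetization only
        x = M[:, 0] * cp - M[:, 1] * sp
        y = M[:, 0] * sp + M[:, 1] * cp
        M[:, 0], M[:, 1] = x, y
        return M

    echoes = np.empty(n_echoes)
    for k in range(n_echoes):
        M = half_interval(M)
        M = M @ Ry.T
        M = half_interval(M)
        echoes[k] = abs(complex(M[:, 0].mean(), M[:, 1].mean()))
    return echoes


def dense_watson_stick(bd, cos_beta, kappa, n_polar=400, n_azimuth=400):
    """E_Watson[exp(-bd (g.n)^2)] by dense 2-D product quadrature."""
    u, w = np.polynomial.legendre.leggauss(n_polar)
    phi = np.linspace(0.0, 2.0 * np.pi, n_azimuth, endpoint=False)
    s = np.sqrt(1.0 - u**2)
    # mean orientation along z; g in the x-z plane at angle beta
    nz = u[:, None] * np.ones_like(phi)[None, :]
    nx = s[:, None] * np.cos(phi)[None, :]
    sb = np.sqrt(max(0.0, 1.0 - cos_beta**2))
    gdotn = cos_beta * nz + sb * nx
    weight = np.exp(kappa * nz**2)
    integrand = np.exp(-bd * gdotn**2) * weight
    num = np.einsum("i,ij->", w, integrand)
    den = np.einsum("i,ij->", w, weight)
    return num / den


def sample_watson(kappa, n, rng):
    """Rejection-sampled unit vectors from Watson(kappa) about +z."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        t = rng.uniform(-1.0, 1.0, size=2 * (n - filled))
        accept = rng.uniform(size=t.shape[0]) < np.exp(kappa * (t**2 - 1.0))
        good = t[accept][: n - filled]
        out[filled : filled + good.shape[0]] = good
        filled += good.shape[0]
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - out**2)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), out])


def mc_watson_stick(bd, g, kappa, n, rng):
    """Monte-Carlo E_Watson[exp(-bd (g.n)^2)] with mu = +z."""
    dirs = sample_watson(kappa, n, rng)
    return float(np.mean(np.exp(-bd * (dirs @ g) ** 2)))


def normal_equations_line(x, y):
    """(intercept, slope) by explicit normal equations."""
    A = np.column_stack([np.ones_like(x), x])
    coeffs = np.linalg.solve(A.T @ A, A.T @ y)
    return float(coeffs[0]), float(coeffs[1])


def paired_t_explicit(a, b):
    """Paired t statistic from explicit mean/SD computation."""
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.shape[0]
    mean = d.sum() / n
    var = ((d - mean) ** 2).sum() / (n - 1)
    return mean / np.sqrt(var / n)


def spherical_average(fn, n_polar=200, n_azimuth=200):
    """Average of fn(direction) over the unit sphere by product quadrature."""
    u, w = np.polynomial.legendre.leggauss(n_polar)
    phi = np.linspace(0.0, 2.0 * np.pi, n_azimuth, endpoint=False)
    s = np.sqrt(1.0 - u**2)
    dirs = np.stack(
        [
            s[:, None] * np.cos(phi)[None, :],
            s[:, None] * np.sin(phi)[None, :],
            u[:, None] * np.ones_like(phi)[None, :],
        ],
        axis=-1,
    ).reshape(-1, 3)
    weights = np.repeat(w, n_azimuth) / (2.0 * n_azimuth)
    return float(np.sum(weights * fn(dirs)))
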