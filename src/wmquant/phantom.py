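"""Synthetic multi-modal white-matter phantom with known ground truth.

Three region archetypes are modelled, mirroring the classic comparison of
myelo-architecturally distinct white matter: frontal WM (thin myelin,
crossing fibres), the cortico-spinal tract at the centrum semiovale
(CST-CS: thick myelin, crossing fibres) and at the posterior limb of the
internal capsule (CST-PLIC: thick myelin, parallel fibres).  Each region
carries a full set of ground-truth microstructure parameters (tensor
eigenvalues, kurtosis, neurite density/dispersion/free water, T2
components, MTR, R2*) whose defaults are normative adult means, and the
phantom emits every acquisition the pipeline fits: two-shell DWI, a
32-echo CPMG train with a B1 map, an MT/non-MT pair and a multi-echo
gradient-echo series.  Geometry is a deliberately unrealistic flat slab
(one slice, one rectangular block per region) -- the phantom exists for
parameter-recovery verification, not anatomical realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epg import cpmg_echo_train
from .gradients import GradientTable, default_gradient_table
from .watson import kappa_from_odi, watson_stick_attenuation, watson_tau

__all__ = [
    "MicrostructureGroundTruth",
    "PhantomSpec",
    "Phantom",
    "REGION_DEFAULTS",
    "simulate_tensor_signal",
    "simulate_dki_signal",
    "simulate_noddi_signal",
    "simulate_cpmg_decay",
    "simulate_mt_pair",
    "simulate_gre_magnitudes",
    "simulate_orientation_series",
    "add_rician_noise",
    "build_phantom",
]

#: NODDI fixed diffusivities (um^2/ms): canonical values of the
#: three-compartment model (intra/extra-neurite parallel, isotropic ball).
D_PAR_DEFAULT = 1.7
D_ISO_DEFAULT = 3.0

#: Gradient-echo echo times of the acquisition protocol (ms).
GRE_ECHO_TIMES = (4.5, 10.0, 15.0, 21.0, 27.0, 33.0, 39.0, 46.0)


@dataclass(frozen=True)
class MicrostructureGroundTruth:
    """Per-region true parameters driving every forward model."""

    eigenvalues: tuple[float, float, float]  # um^2/ms, descending
    principal_orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    kurtosis_iso: float = 1.0  # direction-independent apparent kurtosis
    icvf: float = 0.6
    odi: float = 0.2
    iso_fraction: float = 0.05
    t2_components: tuple[tuple[float, float], ...] = ((20.0, 0.1), (80.0, 0.9))
    t1: float = 1000.0  # ms
    flip_angle: float = 160.0  # deg, true refocusing flip of the CPMG train
    mtr_true: float = 40.0  # percent
    r2star_true: float = 18.0  # 1/s
    s0: float = 100.0

    def __post_init__(self) -> None:
        lam = self.eigenvalues
        if not (lam[0] >= lam[1] >= lam[2] > 0):
            raise ValueError(f"eigenvalues must satisfy l1>=l2>=l3>0, got {lam}")
        n = np.linalg.norm(self.principal_orientation)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("principal_orientation must be a unit vector")
        for name in ("icvf", "odi", "iso_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        fr = sum(f for _, f in self.t2_components)
        if abs(fr - 1.0) > 1e-8:
            raise ValueError(f"T2 component fractions must sum to 1, got {fr}")
        if not 0.0 <= self.mtr_true < 100.0:
            raise ValueError("mtr_true must lie in [0, 100)")
        if self.r2star_true <= 0:
            raise ValueError("r2star_true must be positive")
        if not 0.0 < self.flip_angle <= 180.0:
            raise ValueError("flip_angle must lie in (0, 180] deg")

    @property
    def md(self) -> float:
        return float(np.mean(self.eigenvalues))

    @property
    def mwf(self) -> float:
        """Ground-truth myelin water fraction: short-T2 (< 30 ms) weight."""
        return float(sum(f for t2, f in self.t2_components if t2 < 30.0))

    def diffusion_tensor(self) -> np.ndarray:
        """3x3 tensor with the given eigenvalues, axially symmetric about
        the principal orientation (l2 = l3 = radial)."""
        e1 = np.asarray(self.principal_orientation, float)
        l1, l2, l3 = self.eigenvalues
        # orthonormal completion of e1
        helper = np.array([1.0, 0.0, 0.0])
        if abs(e1 @ helper) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        e2 = np.cross(e1, helper)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        return l1 * np.outer(e1, e1) + l2 * np.outer(e2, e2) + l3 * np.outer(e3, e3)


def _table1_region(lam1, lam_perp, mk, icvf, odi, iso, mwf, mtr, r2s, orient):
    return MicrostructureGroundTruth(
        eigenvalues=(lam1, lam_perp, lam_perp),
        principal_orientation=orient,
        kurtosis_iso=mk,
        icvf=icvf,
        odi=odi,
        iso_fraction=iso,
        t2_components=((20.0, mwf), (80.0, 1.0 - mwf)),
        mtr_true=mtr,
        r2star_true=r2s,
    )


#: Default ground truth per region: normative adult white-matter means
#: (diffusivities um^2/ms, MTR percent, R2* 1/s).  The PLIC myelin water
#: fraction was not covered by the single-slice CPMG acquisition the
#: defaults derive from; 0.150 is a synthetic, plausible continuation of
#: the myelination gradient.
REGION_DEFAULTS: dict[str, MicrostructureGroundTruth] = {
    "frontal_wm": _table1_region(
        1.207, 0.611, 0.972, 0.551, 0.230, 0.045, 0.053, 38.91, 17.97, (1.0, 0.0, 0.0)
    ),
    "cst_cs": _table1_region(
        1.179, 0.523, 1.144, 0.656, 0.215, 0.067, 0.125, 38.08, 18.54, (0.0, 1.0, 0.0)
    ),
    "cst_plic": _table1_region(
        1.611, 0.318, 1.392, 0.745, 0.104, 0.106, 0.150, 40.94, 18.17, (0.0, 0.0, 1.0)
    ),
}

#: Region -> integer label in the phantom mask.
REGION_LABELS = {"frontal_wm": 1, "cst_cs": 2, "cst_plic": 3}


@dataclass(frozen=True)
class PhantomSpec:
    """Layout and noise settings of one phantom realisation ("subject")."""

    regions: dict[str, MicrostructureGroundTruth] = field(
        default_factory=lambda: dict(REGION_DEFAULTS)
    )
    voxels_per_region: int = 10
    noise_sigma: float = 0.0  # signal units; 0 = noise-free
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxels_per_region < 1:
            raise ValueError("voxels_per_region must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not self.regions:
            raise ValueError("at least one region is required")


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def simulate_tensor_signal(
    gt: MicrostructureGroundTruth, gtab: GradientTable
) -> np.ndarray:
    """Single-tensor DWI signal S = S0 exp(-b g^T D g)."""
    D = gt.diffusion_tensor()
    quad = np.einsum("ij,nj,ni->n", D, gtab.bvecs, gtab.bvecs)
    return gt.s0 * np.exp(-gtab.bvals_ms * quad)


def simulate_dki_signal(
    gt: MicrostructureGroundTruth, gtab: GradientTable
) -> np.ndarray:
    """Kurtosis DWI signal ln S = ln S0 - b D(n) + (1/6) b^2 D(n)^2 K.

    The apparent kurtosis K is direction-independent (``gt.kurtosis_iso``),
    which the full kurtosis-tensor model represents exactly via
    W proportional to the symmetrised outer product of D with itself.  At
    K = 0 this reduces to :func:`simulate_tensor_signal`.
    """
    if gt.kurtosis_iso < 0:
        raise ValueError("kurtosis must be non-negative")
    D = gt.diffusion_tensor()
    d_app = np.einsum("ij,nj,ni->n", D, gtab.bvecs, gtab.bvecs)
    b = gtab.bvals_ms
    exponent = -b * d_app + (b**2) * (d_app**2) * gt.kurtosis_iso / 6.0
    # monotonicity guard over the acquired b-range (model validity)
    b_max = b.max()
    if b_max > 0 and np.any(b_max * gt.kurtosis_iso * np.max(d_app, initial=0.0) > 3.0):
        import warnings

        warnings.warn(
            "kurtosis term makes the signal non-monotone within the acquired "
            "b-range; the quadratic cumulant expansion is invalid there",
            stacklevel=2,
        )
    return gt.s0 * np.exp(exponent)


def simulate_noddi_signal(
    gt: MicrostructureGroundTruth,
    gtab: GradientTable,
    d_par: float = D_PAR_DEFAULT,
    d_iso: float = D_ISO_DEFAULT,
) -> np.ndarray:
    """Three-compartment neurite signal: Watson stick + tortuous zeppelin + ball.

    S = S0 [ (1-ISO) (ICVF A_ic + (1-ICVF) A_ec) + ISO exp(-b d_iso) ] with
    A_ic the Watson-dispersed stick and A_ec a zeppelin whose intrinsic
    perpendicular diffusivity follows the tortuosity rule
    d_perp = d_par (1 - ICVF), dispersed by the same Watson distribution.
    ODI = 0 selects the parallel-stick closed form (kappa -> inf).
    """
    mu = np.asarray(gt.principal_orientation, float)
    b = gtab.bvals_ms
    cos_beta = gtab.bvecs @ mu
    kappa = kappa_from_odi(gt.odi)
    a_ic = watson_stick_attenuation(b * d_par, cos_beta, kappa)
    # mean (Watson-averaged) extra-neurite tensor
    tau = watson_tau(kappa)
    d_perp0 = d_par * (1.0 - gt.icvf)
    d_par_ec = d_perp0 + (d_par - d_perp0) * tau
    d_perp_ec = d_perp0 + (d_par - d_perp0) * (1.0 - tau) / 2.0
    a_ec = np.exp(-b * (d_perp_ec + (d_par_ec - d_perp_ec) * cos_beta**2))
    a_iso = np.exp(-b * d_iso)
    f_iso, f_ic = gt.iso_fraction, gt.icvf
    return gt.s0 * (
        (1.0 - f_iso) * (f_ic * a_ic + (1.0 - f_ic) * a_ec) + f_iso * a_iso
    )


def simulate_cpmg_decay(
    gt: MicrostructureGroundTruth,
    n_echoes: int = 32,
    echo_spacing: float = 10.0,
) -> np.ndarray:
    """Multi-component CPMG echo train with stimulated-echo (EPG) modulation.

    Echo k = S0 sum_j f_j EPG(flip, T2_j, T1, k, esp).  At a 180 deg flip
    this is the plain multi-exponential sum; at lower flips early echoes
    need not decrease monotonically.
    """
    if n_echoes < 2:
        raise ValueError("at least 2 echoes are required")
    t2s = np.array([t2 for t2, _ in gt.t2_components])
    fracs = np.array([f for _, f in gt.t2_components])
    basis = cpmg_echo_train(gt.flip_angle, t2s, gt.t1, echo_spacing, n_echoes)
    return gt.s0 * basis @ fracs


def simulate_mt_pair(gt: MicrostructureGroundTruth) -> tuple[float, float]:
    """(non-MT, MT) image pair consistent with the true MTR percentage."""
    return gt.s0, gt.s0 * (1.0 - gt.mtr_true / 100.0)


def simulate_gre_magnitudes(
    gt: MicrostructureGroundTruth, echo_times: np.ndarray | tuple = GRE_ECHO_TIMES
) -> np.ndarray:
    """Mono-exponential gradient-echo magnitudes M(TE) = S0 exp(-R2* TE).

    ``echo_times`` in ms, R2* in 1/s (TE converted internally).
    """
    te = np.asarray(echo_times, float)
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly increasing")
    return gt.s0 * np.exp(-gt.r2star_true * te / 1000.0)


def simulate_orientation_series(
    baseline: float,
    amplitude: float,
    exponent: float,
    theta_grid_deg: np.ndarray,
) -> np.ndarray:
    """Orientation-dependence series v(theta) = baseline + amplitude sin^n(theta)."""
    if exponent <= 0:
        raise ValueError("exponent must be positive")
    theta = np.asarray(theta_grid_deg, float)
    if np.any((theta < 0) | (theta > 90)):
        raise ValueError("theta grid must lie in [0, 90] degrees")
    return baseline + amplitude * np.sin(np.deg2rad(theta)) ** exponent


def add_rician_noise(
    signal: np.ndarray, sigma: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Rician magnitude noise: sqrt((s + n1)^2 + n2^2), n1, n2 ~ N(0, sigma).

    ``sigma = 0`` returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    signal = np.asarray(signal, float)
    if sigma == 0:
        return signal.copy()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


# ---------------------------------------------------------------------------
# assembled phantom
# ---------------------------------------------------------------------------

@dataclass
class Phantom:
    """In-memory multi-modal phantom dataset (one slab slice).

    Volumes are (nx, ny, 1[, n]) arrays; ``labels`` holds the integer
    region mask and ``truth`` a long-format table of generating values.
    """

    spec: PhantomSpec
    gtab: GradientTable
    dwi_tensor: np.ndarray
    dwi_kurtosis: np.ndarray
    dwi_noddi: np.ndarray
    cpmg: np.ndarray
    cpmg_echo_times: np.ndarray
    b1: np.ndarray
    non_mt: np.ndarray
    mt: np.ndarray
    gre: np.ndarray
    gre_echo_times: np.ndarray
    labels: np.ndarray
    truth: pd.DataFrame
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    @property
    def region_labels(self) -> dict[str, int]:
        return {name: i + 1 for i, name in enumerate(self.spec.regions)}


def build_phantom(
    spec: PhantomSpec,
    gtab: GradientTable | None = None,
    n_echoes: int = 32,
    echo_spacing: float = 10.0,
    gre_echo_times: tuple = GRE_ECHO_TIMES,
    d_par: float = D_PAR_DEFAULT,
    d_iso: float = D_ISO_DEFAULT,
) -> Phantom:
    """Assemble the full multi-modal phantom for every region archetype.

    The slab is (voxels_per_region, n_regions, 1); column j carries region
    j's signals, so noise-free voxels within a region are identical and a
    fixed seed reproduces the dataset bit for bit.  Each modality draws its
    Rician noise from an independent child stream of the master seed.
    """
    if gtab is None:
        gtab = default_gradient_table()
    nv, nr = spec.voxels_per_region, len(spec.regions)
    shape = (nv, nr, 1)
    labels = np.zeros(shape, dtype=np.int16)
    n_grad = len(gtab)
    dwi_t = np.zeros(shape + (n_grad,))
    dwi_k = np.zeros_like(dwi_t)
    dwi_n = np.zeros_like(dwi_t)
    cpmg = np.zeros(shape + (n_echoes,))
    b1 = np.ones(shape)
    non_mt = np.zeros(shape)
    mt = np.zeros(shape)
    gre = np.zeros(shape + (len(gre_echo_times),))

    rows = []
    for j, (name, gt) in enumerate(spec.regions.items()):
        labels[:, j, 0] = j + 1
        dwi_t[:, j, 0, :] = simulate_tensor_signal(gt, gtab)
        # kurtosis channel: isotropic tensor at the region MD, so the
        # ground truth respects the fitter's kurtosis cap 3/(b_max d) on
        # every direction even in the strongly anisotropic PLIC
        gt_k = replace(gt, eigenvalues=(gt.md, gt.md, gt.md))
        dwi_k[:, j, 0, :] = simulate_dki_signal(gt_k, gtab)
        dwi_n[:, j, 0, :] = simulate_noddi_signal(gt, gtab, d_par, d_iso)
        cpmg[:, j, 0, :] = simulate_cpmg_decay(gt, n_echoes, echo_spacing)
        non_mt[:, j, 0], mt[:, j, 0] = simulate_mt_pair(gt)
        gre[:, j, 0, :] = simulate_gre_magnitudes(gt, np.asarray(gre_echo_times))
        lam1, lam2, lam3 = gt.eigenvalues
        for param, value in [
            ("md", gt.md),
            ("lambda_par", lam1),
            ("lambda_perp", (lam2 + lam3) / 2.0),
            ("mk", gt.kurtosis_iso),
            ("icvf", gt.icvf),
            ("odi", gt.odi),
            ("iso", gt.iso_fraction),
            ("mwf", gt.mwf),
            ("mtr", gt.mtr_true),
            ("r2star", gt.r2star_true),
            ("flip_angle", gt.flip_angle),
            ("s0", gt.s0),
        ]:
            rows.append({"region": name, "parameter": param, "value": value})
    truth = pd.DataFrame(rows)

    if spec.noise_sigma > 0:
        streams = np.random.SeedSequence(spec.seed).spawn(5)
        for arr, ss in zip((dwi_t, dwi_k, dwi_n, cpmg, gre), streams):
            arr[...] = add_rician_noise(
                arr, spec.noise_sigma, np.random.default_rng(ss)
            )

    return Phantom(
        spec=spec,
        gtab=gtab,
        dwi_tensor=dwi_t,
        dwi_kurtosis=dwi_k,
        dwi_noddi=dwi_n,
        cpmg=cpmg,
        cpmg_echo_times=echo_spacing * np.arange(1, n_echoes + 1),
        b1=b1,
        non_mt=non_mt,
        mt=mt,
        gre=gre,
        gre_echo_times=np.asarray(gre_echo_times, float),
        labels=labels,
        truth=truth,
    )
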