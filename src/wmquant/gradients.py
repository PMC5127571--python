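"""Diffusion gradient tables.

A two-shell high-angular-resolution scheme is used throughout: 30
directions at b = 700 s/mm**2 (the "classic DTI" shell), 64 directions at
b = 2000 s/mm**2, plus at least one b = 0 image.  Directions are stored in
the image coordinate frame, FSL dialect (``bvals``/``bvecs`` text files,
3 rows x N columns for the vectors).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GradientTable",
    "fibonacci_hemisphere",
    "default_gradient_table",
    "read_bvals_bvecs",
    "write_bvals_bvecs",
]

#: b-values below this (s/mm^2) are treated as b = 0.
B0_THRESHOLD = 10.0


class InvalidGradientError(ValueError):
    """A direction with b > 0 is not a unit vector, or the table is malformed."""


@dataclass(frozen=True)
class GradientTable:
    """b-values (s/mm**2) paired with unit diffusion-encoding directions.

    Invariants enforced on construction: b-values are non-negative, at
    least one b = 0 entry is present, and every direction with b > 0 has
    unit Euclidean norm to within 1e-6.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise InvalidGradientError(f"bvecs must be (N, 3), got {bvecs.shape}")
        if bvals.shape[0] != bvecs.shape[0]:
            raise InvalidGradientError(
                f"{bvals.shape[0]} b-values but {bvecs.shape[0]} directions"
            )
        if np.any(bvals < 0):
            raise InvalidGradientError("negative b-values")
        dwi = bvals > B0_THRESHOLD
        if not np.any(~dwi):
            raise InvalidGradientError("gradient table contains no b=0 entry")
        norms = np.linalg.norm(bvecs[dwi], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise InvalidGradientError(
                "non-unit direction for b > 0 (max |norm-1| = "
                f"{np.max(np.abs(norms - 1.0)):.2e})"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.bvals > B0_THRESHOLD

    @property
    def bvals_ms(self) -> np.ndarray:
        """b-values in ms/um**2 so that b*D is dimensionless for D in um**2/ms."""
        return self.bvals / 1000.0

    @property
    def b_max(self) -> float:
        return float(self.bvals.max())

    def subset(self, mask: np.ndarray) -> "GradientTable":
        return GradientTable(self.bvals[mask], self.bvecs[mask])

    def low_shell(self, b_cut: float = 1000.0) -> "GradientTable":
        """b=0 plus all shells with b <= ``b_cut`` (the DTI sub-table)."""
        return self.subset(self.bvals <= b_cut)

    def shells(self, tol: float = 50.0) -> list[float]:
        """Distinct non-zero shell b-values (grouped to within ``tol``)."""
        out: list[float] = []
        for b in sorted(self.bvals[self.dwi_mask]):
            if not out or abs(b - out[-1]) > tol:
                out.append(float(b))
        return out


def fibonacci_hemisphere(n: int) -> np.ndarray:
    """``n`` roughly uniform unit vectors on the upper hemisphere.

    Spherical Fibonacci points folded to z >= 0; deterministic and well
    conditioned for tensor design matrices.
    """
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - i / n  # upper hemisphere band
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` roughly uniform unit vectors on the full sphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def default_gradient_table(
    n_low: int = 30,
    b_low: float = 700.0,
    n_high: int = 64,
    b_high: float = 2000.0,
    n_b0: int = 1,
) -> GradientTable:
    """The acquisition's two-shell scheme: b=0, 30 @ 700, 64 @ 2000 s/mm**2."""
    bvals = np.concatenate(
        [np.zeros(n_b0), np.full(n_low, b_low), np.full(n_high, b_high)]
    )
    bvecs = np.vstack(
        [np.zeros((n_b0, 3)), fibonacci_hemisphere(n_low), fibonacci_hemisphere(n_high)]
    )
    return GradientTable(bvals, bvecs)


def read_bvals_bvecs(
    bval_path: str | Path, bvec_path: str | Path, norm_tol: float = 1e-3
) -> GradientTable:
    """Read FSL-dialect ``bvals``/``bvecs`` text files.

    Directions whose norm is off unit by less than ``norm_tol`` are
    renormalised; larger deviations raise :class:`InvalidGradientError`.
    """
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3) and bvals.shape[0] == 3:
        pass  # ambiguous 3x3; rows-as-measurements assumed
    if bvecs.shape[0] != bvals.shape[0] and bvecs.shape[1] == bvals.shape[0]:
        bvecs = bvecs.T
    dwi = bvals > B0_THRESHOLD
    norms = np.linalg.norm(bvecs[dwi], axis=1)
    if np.any(np.abs(norms - 1.0) > norm_tol * (1.0 + 1e-9) + 1e-12):
        raise InvalidGradientError(
            f"bvec norms deviate from 1 by more than {norm_tol}"
        )
    fixed = bvecs.copy()
    fixed[dwi] = bvecs[dwi] / norms[:, None]
    return GradientTable(bvals, fixed)


def write_bvals_bvecs(
    gtab: GradientTable, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """Write FSL-dialect files: one row of b-values; 3 rows (x, y, z) of vectors."""
    np.savetxt(bval_path, gtab.bvals[None, :], fmt="%.1f")
    np.savetxt(bvec_path, gtab.bvecs.T, fmt="%.8f")
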