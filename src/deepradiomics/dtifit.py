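"""Per-voxel diffusion tensor estimation and FA/MD parametric maps.

The diffusion-weighted signal is modelled as the mono-exponential tensor
decay S(b, g) = S0 * exp(-b * g' D g) with D a symmetric 3x3 tensor in
mm^2/s.  The tensor is estimated voxel-wise by log-linear least squares on
the design

    ln S = ln S0 - b * [gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz] . d

using the unweighted (b ~ 0) volumes plus the single highest-b shell.
Eigenvalues are sorted descending; negative eigenvalues (noise) are clamped
to zero before computing fractional anisotropy (FA) and mean diffusivity
(MD).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .volio import ROIMask

B0_THRESHOLD = 50.0  # s/mm^2 below which an acquisition counts as unweighted
SIGNAL_FLOOR_FRACTION = 1e-6  # signals <= 0 floored to this fraction of S0


class DesignError(ValueError):
    """Raised when the gradient scheme cannot support a tensor fit."""


@dataclasses.dataclass
class DWISeries:
    """A diffusion-weighted acquisition: 4D signals plus b-values/b-vectors."""

    signals: np.ndarray  # (X, Y, Z, N)
    bvals: np.ndarray  # (N,) in s/mm^2
    bvecs: np.ndarray  # (N, 3) unit directions for b > 0

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape == (3, self.bvals.size):
            self.bvecs = self.bvecs.T  # accept FSL row-per-axis layout
        if self.signals.ndim != 4:
            raise ValueError(f"signals must be 4D, got shape {self.signals.shape}")
        n = self.signals.shape[-1]
        if self.bvals.size != n or self.bvecs.shape != (n, 3):
            raise ValueError("bvals/bvecs length must match the acquisition axis")
        if n < 7:
            raise DesignError("need at least 7 acquisitions (1 b0 + 6 directions)")
        if not np.any(self.bvals < B0_THRESHOLD):
            raise DesignError("need at least one b~0 acquisition")
        weighted = self.bvals >= B0_THRESHOLD
        norms = np.linalg.norm(self.bvecs[weighted], axis=1)
        if weighted.any() and not np.allclose(norms, 1.0, atol=1e-3):
            raise DesignError("b-vectors for weighted volumes must be unit length")


@dataclasses.dataclass
class DTIMaps:
    """Per-voxel tensor eigenvalues (descending, mm^2/s) with FA/MD/S0 maps."""

    eigenvalues: np.ndarray  # (X, Y, Z, 3), l1 >= l2 >= l3
    fa: np.ndarray
    md: np.ndarray
    s0: np.ndarray


def read_bvals_bvecs(bval_path, bvec_path) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-style whitespace-separated .bval/.bvec files.

    The .bvec file carries one row per spatial axis (3 x N); it is returned
    transposed to (N, 3).
    """
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return bvals, bvecs


def _design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows [1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz]
    so that X @ [ln S0, dxx, dyy, dzz, dxy, dxz, dyz] = ln S."""
    g = bvecs
    b = bvals
    cols = np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ]
    )
    return cols


def _tensors_from_coeffs(d: np.ndarray) -> np.ndarray:
    """(..., 6) [dxx,dyy,dzz,dxy,dxz,dyz] -> (..., 3, 3) symmetric tensors."""
    t = np.empty(d.shape[:-1] + (3, 3))
    t[..., 0, 0] = d[..., 0]
    t[..., 1, 1] = d[..., 1]
    t[..., 2, 2] = d[..., 2]
    t[..., 0, 1] = t[..., 1, 0] = d[..., 3]
    t[..., 0, 2] = t[..., 2, 0] = d[..., 4]
    t[..., 1, 2] = t[..., 2, 1] = d[..., 5]
    return t


def fa_from_eigenvalues(l1: float, l2: float, l3: float) -> float:
    """Fractional anisotropy from tensor eigenvalues, clipped to [0, 1].

    FA = sqrt(3/2) * sqrt(sum (li - lbar)^2) / sqrt(sum li^2); an all-zero
    tensor is degenerate and maps to 0.
    """
    lam = np.array([l1, l2, l3], dtype=float)
    denom = np.sqrt((lam**2).sum())
    if denom == 0:
        return 0.0
    num = np.sqrt(((lam - lam.mean()) ** 2).sum())
    return float(np.clip(np.sqrt(1.5) * num / denom, 0.0, 1.0))


def md_from_eigenvalues(l1: float, l2: float, l3: float) -> float:
    """Mean diffusivity: the arithmetic mean of the eigenvalues (mm^2/s)."""
    return (float(l1) + float(l2) + float(l3)) / 3.0


def _fa_md_from_eigs(eigs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised FA/MD over an (..., 3) eigenvalue array (clamped >= 0)."""
    md = eigs.mean(axis=-1)
    denom = np.sqrt((eigs**2).sum(axis=-1))
    num = np.sqrt(((eigs - md[..., None]) ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / denom
    fa = np.where(denom > 0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0), md


def fit_tensor(
    dwi: DWISeries,
    brain: ROIMask | None = None,
    *,
    shell: str = "highest",
    directional_average: bool = False,
) -> DTIMaps:
    """Log-linear least-squares tensor fit per voxel.

    By default the fit uses the b~0 volumes plus the single highest-b shell
    (``shell="highest"``); ``shell="all"`` uses every acquisition.  With
    ``directional_average=True`` the weighted signals of the chosen shell are
    first geometrically averaged over directions and only an apparent
    isotropic diffusivity is estimated (FA is 0 by construction) — a
    documented alternative reading, not the default.

    Voxels outside ``brain`` are emitted as 0 in every map.
    """
    b0 = dwi.bvals < B0_THRESHOLD
    if shell == "highest":
        bmax = dwi.bvals.max()
        use = b0 | np.isclose(dwi.bvals, bmax, rtol=1e-3)
    elif shell == "all":
        use = np.ones_like(b0, dtype=bool)
    else:
        raise ValueError(f"unknown shell selection {shell!r}")

    bvals = dwi.bvals[use]
    bvecs = dwi.bvecs[use]
    sig = dwi.signals[..., use]
    shape = sig.shape[:3]

    if brain is not None:
        if brain.shape != shape:
            raise ValueError("brain mask grid differs from DWI grid")
        inside = brain.data
    else:
        inside = np.ones(shape, dtype=bool)

    vox = sig[inside]  # (M, N)
    s0_est = np.maximum(vox[:, bvals < B0_THRESHOLD].mean(axis=1), 0.0)

    if directional_average:
        w = bvals >= B0_THRESHOLD
        floor = np.maximum(s0_est, 1e-300)[:, None] * SIGNAL_FLOOR_FRACTION
        logs = np.log(np.maximum(vox[:, w], floor))
        adc = (np.log(np.maximum(s0_est, 1e-300))[:, None] - logs) / bvals[w]
        d_iso = adc.mean(axis=1)
        eigs = np.repeat(np.clip(d_iso, 0, None)[:, None], 3, axis=1)
    else:
        X = _design_matrix(bvals, bvecs)
        if np.linalg.matrix_rank(X) < 7:
            raise DesignError("gradient directions are rank-deficient for a tensor fit")
        floor = np.maximum(s0_est, 1e-300)[:, None] * SIGNAL_FLOOR_FRACTION
        y = np.log(np.maximum(vox, np.maximum(floor, 1e-300)))
        beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # (7, M)
        s0_est = np.exp(beta[0])
        tensors = _tensors_from_coeffs(beta[1:].T)
        eigs = np.linalg.eigvalsh(tensors)[..., ::-1]  # descending
        eigs = np.clip(eigs, 0.0, None)

    fa_v, md_v = _fa_md_from_eigs(eigs)

    eigenvalues = np.zeros(shape + (3,))
    fa = np.zeros(shape)
    md = np.zeros(shape)
    s0 = np.zeros(shape)
    eigenvalues[inside] = eigs
    fa[inside] = fa_v
    md[inside] = md_v
    s0[inside] = s0_est
    return DTIMaps(eigenvalues=eigenvalues, fa=fa, md=md, s0=s0)
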