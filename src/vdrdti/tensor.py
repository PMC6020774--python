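"""Diffusion tensor fitting and FA extraction in atlas masks.

Tensors are fit per voxel by ordinary least squares on the log-signal
(``ln S = ln S0 - b g^T D g``), the classic DTIFIT-style estimator, with an
optional one-step weighted refinement.  FA is computed from the sorted
eigenvalues; atlas probability maps are thresholded (inclusive, default
10%) and can be combined by exclusive set difference before averaging FA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .phantom import DWIVolume, GradientTable, ROIMask

__all__ = [
    "TensorResult",
    "MaskedFAStat",
    "fit_tensor",
    "fa_from_eigenvalues",
    "fa_map",
    "threshold_mask",
    "exclusive_mask",
    "mean_fa",
    "UnidentifiableFitError",
]

SIGNAL_FLOOR_FRAC = 1e-6  # floor = frac * S0 before taking logs


class UnidentifiableFitError(ValueError):
    """Design matrix cannot identify the six tensor elements plus ln S0."""


@dataclass(frozen=True)
class TensorResult:
    tensor: np.ndarray  # 3x3 symmetric, mm^2/s (raw fit, may be indefinite)
    eigenvalues: np.ndarray  # sorted descending
    principal_direction: np.ndarray  # unit eigenvector of lambda_1
    S0_fit: float
    fa: float


@dataclass(frozen=True)
class MaskedFAStat:
    roi_name: str
    threshold: float
    n_voxels: int
    mean_fa: float


def _design_matrix(gtab: GradientTable) -> np.ndarray:
    """Columns: [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    b = gtab.b_values
    g = gtab.b_vectors
    return np.column_stack(
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


def _check_identifiable(gtab: GradientTable, X: np.ndarray) -> None:
    if gtab.n_volumes < 7 or gtab.n_b0 < 1 or gtab.dwi_mask.sum() < 6:
        raise UnidentifiableFitError("need >= 1 b0 and >= 6 weighted volumes")
    if np.linalg.matrix_rank(X) < 7:
        raise UnidentifiableFitError("gradient directions are collinear: rank-deficient design")


def _coeffs_to_tensor(coef: np.ndarray) -> np.ndarray:
    xx, yy, zz, xy, xz, yz = coef
    return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])


def fa_from_eigenvalues(l1: float, l2: float, l3: float) -> float:
    """Fractional anisotropy from tensor eigenvalues.

    FA = sqrt(3/2) * ||lambda - mean||/||lambda||; negative eigenvalues are
    clamped to zero first so the result stays in [0, 1].
    """
    lam = np.maximum(np.array([l1, l2, l3], float), 0.0)
    norm2 = (lam**2).sum()
    if norm2 == 0:
        raise ValueError("FA undefined for all-zero eigenvalues")
    dev = lam - lam.mean()
    return float(min(np.sqrt(1.5 * (dev**2).sum() / norm2), 1.0))


def fit_tensor(
    signal: Sequence[float],
    gtab: GradientTable,
    weighted: bool = False,
) -> TensorResult:
    """Fit one voxel's tensor by log-linear least squares.

    Signals at or below ``1e-6 * S0`` are floored before the log (Rician
    magnitudes can reach zero).  Negative eigenvalues are clamped only for
    the FA value; the raw tensor is preserved.
    """
    s = np.asarray(signal, float)
    X = _design_matrix(gtab)
    _check_identifiable(gtab, X)
    s0_obs = s[gtab.b_values == 0].mean()
    floor = SIGNAL_FLOOR_FRAC * max(s0_obs, 1.0)
    y = np.log(np.maximum(s, floor))
    # column scaling keeps the b-value magnitude out of the conditioning
    col = np.linalg.norm(X, axis=0)
    Xn = X / col
    beta, *_ = np.linalg.lstsq(Xn, y, rcond=None)
    beta /= col
    if weighted:
        w = np.exp(X @ beta)  # predicted signals as weights
        Xw = Xn * w[:, None]
        beta, *_ = np.linalg.lstsq(Xw, y * w, rcond=None)
        beta /= col
    D = _coeffs_to_tensor(beta[1:])
    vals, vecs = np.linalg.eigh(D)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]
    return TensorResult(
        tensor=D,
        eigenvalues=vals,
        principal_direction=vecs[:, 0],
        S0_fit=float(np.exp(beta[0])),
        fa=fa_from_eigenvalues(*vals),
    )


def fa_map(
    dwi: DWIVolume,
    weighted: bool = False,
    return_directions: bool = False,
):
    """Voxelwise tensor fit and FA over a whole volume.

    Background voxels (mean b0 below the signal floor) get FA 0.  With
    ``return_directions`` the principal eigenvector field and eigenvalue
    array are returned as well (used by the tractography orientation model).
    """
    gtab = dwi.gradient_table
    X = _design_matrix(gtab)
    _check_identifiable(gtab, X)
    shape = dwi.signal.shape[:3]
    s = dwi.signal.reshape(-1, gtab.n_volumes)
    s0_obs = s[:, gtab.b_values == 0].mean(axis=1)
    floor = SIGNAL_FLOOR_FRAC * dwi.S0
    y = np.log(np.maximum(s, floor))
    col = np.linalg.norm(X, axis=0)
    pinv = np.linalg.pinv(X / col)
    beta = (y @ pinv.T) / col  # (N, 7)
    if weighted:
        w = np.exp(beta @ X.T)
        # per-voxel weighted refit: solve (X^T W^2 X) beta = X^T W^2 y
        for i in range(s.shape[0]):
            Xw = (X / col) * w[i][:, None]
            sol, *_ = np.linalg.lstsq(Xw, y[i] * w[i], rcond=None)
            beta[i] = sol / col
    tensors = np.zeros((s.shape[0], 3, 3))
    c = beta[:, 1:]
    tensors[:, 0, 0] = c[:, 0]
    tensors[:, 1, 1] = c[:, 1]
    tensors[:, 2, 2] = c[:, 2]
    tensors[:, 0, 1] = tensors[:, 1, 0] = c[:, 3]
    tensors[:, 0, 2] = tensors[:, 2, 0] = c[:, 4]
    tensors[:, 1, 2] = tensors[:, 2, 1] = c[:, 5]
    vals, vecs = np.linalg.eigh(tensors)
    vals = vals[:, ::-1]  # descending
    vecs = vecs[:, :, ::-1]
    lam = np.maximum(vals, 0.0)
    norm2 = (lam**2).sum(axis=1)
    dev2 = ((lam - lam.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev2 / norm2)
    fa = np.minimum(np.nan_to_num(fa), 1.0)
    background = s0_obs <= floor
    fa[background] = 0.0
    fa_vol = fa.reshape(shape)
    if not return_directions:
        return fa_vol
    pdirs = vecs[:, :, 0].reshape(shape + (3,))
    return fa_vol, pdirs, vals.reshape(shape + (3,))


def threshold_mask(mask: ROIMask, threshold: float = 0.10) -> np.ndarray:
    """Binary mask of voxels with probability >= threshold (inclusive)."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    return mask.prob_map >= threshold


def exclusive_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Set difference a \\ b of two binary masks on the same grid."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    if a.shape != b.shape:
        raise ValueError("masks must share one grid")
    return a & ~b


def mean_fa(fa_volume: np.ndarray, mask: np.ndarray, roi_name: str = "",
            threshold: float = np.nan) -> MaskedFAStat:
    """Mean FA over a binary mask; an empty mask is an error (it signals
    over-thresholding upstream)."""
    mask = np.asarray(mask, bool)
    if fa_volume.shape != mask.shape:
        raise ValueError("FA volume and mask must share one grid")
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"empty mask {roi_name!r}: nothing to average")
    return MaskedFAStat(roi_name=roi_name, threshold=threshold, n_voxels=n,
                        mean_fa=float(fa_volume[mask].mean()))


def fa_stats_to_tsv(path, stats: Sequence[MaskedFAStat]) -> None:
    pd.DataFrame([s.__dict__ for s in stats]).to_csv(path, sep="\t", index=False)
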