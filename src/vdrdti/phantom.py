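"""Synthetic diffusion-weighted phantoms with known fiber geometry.

A phantom is a small voxel grid (default 24^3 at 2 mm isotropic) holding:

* an "IFOF-like" corridor: a long straight bundle,
* a "UF-like" bundle whose anterior section runs inside that corridor and
  then hooks away from it, so the two atlas masks overlap the way the real
  tracts do in probabilistic atlas space,
* a control bundle, geometrically isolated and trait-independent,
* a crossing bundle intersecting the corridor (two-fiber voxels),
* a short seed->target bundle joining two compact ROIs, with per-subject
  orientation dispersion,
* isotropic background everywhere else.

Signals follow the multi-tensor forward model
``S = S0 * sum_k f_k exp(-b g^T D_k g)`` with optional Rician noise
(magnitude of a complex Gaussian perturbation).  Ground-truth FA maps and
Gaussian-smoothed probabilistic atlas masks are returned alongside the DWI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

__all__ = [
    "GradientTable",
    "DWIVolume",
    "ROIMask",
    "FiberField",
    "PhantomLayout",
    "SubjectPhantomParams",
    "make_gradient_table",
    "tensor_from_fiber",
    "axially_symmetric_eigenvalues",
    "fa_of_axially_symmetric",
    "simulate_signal",
    "build_phantom",
    "save_dwi",
    "load_dwi",
    "save_map",
    "load_map",
]

# reference diffusivities (mm^2/s)
DEFAULT_MD = 0.8e-3  # mean diffusivity inside bundles
BACKGROUND_D = 0.8e-3  # isotropic background


@dataclass(frozen=True)
class GradientTable:
    """Acquisition scheme: b-values (s/mm^2) and unit gradient directions."""

    b_values: np.ndarray  # (n_volumes,)
    b_vectors: np.ndarray  # (n_volumes, 3); zero rows allowed for b=0

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, float)
        g = np.asarray(self.b_vectors, float)
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "b_vectors", g)
        if g.shape != (b.size, 3):
            raise ValueError("b_vectors must be (n_volumes, 3)")
        dw = b > 0
        norms = np.linalg.norm(g[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("diffusion-weighted b-vectors must have unit norm")

    @property
    def n_volumes(self) -> int:
        return self.b_values.size

    @property
    def n_b0(self) -> int:
        return int((self.b_values == 0).sum())

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.b_values > 0


@dataclass
class DWIVolume:
    """4-D diffusion-weighted signal grid plus its acquisition scheme."""

    signal: np.ndarray  # (nx, ny, nz, n_volumes)
    gradient_table: GradientTable
    voxel_size: float = 2.0
    S0: float = 1000.0

    def __post_init__(self) -> None:
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D (x, y, z, volume)")
        if self.signal.shape[-1] != self.gradient_table.n_volumes:
            raise ValueError("signal volumes do not match gradient table")
        if (self.signal < 0).any():
            raise ValueError("signals must be non-negative")

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_size] * 3 + [1.0])
        return a


@dataclass
class ROIMask:
    """Probability map (0-1 per voxel) for a tract atlas or seed/target ROI."""

    prob_map: np.ndarray
    name: str
    kind: str = "tract-atlas"  # tract-atlas | seed | target | control

    def __post_init__(self) -> None:
        if self.prob_map.min() < 0 or self.prob_map.max() > 1 + 1e-12:
            raise ValueError("probability map values must lie in [0, 1]")


@dataclass
class FiberField:
    """Ground-truth fiber configuration per voxel (up to two components).

    Fractions sum to <= 1; the remainder diffuses isotropically at
    ``background_d``.  Single-fiber bundle voxels use fraction 1 so their
    noise-free signal is mono-exponential.
    """

    directions: np.ndarray  # (nx, ny, nz, 2, 3) unit vectors (zeros if unused)
    fractions: np.ndarray  # (nx, ny, nz, 2)
    axial_d: np.ndarray  # (nx, ny, nz, 2) lambda_parallel
    radial_d: np.ndarray  # (nx, ny, nz, 2) lambda_perp
    background_d: float = BACKGROUND_D

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.directions.shape[:3]


# ---------------------------------------------------------------------------
# gradient scheme


def make_gradient_table(
    n_dirs: int = 64,
    b: float = 1000.0,
    n_b0: int = 1,
    rng: Optional[np.random.Generator] = None,
    n_iter: int = 150,
) -> GradientTable:
    """Gradient table with ~uniform directions on the sphere.

    Directions start from a random draw and are refined by electrostatic
    repulsion acting on antipodal point pairs, the standard way DW schemes
    are spread.  Deterministic under a seeded ``rng``.
    """
    if n_dirs < 6:
        raise ValueError("need >= 6 directions for an identifiable tensor")
    rng = rng or np.random.default_rng(0)
    x = rng.normal(size=(n_dirs, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    for it in range(n_iter):
        diff = x[:, None, :] - x[None, :, :]
        ssum = x[:, None, :] + x[None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        sdist = np.linalg.norm(ssum, axis=-1)
        np.fill_diagonal(dist, np.inf)
        np.fill_diagonal(sdist, np.inf)
        force = (diff / dist[..., None] ** 3).sum(axis=1) + (ssum / sdist[..., None] ** 3).sum(axis=1)
        # project onto the tangent plane; bound the step so close pairs
        # separate without overshooting
        force -= (force * x).sum(axis=1, keepdims=True) * x
        fnorm = np.linalg.norm(force, axis=1, keepdims=True)
        lr = 0.1 * (1.0 - it / n_iter) + 0.005
        x += lr * force / (1.0 + fnorm)
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), x])
    return GradientTable(bvals, bvecs)


# ---------------------------------------------------------------------------
# tensors and signals


def tensor_from_fiber(direction: Sequence[float], axial_d: float, radial_d: float) -> np.ndarray:
    """Axially symmetric diffusion tensor with the given principal axis."""
    d = np.asarray(direction, float)
    if not np.isclose(np.linalg.norm(d), 1.0, atol=1e-8):
        raise ValueError("fiber direction must be a unit vector")
    if not (axial_d >= radial_d > 0):
        raise ValueError("need lambda_parallel >= lambda_perp > 0")
    return radial_d * np.eye(3) + (axial_d - radial_d) * np.outer(d, d)


def axially_symmetric_eigenvalues(fa: float, md: float = DEFAULT_MD) -> tuple[float, float]:
    """(lambda_parallel, lambda_perp) of a prolate tensor with given FA, MD.

    For eigenvalues (a, b, b), FA = (a - b)/sqrt(a^2 + 2 b^2); inverting at
    fixed mean diffusivity gives a = md (1 + 2 delta), b = md (1 - delta)
    with delta = FA / sqrt(3 - 2 FA^2).
    """
    if not 0 <= fa < 1:
        raise ValueError("FA must lie in [0, 1)")
    delta = fa / np.sqrt(3.0 - 2.0 * fa * fa)
    return md * (1 + 2 * delta), md * (1 - delta)


def fa_of_axially_symmetric(axial_d: float, radial_d: float) -> float:
    """Closed-form FA of eigenvalues (a, b, b)."""
    a, b = axial_d, radial_d
    return float((a - b) / np.sqrt(a * a + 2 * b * b))


def simulate_signal(
    tensor_mixture: Sequence[tuple[np.ndarray, float]],
    S0: float,
    gtab: GradientTable,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    iso_diffusivity: float = BACKGROUND_D,
) -> np.ndarray:
    """Signal of one voxel under the multi-tensor forward model.

    ``tensor_mixture`` is a list of (3x3 tensor, fraction); any remaining
    fraction diffuses isotropically at ``iso_diffusivity``.  Rician noise of
    scale ``noise_sd`` is added when requested; signals never go negative.
    """
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fracs = np.array([f for _, f in tensor_mixture], float)
    if (fracs < 0).any() or fracs.sum() > 1 + 1e-12:
        raise ValueError("fractions must be >= 0 and sum to <= 1")
    b = gtab.b_values
    g = gtab.b_vectors
    s = np.zeros(gtab.n_volumes)
    for D, f in tensor_mixture:
        s += f * np.exp(-b * np.einsum("ij,jk,ik->i", g, np.asarray(D, float), g))
    f_iso = 1.0 - fracs.sum()
    if f_iso > 1e-12:
        s += f_iso * np.exp(-b * iso_diffusivity)
    s *= S0
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        s = np.hypot(s + rng.normal(0, noise_sd, s.shape), rng.normal(0, noise_sd, s.shape))
    return s


def _field_signal(
    fibers: FiberField,
    gtab: GradientTable,
    S0: float,
    noise_sd: float,
    rng: Optional[np.random.Generator],
) -> np.ndarray:
    """Vectorized multi-tensor signal over a whole fiber field."""
    b = gtab.b_values  # (V,)
    g = gtab.b_vectors  # (V, 3)
    shape = fibers.grid_shape
    att = np.zeros(shape + (gtab.n_volumes,))
    for k in range(fibers.fractions.shape[3]):
        f = fibers.fractions[..., k]
        sel = f > 0
        if not sel.any():
            continue
        d = fibers.directions[sel][:, k, :]  # (m, 3)
        ad = fibers.axial_d[sel][:, k]
        rd = fibers.radial_d[sel][:, k]
        gd2 = (g @ d.T) ** 2  # (V, m)
        expo = -b[:, None] * (rd[None, :] + (ad - rd)[None, :] * gd2)
        att[sel] += (f[sel][None, :] * np.exp(expo)).T
    f_iso = 1.0 - fibers.fractions.sum(axis=3)
    iso_att = np.exp(-b * fibers.background_d)  # (V,)
    att += f_iso[..., None] * iso_att
    s = S0 * att
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        s = np.hypot(s + rng.normal(0, noise_sd, s.shape), rng.normal(0, noise_sd, s.shape))
    return s


# ---------------------------------------------------------------------------
# geometry


def _subdivide(points: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Resample a polyline at roughly uniform arc-length spacing."""
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / step)), 1)
        for i in range(1, n + 1):
            out.append(a + (b - a) * i / n)
    return np.asarray(out)


def _rasterize_path(
    points: np.ndarray, radius: float, grid_shape: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Voxels within ``radius`` of a polyline, with local tangent directions.

    Returns (mask, directions) where directions holds the unit tangent of
    the nearest polyline sample in each in-mask voxel.
    """
    pts = _subdivide(np.asarray(points, float))
    if pts.min() < -0.5 or (pts > np.asarray(grid_shape) - 0.5).any():
        raise ValueError("bundle path exits the voxel grid")
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    centers = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in grid_shape], indexing="ij"), axis=-1
    )  # (nx, ny, nz, 3), voxel units
    flat = centers.reshape(-1, 3)
    d2 = ((flat[:, None, :] - pts[None, :, :]) ** 2).sum(-1)  # (N, P)
    nearest = d2.argmin(axis=1)
    dist = np.sqrt(d2[np.arange(flat.shape[0]), nearest])
    mask = (dist <= radius).reshape(grid_shape)
    dirs = tangents[nearest].reshape(grid_shape + (3,))
    dirs[~mask] = 0.0
    return mask, dirs


def _sphere(center: Sequence[float], radius: float, grid_shape) -> np.ndarray:
    centers = np.stack(
        np.meshgrid(*[np.arange(s, dtype=float) for s in grid_shape], indexing="ij"), axis=-1
    )
    return ((centers - np.asarray(center, float)) ** 2).sum(-1) <= radius**2


@dataclass
class PhantomLayout:
    """Geometry of the default phantom, in 0-based voxel units."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 2.0
    S0: float = 1000.0
    noise_sd: float = 40.0  # Rician scale (SNR 25 at the default S0); 0 disables noise
    ifof_radius: float = 2.2
    uf_radius: float = 1.5
    control_radius: float = 1.5
    crossing_radius: float = 1.2
    st_radius: float = 2.0
    seed_center: tuple[float, float, float] = (5.5, 16.0, 6.0)
    seed_radius: float = 1.5
    target_center: tuple[float, float, float] = (14.5, 16.0, 6.0)
    atlas_sigma: float = 1.0  # smoothing of binary bundles -> probability maps
    ifof_fa: float = 0.55  # trait-independent corridor coherence
    st_fa: float = 0.65  # seed-target bundle coherence before dispersion

    def scaled(self) -> "PhantomLayout":
        return self

    def paths(self) -> dict[str, np.ndarray]:
        nx, ny, nz = self.grid_shape
        sx = nx / 24.0  # allow smaller grids (>=16) by scaling the layout
        sy = ny / 24.0
        sz = nz / 24.0
        sc = np.array([sx, sy, sz])
        p = {
            "ifof": np.array([[2.5, 8, 12], [21.5, 8, 12.0]]),
            "uf": np.array(
                [[2.5, 8, 12], [10, 8, 12], [12, 8, 11], [13.5, 8, 9], [14, 8, 6.0]]
            ),
            "control": np.array([[16, 2.5, 18], [16, 21.5, 18.0]]),
            "crossing": np.array([[18, 2.5, 12], [18, 13.5, 12.0]]),
            "st": np.array([[4.0, 16, 6], [16.0, 16, 6.0]]),
        }
        return {k: v * sc for k, v in p.items()}


@dataclass
class SubjectPhantomParams:
    """Per-subject knobs derived from latent traits."""

    uf_fa: float = 0.60
    control_fa: float = 0.55
    ifof_fa: Optional[float] = None  # None -> the layout's nominal corridor FA
    st_dispersion: float = 0.05  # angular sd (radians) of fiber jitter
    target_radius: float = 1.9


def build_phantom(
    layout: PhantomLayout,
    params: SubjectPhantomParams,
    gtab: GradientTable,
    rng: Optional[np.random.Generator] = None,
) -> tuple[DWIVolume, np.ndarray, dict[str, ROIMask], FiberField]:
    """Build one subject's phantom.

    Returns (dwi, ground-truth FA map, masks, fiber field).  Masks: ``uf``,
    ``ifof``, ``control`` probabilistic atlas maps (smoothed indicators),
    plus binary ``seed`` and ``target`` ROIs.
    """
    if min(layout.grid_shape) < 16:
        raise ValueError("default layout needs a grid of at least 16^3")
    rng = rng or np.random.default_rng(0)
    shape = layout.grid_shape
    paths = layout.paths()

    ifof_mask, ifof_dirs = _rasterize_path(paths["ifof"], layout.ifof_radius, shape)
    uf_mask, uf_dirs = _rasterize_path(paths["uf"], layout.uf_radius, shape)
    ctrl_mask, ctrl_dirs = _rasterize_path(paths["control"], layout.control_radius, shape)
    cross_mask, cross_dirs = _rasterize_path(paths["crossing"], layout.crossing_radius, shape)
    st_mask, st_dirs = _rasterize_path(paths["st"], layout.st_radius, shape)

    directions = np.zeros(shape + (2, 3))
    fractions = np.zeros(shape + (2,))
    axial = np.full(shape + (2,), DEFAULT_MD)
    radial = np.full(shape + (2,), DEFAULT_MD)

    def _set_single(mask, dirs, fa):
        ad, rd = axially_symmetric_eigenvalues(fa)
        directions[mask, 0, :] = dirs[mask]
        fractions[mask, 0] = 1.0
        fractions[mask, 1] = 0.0
        axial[mask, 0] = ad
        radial[mask, 0] = rd

    ifof_fa = layout.ifof_fa if params.ifof_fa is None else params.ifof_fa
    # assignment order: corridor first, then bundles that override it
    _set_single(ifof_mask, ifof_dirs, ifof_fa)
    _set_single(uf_mask, uf_dirs, params.uf_fa)
    _set_single(ctrl_mask, ctrl_dirs, params.control_fa)

    # seed-target bundle with per-voxel orientation jitter (dispersion)
    st_jdirs = st_dirs.copy()
    if params.st_dispersion > 0:
        jitter = rng.normal(0, params.st_dispersion, shape + (3,))
        sel = st_mask
        v = st_jdirs[sel] + jitter[sel]
        st_jdirs[sel] = v / np.linalg.norm(v, axis=1, keepdims=True)
    _set_single(st_mask, st_jdirs, layout.st_fa)

    # crossing region: corridor voxels shared with the crossing bundle carry
    # two equal-fraction fibers
    both = ifof_mask & cross_mask & ~uf_mask & ~ctrl_mask & ~st_mask
    adx, rdx = axially_symmetric_eigenvalues(ifof_fa)
    directions[both, 0, :] = ifof_dirs[both]
    directions[both, 1, :] = cross_dirs[both]
    fractions[both] = 0.5
    axial[both] = adx
    radial[both] = rdx
    # crossing-only voxels are a plain single-fiber bundle
    cross_only = cross_mask & ~ifof_mask & ~uf_mask & ~ctrl_mask & ~st_mask
    _set_single(cross_only, cross_dirs, ifof_fa)

    fibers = FiberField(directions, fractions, axial, radial)
    signal = _field_signal(fibers, gtab, layout.S0, layout.noise_sd, rng)
    dwi = DWIVolume(signal, gtab, voxel_size=layout.voxel_size, S0=layout.S0)

    # ground-truth FA: closed form in single-fiber voxels, FA of the
    # fraction-weighted mean tensor in mixed voxels, 0 in background
    fa_truth = np.zeros(shape)
    single = (fractions[..., 0] == 1.0) & (fractions[..., 1] == 0.0)
    a = axial[..., 0][single]
    r = radial[..., 0][single]
    fa_truth[single] = (a - r) / np.sqrt(a * a + 2 * r * r)
    if both.any():
        mean_t = np.zeros((both.sum(), 3, 3))
        for k in range(2):
            d = directions[both][:, k, :]
            ad = axial[both][:, k]
            rd = radial[both][:, k]
            mean_t += 0.5 * (
                rd[:, None, None] * np.eye(3)
                + (ad - rd)[:, None, None] * d[:, :, None] * d[:, None, :]
            )
        ev = np.linalg.eigvalsh(mean_t)
        num = np.sqrt(((ev - ev.mean(1, keepdims=True)) ** 2).sum(1))
        fa_truth[both] = np.sqrt(1.5) * num / np.sqrt((ev**2).sum(1))

    scale = np.array(shape) / 24.0
    target_mask = _sphere(np.asarray(layout.target_center) * scale,
                          params.target_radius, shape)
    seed_mask = _sphere(np.asarray(layout.seed_center) * scale, layout.seed_radius, shape)

    def _atlas(mask: np.ndarray) -> np.ndarray:
        m = gaussian_filter(mask.astype(float), layout.atlas_sigma)
        return np.clip(m / m.max(), 0, 1) if m.max() > 0 else m

    masks = {
        "uf": ROIMask(_atlas(uf_mask), "uf", "tract-atlas"),
        "ifof": ROIMask(_atlas(ifof_mask), "ifof", "tract-atlas"),
        "control": ROIMask(_atlas(ctrl_mask), "control", "control"),
        "seed": ROIMask(seed_mask.astype(float), "seed", "seed"),
        "target": ROIMask(target_mask.astype(float), "target", "target"),
    }
    return dwi, fa_truth, masks, fibers


# ---------------------------------------------------------------------------
# NIfTI / FSL-style text I/O


def save_dwi(prefix, dwi: DWIVolume) -> None:
    """Write <prefix>.nii plus FSL-style <prefix>.bval / <prefix>.bvec."""
    img = nib.Nifti1Image(dwi.signal.astype(np.float64), dwi.affine)
    nib.save(img, f"{prefix}.nii")
    np.savetxt(f"{prefix}.bval", dwi.gradient_table.b_values[None, :], fmt="%.6g")
    np.savetxt(f"{prefix}.bvec", dwi.gradient_table.b_vectors.T, fmt="%.10g")


def load_dwi(prefix, S0: Optional[float] = None) -> DWIVolume:
    img = nib.load(f"{prefix}.nii")
    bvals = np.loadtxt(f"{prefix}.bval").ravel()
    bvecs = np.loadtxt(f"{prefix}.bvec")
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    sig = np.asarray(img.dataobj, dtype=np.float64)
    vox = float(img.affine[0, 0])
    s0 = S0 if S0 is not None else float(sig[..., bvals == 0].mean())
    return DWIVolume(sig, GradientTable(bvals, bvecs), voxel_size=vox, S0=s0)


def save_map(path, data: np.ndarray, voxel_size: float = 2.0) -> None:
    nib.save(nib.Nifti1Image(data.astype(np.float64), np.diag([voxel_size] * 3 + [1.0])), path)


def load_map(path) -> np.ndarray:
    return np.asarray(nib.load(path).dataobj, dtype=np.float64)
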