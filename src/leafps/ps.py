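"""Photometric-stereo core: per-pixel normal/albedo estimation and
integration of the normal field to a relative depth map.

The solver assumes Lambertian reflectance: a pixel observed under light j
has intensity ``I_j = g_j * rho * max(0, n . l_j)`` where ``g_j`` is the
per-light gain, ``rho`` the albedo and ``n`` the unit surface normal.
Stacking the usable (lit) measurements gives a linear system whose
least-squares solution ``G = rho * n`` yields both quantities at once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.fft

from .exceptions import ConfigurationError
from .rig import CameraModel, LightModel


@dataclass
class PSImageSet:
    """A co-registered photometric-stereo capture.

    ``images`` is an (n_lights, rows, cols) stack with intensities on
    [0, 1]; frames are ordered like ``rig.directions``.
    """

    images: np.ndarray
    rig: LightModel
    camera: CameraModel
    foreground_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        imgs = np.asarray(self.images, dtype=float)
        if imgs.ndim != 3:
            raise ConfigurationError("images must be (n_lights, rows, cols)")
        if imgs.shape[0] != self.rig.n_lights:
            raise ConfigurationError(
                f"{imgs.shape[0]} frames for {self.rig.n_lights} lights"
            )
        self.images = imgs
        if self.foreground_mask is not None:
            fg = np.asarray(self.foreground_mask, dtype=bool)
            if fg.shape != imgs.shape[1:]:
                raise ConfigurationError("foreground_mask shape mismatch")
            self.foreground_mask = fg

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]


@dataclass
class NormalMap:
    """Per-pixel unit surface normals with albedo and a validity mask.

    Normals are stored as an (rows, cols, 3) array in the camera frame
    (x right, y down, z toward the camera); ``valid`` marks pixels where
    the solve was reliable.  Invalid pixels hold the benign placeholder
    (0, 0, 1) with zero albedo so that downstream sums never see NaN.
    """

    normals: np.ndarray
    albedo: np.ndarray
    valid: np.ndarray

    @property
    def nx(self) -> np.ndarray:
        return self.normals[..., 0]

    @property
    def ny(self) -> np.ndarray:
        return self.normals[..., 1]

    @property
    def nz(self) -> np.ndarray:
        return self.normals[..., 2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.normals.shape[:2]

    def inclination_deg(self) -> np.ndarray:
        """Per-pixel surface inclination arccos(nz), degrees."""
        return np.degrees(np.arccos(np.clip(self.nz, -1.0, 1.0)))


@dataclass
class DepthMap:
    """Relative height map in mm (arbitrary offset), NaN outside ``valid``."""

    z: np.ndarray
    valid: np.ndarray
    warnings: list[str] = field(default_factory=list)


def solve_normals(
    imgs: PSImageSet,
    shadow_threshold: float = 0.02,
    discard_extremes: bool = False,
    rho_floor: float = 1e-3,
) -> NormalMap:
    """Estimate per-pixel normals and albedo by least squares.

    Measurements below ``shadow_threshold`` (attached shadows, background)
    are excluded per pixel; pixels left with fewer than 3 usable lights, or
    with albedo below ``rho_floor``, are marked invalid.  With
    ``discard_extremes`` and more than 4 lights, the brightest and dimmest
    usable measurement of each pixel are additionally dropped, a cheap
    guard against residual highlights and soft shadows.
    """
    L = imgs.rig.matrix
    if np.linalg.matrix_rank(L, tol=1e-9) < 3:
        raise ConfigurationError("light matrix is rank-deficient")
    n_lights = L.shape[0]
    rows, cols = imgs.shape
    P = rows * cols
    raw = imgs.images.reshape(n_lights, P)
    I = raw / imgs.rig.intensities[:, None]

    usable = raw > shadow_threshold
    if imgs.foreground_mask is not None:
        usable &= imgs.foreground_mask.reshape(P)[None, :]

    if discard_extremes and n_lights > 4:
        masked = np.where(usable, I, np.inf)
        dim = np.argmin(masked, axis=0)
        masked = np.where(usable, I, -np.inf)
        bright = np.argmax(masked, axis=0)
        has_any = usable.any(axis=0)
        cols_idx = np.arange(P)
        drop = usable.copy()
        drop[dim[has_any], cols_idx[has_any]] = False
        drop[bright[has_any], cols_idx[has_any]] = False
        # only drop where >= 5 usable measurements remain available
        enough = usable.sum(axis=0) >= 5
        usable = np.where(enough[None, :], drop, usable)

    count = usable.sum(axis=0)
    solvable = count >= 3

    G = np.zeros((3, P))
    pinv_full = np.linalg.pinv(L)
    full = solvable & (count == n_lights)
    if full.any():
        G[:, full] = pinv_full @ I[:, full]

    partial = solvable & ~full
    if partial.any():
        idx = np.flatnonzero(partial)
        # group pixels sharing the same usable-light pattern
        codes = (usable[:, idx] * (1 << np.arange(n_lights))[:, None]).sum(axis=0)
        for code in np.unique(codes):
            sel = idx[codes == code]
            lights = [j for j in range(n_lights) if code & (1 << j)]
            Lsub = L[lights]
            if np.linalg.matrix_rank(Lsub, tol=1e-9) < 3:
                solvable[sel] = False
                continue
            G[:, sel] = np.linalg.pinv(Lsub) @ I[lights][:, sel]

    rho = np.linalg.norm(G, axis=0)
    ok = solvable & (rho > rho_floor)
    n = np.zeros((3, P))
    n[2] = 1.0
    n[:, ok] = G[:, ok] / rho[ok]

    # normals facing away from the camera: keep the flipped normal only if
    # it explains the measurements at least as well, else invalidate
    downward = ok & (n[2] <= 0)
    if downward.any():
        idx = np.flatnonzero(downward)
        resid_pos = np.zeros(idx.size)
        resid_neg = np.zeros(idx.size)
        for k, p in enumerate(idx):
            lights = np.flatnonzero(usable[:, p])
            Iv = I[lights, p]
            pred = L[lights] @ G[:, p]
            resid_pos[k] = np.sum((np.maximum(pred, 0.0) - Iv) ** 2)
            resid_neg[k] = np.sum((np.maximum(-pred, 0.0) - Iv) ** 2)
        flip = resid_neg <= resid_pos
        flip_idx = idx[flip]
        n[:, flip_idx] = -n[:, flip_idx]
        bad = idx[~flip | (n[2, idx] <= 0)]
        ok[bad] = False
        n[:, bad] = np.array([0.0, 0.0, 1.0])[:, None]

    rho = np.where(ok, rho, 0.0)
    normals = n.T.reshape(rows, cols, 3)
    return NormalMap(
        normals=normals,
        albedo=rho.reshape(rows, cols),
        valid=ok.reshape(rows, cols),
    )


def _gradients(nm: NormalMap, nz_min: float) -> tuple[np.ndarray, np.ndarray, list[str]]:
    warns: list[str] = []
    nz = nm.nz
    clamped = nm.valid & (nz < nz_min)
    if nm.valid.sum() and clamped.sum() > 0.5 * nm.valid.sum():
        msg = "nz below clamp floor on more than half of the valid region"
        warnings.warn(msg)
        warns.append(msg)
    nz_safe = np.maximum(nz, nz_min)
    p = np.where(nm.valid, -nm.nx / nz_safe, 0.0)
    q = np.where(nm.valid, -nm.ny / nz_safe, 0.0)
    return p, q, warns


def _staggered_rhs(p: np.ndarray, q: np.ndarray, spacing: float) -> np.ndarray:
    """Right-hand side of the discrete least-squares normal equations.

    The functional is sum over forward differences
    (z[i,j+1]-z[i,j] - P[i,j])^2 + (z[i+1,j]-z[i,j] - Q[i,j])^2 with the
    gradient samples averaged onto the staggered midpoints.  Its
    stationarity condition is (Neumann Laplacian) z = f with the f built
    here; natural boundary conditions arise automatically, so tilted
    planes are recovered exactly.
    """
    H, W = p.shape
    P = spacing * 0.5 * (p[:, :-1] + p[:, 1:])  # (H, W-1)
    Q = spacing * 0.5 * (q[:-1, :] + q[1:, :])  # (H-1, W)
    f = np.zeros((H, W))
    f[:, 1:] += P
    f[:, :-1] -= P
    f[1:, :] += Q
    f[:-1, :] -= Q
    return f


def _integrate_frequency(p: np.ndarray, q: np.ndarray, spacing: float) -> np.ndarray:
    """Cosine-transform solve of the normal equations.

    The DCT-II basis diagonalizes the Neumann Laplacian (equivalently: a
    frequency-domain least-squares solve on the mirror-padded domain).
    """
    H, W = p.shape
    f = _staggered_rhs(p, q, spacing)
    fc = scipy.fft.dctn(f, type=2, norm="ortho")
    mu = (2 - 2 * np.cos(np.pi * np.arange(W) / W))[None, :] + (
        2 - 2 * np.cos(np.pi * np.arange(H) / H)
    )[:, None]
    mu[0, 0] = 1.0
    zc = fc / mu
    zc[0, 0] = 0.0
    return scipy.fft.idctn(zc, type=2, norm="ortho")


def _integrate_poisson(p: np.ndarray, q: np.ndarray, spacing: float) -> np.ndarray:
    """Sparse direct solve of the same normal equations.

    Builds the Neumann Laplacian explicitly and solves it with a sparse
    LU factorization (gauge fixed at one pixel); an algebraically
    independent cross-check of the transform solver.
    """
    import scipy.sparse as sp
    import scipy.sparse.linalg as spla

    H, W = p.shape
    f = _staggered_rhs(p, q, spacing)

    def lap1d(n: int) -> sp.csr_matrix:
        d = np.full(n, 2.0)
        d[0] = d[-1] = 1.0
        return sp.diags([d, -np.ones(n - 1), -np.ones(n - 1)], [0, 1, -1])

    A = sp.kron(sp.identity(H), lap1d(W)) + sp.kron(lap1d(H), sp.identity(W))
    A = A.tolil()
    A[0, 0] += 1.0  # fixes the additive gauge (consistent RHS sums to 0)
    z = spla.spsolve(A.tocsr(), f.ravel())
    return z.reshape(H, W)


def integrate_normals(
    nm: NormalMap,
    camera: CameraModel | None = None,
    method: str = "frequency",
    nz_min: float = 0.05,
) -> DepthMap:
    """Integrate a normal map into a relative height map (mm).

    Gradients p = -nx/nz, q = -ny/nz (nz clamped at ``nz_min``) are
    integrated in least squares over the bounding box of the valid region;
    the result is zero-meaned over that region.  ``method`` is
    ``"frequency"`` (default; cosine-transform solve) or ``"poisson"``
    (sparse direct solve of the same functional, an independent
    cross-check).
    """
    if not nm.valid.any():
        raise ConfigurationError("no valid pixels to integrate")
    scale = camera.pixel_scale if camera is not None else 1.0
    rows = np.flatnonzero(nm.valid.any(axis=1))
    cols = np.flatnonzero(nm.valid.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    sub = NormalMap(
        nm.normals[r0:r1, c0:c1], nm.albedo[r0:r1, c0:c1], nm.valid[r0:r1, c0:c1]
    )
    p, q, warns = _gradients(sub, nz_min)
    if method == "frequency":
        z_box = _integrate_frequency(p, q, spacing=scale)
    elif method == "poisson":
        z_box = _integrate_poisson(p, q, spacing=scale)
    else:
        raise ConfigurationError(f"unknown integration method {method!r}")
    z = np.full(nm.shape, np.nan)
    z[r0:r1, c0:c1] = z_box
    z[~nm.valid] = np.nan
    z_valid = z[nm.valid]
    z[nm.valid] = z_valid - z_valid.mean()
    return DepthMap(z=z, valid=nm.valid.copy(), warnings=warns)
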