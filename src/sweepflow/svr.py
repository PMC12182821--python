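"""Slice-to-volume super-resolution along the sweep axis.

The CINE stack holds thick overlapping slices at known z positions (the
SWEEP schedule provides them exactly, so no registration stage is needed).
Per cardiac phase and velocity encoding the complex volume V on an isotropic
z grid is recovered from

    argmin_V  1/2 ||S V - y||^2 + mu * sum ρ_δ(∇V)

where S evaluates the volume convolved along z with the acquisition's
slice excitation profile at each window centre, ρ_δ is the Huber function
(edge-preserving: quadratic below δ, linear above), and ∇ are forward
spatial differences on all three axes.  Complex-valued fusion preserves the
velocity-encoding phase so decoding happens after, not before, the fusion —
this avoids phase-averaging artefacts at aliasing wraps.  The solver is a
monotone accelerated gradient descent with fixed step from a power-method
operator-norm estimate, warm-started from linear interpolation of the slice
stack along z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d

from .acquire import slice_sensitivity


class SliceCoverageError(ValueError):
    """Gaps between slice positions exceed the through-slice PSF."""


@dataclass(frozen=True)
class SVRConfig:
    """Super-resolution parameters: nominal weight 0.01 for 10 iterations,
    4 mm through-slice PSF fused to 1.2 mm isotropic."""

    n_iterations: int = 10
    reg_weight: float = 0.01
    target_voxel_mm: float = 1.2
    psf_fwhm_mm: float = 4.0
    huber_delta_frac: float = 0.01  # Huber threshold / max|data|

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.reg_weight < 0:
            raise ValueError("reg_weight must be >= 0")
        if self.target_voxel_mm > self.psf_fwhm_mm:
            raise ValueError("target_voxel_mm must not exceed psf_fwhm_mm")


def slice_profile_matrix(window_z_mm, z_grid_mm, psf_fwhm_mm: float) -> np.ndarray:
    """(n_windows, nz) matrix of unit-sum slice-profile weights.

    Uses the acquisition's smoothed-rectangle excitation profile so the SVR
    forward model is self-consistent with the simulated acquisition.
    """
    w = slice_sensitivity(
        np.asarray(z_grid_mm, dtype=float)[None, :],
        np.asarray(window_z_mm, dtype=float)[:, None],
        psf_fwhm_mm,
    )
    return w / w.sum(axis=1, keepdims=True)


def slice_forward(volume: np.ndarray, window_z_mm, z_grid_mm, psf_fwhm_mm: float) -> np.ndarray:
    """Forward slice-acquisition model: volume (nx, ny, nz) -> slices (n_w, nx, ny)."""
    S = slice_profile_matrix(window_z_mm, z_grid_mm, psf_fwhm_mm)
    return np.einsum("wz,xyz->wxy", S, volume)


def _grad3(v: np.ndarray) -> list[np.ndarray]:
    """Forward differences along the three spatial axes (zero at the far edge)."""
    out = []
    for ax in range(3):
        d = np.zeros_like(v)
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        d[tuple(sl_lo)] = v[tuple(sl_hi)] - v[tuple(sl_lo)]
        out.append(d)
    return out


def _huber_value_grad(grads, delta: float):
    """Sum of Huber penalties of the gradient fields and its gradient w.r.t. V."""
    value = 0.0
    back = np.zeros_like(grads[0])
    for ax, g in enumerate(grads):
        a = np.abs(g)
        quad = a <= delta
        value += float(0.5 * (a[quad] ** 2).sum() + (delta * a[~quad] - 0.5 * delta**2).sum())
        psi = g * np.minimum(1.0, delta / np.maximum(a, 1e-30))  # Huber derivative
        # adjoint of forward difference: psi(i-1) - psi(i) accumulated
        d = np.zeros_like(psi)
        sl_hi = [slice(None)] * 3
        sl_lo = [slice(None)] * 3
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(None, -1)
        d[tuple(sl_hi)] = psi[tuple(sl_lo)]
        back += d - psi
    return value, back


@dataclass
class FlowVolume4D:
    """Isotropic time-resolved flow volume: magnitude plus three velocity
    components on a shared (x, y, z, cardiac-phase) grid."""

    magnitude: np.ndarray  # (n_phases, nx, ny, nz)
    velocity: np.ndarray  # (3, n_phases, nx, ny, nz), cm/s
    z_grid_mm: np.ndarray
    in_plane_resolution_mm: float
    target_voxel_mm: float
    venc_cm_s: float


@dataclass
class SVRResult:
    """Fused complex volumes: (n_enc, n_phases, nx, ny, nz) on the z grid."""

    volumes: np.ndarray
    z_grid_mm: np.ndarray
    in_plane_resolution_mm: float
    target_voxel_mm: float
    venc_cm_s: float
    objective: np.ndarray  # (n_enc, n_phases, n_iterations)

    def to_flow_volume(self) -> FlowVolume4D:
        """Decode the four fused encodings into a :class:`FlowVolume4D`."""
        from .flow import decode_velocity

        if self.volumes.shape[0] != 4:
            raise ValueError("velocity decoding needs all four encodings")
        return FlowVolume4D(
            magnitude=np.abs(self.volumes[0]),
            velocity=decode_velocity(self.volumes, self.venc_cm_s),
            z_grid_mm=self.z_grid_mm,
            in_plane_resolution_mm=self.in_plane_resolution_mm,
            target_voxel_mm=self.target_voxel_mm,
            venc_cm_s=self.venc_cm_s,
        )


def _interp_init(slices: np.ndarray, window_z_mm, z_grid_mm) -> np.ndarray:
    f = interp1d(
        window_z_mm,
        slices,
        axis=0,
        kind="linear",
        bounds_error=False,
        fill_value=(slices[0], slices[-1]),
    )
    return np.moveaxis(f(z_grid_mm), 0, -1)  # (nx, ny, nz)


def reconstruct_svr_field(
    slices: np.ndarray,
    window_z_mm,
    z_grid_mm,
    svr: SVRConfig,
    n_iterations: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse one stack of complex slices (n_w, nx, ny) into a volume (nx, ny, nz).

    Returns the volume and the objective trace.  ``n_iterations`` overrides
    the config count when given (used by convergence studies).
    """
    window_z_mm = np.asarray(window_z_mm, dtype=float)
    z_grid_mm = np.asarray(z_grid_mm, dtype=float)
    order = np.argsort(window_z_mm)
    gaps = np.diff(window_z_mm[order])
    if gaps.size and gaps.max() > svr.psf_fwhm_mm:
        raise SliceCoverageError(
            f"z-coverage gap of {gaps.max():.2f} mm exceeds the {svr.psf_fwhm_mm:.2f} mm PSF"
        )
    n_it = svr.n_iterations if n_iterations is None else int(n_iterations)
    S = slice_profile_matrix(window_z_mm, z_grid_mm, svr.psf_fwhm_mm)

    scale = float(np.abs(slices).max())
    if scale == 0:
        return np.zeros((*slices.shape[1:], z_grid_mm.size), dtype=complex), np.zeros(n_it)
    y = slices / scale
    delta = svr.huber_delta_frac
    mu = svr.reg_weight

    # Lipschitz bound: ||S^T S|| + mu * ||grad||^2 (<= 12) since Huber'' <= 1
    L = float(np.linalg.norm(S.T @ S, 2)) + mu * 12.0
    tau = 1.0 / L

    def objective_grad(v, need_grad=True):
        r = np.einsum("wz,xyz->wxy", S, v) - y
        f = 0.5 * float(np.real(np.vdot(r, r)))
        hv, hg = (0.0, 0.0)
        if mu > 0:
            hv, hg = _huber_value_grad(_grad3(v), delta)
        F = f + mu * hv
        if not need_grad:
            return F, None
        g = np.einsum("wz,wxy->xyz", S, r)
        if mu > 0:
            g = g + mu * hg
        return F, g

    x = _interp_init(y, window_z_mm, z_grid_mm).astype(complex)
    F_prev, _ = objective_grad(x, need_grad=False)
    yk = x.copy()
    t = 1.0
    obj = np.empty(n_it)
    for it in range(n_it):
        _, g = objective_grad(yk)
        z = yk - tau * g
        Fz, _ = objective_grad(z, need_grad=False)
        if Fz <= F_prev:
            x_new, F_new = z, Fz
        else:
            Fx, gx = objective_grad(x)
            x_new = x - tau * gx
            F_new, _ = objective_grad(x_new, need_grad=False)
            if F_new > F_prev:
                x_new, F_new = x, F_prev
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        yk = x_new + (t / t_new) * (z - x_new) + ((t - 1.0) / t_new) * (x_new - x)
        x, F_prev, t = x_new, F_new, t_new
        obj[it] = F_prev
    return x * scale, obj


def default_z_grid(window_z_mm, target_voxel_mm: float) -> np.ndarray:
    """Isotropic z grid spanning the window centres."""
    window_z_mm = np.asarray(window_z_mm, dtype=float)
    lo, hi = window_z_mm.min(), window_z_mm.max()
    n = int(np.floor((hi - lo) / target_voxel_mm)) + 1
    return lo + np.arange(n) * target_voxel_mm


def reconstruct_svr(cines, svr: SVRConfig, z_grid_mm=None) -> SVRResult:
    """Fuse a :class:`~sweepflow.cine.CineStack` into per-encoding dynamic volumes."""
    if cines.window_z_mm.size < 2:
        raise ValueError("need at least two overlapping windows for SVR")
    if z_grid_mm is None:
        z_grid_mm = default_z_grid(cines.window_z_mm, svr.target_voxel_mm)
    n_w, n_enc, n_ph, nx, ny = cines.images.shape
    volumes = np.zeros((n_enc, n_ph, nx, ny, len(z_grid_mm)), dtype=complex)
    objective = np.zeros((n_enc, n_ph, svr.n_iterations))
    for e in range(n_enc):
        for p in range(n_ph):
            vol, obj = reconstruct_svr_field(
                cines.images[:, e, p], cines.window_z_mm, z_grid_mm, svr
            )
            volumes[e, p] = vol
            objective[e, p] = obj
    return SVRResult(
        volumes=volumes,
        z_grid_mm=np.asarray(z_grid_mm, dtype=float),
        in_plane_resolution_mm=cines.in_plane_resolution_mm,
        target_voxel_mm=svr.target_voxel_mm,
        venc_cm_s=cines.venc_cm_s,
        objective=objective,
    )
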