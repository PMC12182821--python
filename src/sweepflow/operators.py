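"""Non-uniform Fourier sampling operators for spiral k-space.

The forward model maps an image on a regular grid to complex samples at
arbitrary 2D k-space locations,

    (A x)_s = N^{-1/2} * sum_{r} x(r) * exp(-2*pi*i * k_s . r),

with r the physical voxel-centre coordinates and N the number of grid
points (the 1/sqrt(N) factor makes A the exact continuation of the
orthonormal DFT, so Cartesian sampling reduces to numpy's ``norm="ortho"``
FFT).  Because the grid is regular the exponential separates,
exp(-2*pi*i*k.r) = Ex[s, ix] * Ey[s, iy], and both the forward and the
exact adjoint reduce to two small dense matrix products — fast enough at
desk scale and exact to machine precision, which the operator unit oracles
rely on.
"""

from __future__ import annotations

import numpy as np


def grid_coords(n: int, voxel_mm: float) -> np.ndarray:
    """Physical coordinates of voxel centres, centred on the grid (FFT convention)."""
    return (np.arange(n) - n // 2) * voxel_mm


class NonUniformFT2D:
    """Exact separable non-uniform DFT from an (nx, ny) grid to point samples.

    Parameters
    ----------
    kx, ky : (n_samples,) k-space sample coordinates in cycles/mm.
    grid_shape : (nx, ny) image grid.
    voxel_mm : isotropic in-plane voxel size.
    """

    def __init__(self, kx, ky, grid_shape, voxel_mm: float):
        nx, ny = grid_shape
        kx = np.asarray(kx, dtype=float)
        ky = np.asarray(ky, dtype=float)
        x = grid_coords(nx, voxel_mm)
        y = grid_coords(ny, voxel_mm)
        self.grid_shape = (nx, ny)
        self.n_samples = kx.size
        self._Ex = np.exp(-2j * np.pi * np.outer(kx, x))
        self._Ey = np.exp(-2j * np.pi * np.outer(ky, y))
        self._scale = 1.0 / np.sqrt(nx * ny)

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Sample the image at the k-space points. image: (nx, ny) complex."""
        return ((self._Ex @ image) * self._Ey).sum(axis=1) * self._scale

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        """Exact conjugate-transpose of :meth:`forward`."""
        return (self._Ex.conj().T @ (samples[:, None] * self._Ey.conj())) * self._scale

    def normal_operator_norm(self, weights=None, n_iter: int = 20, seed: int = 0) -> float:
        """Power-method estimate of ||A^H W A|| (W diagonal sample weights)."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(self.grid_shape) + 1j * rng.standard_normal(self.grid_shape)
        x /= np.linalg.norm(x)
        lam = 1.0
        for _ in range(n_iter):
            y = self.forward(x)
            if weights is not None:
                y = y * weights
            x = self.adjoint(y)
            lam = np.linalg.norm(x)
            if lam == 0:
                return 0.0
            x /= lam
        return float(lam)


def ndft2_bruteforce(image: np.ndarray, kx, ky, voxel_mm: float) -> np.ndarray:
    """Brute-force reference non-uniform DFT (explicit double loop over the grid).

    Independent oracle for :class:`NonUniformFT2D`; O(n_samples * nx * ny)
    with no separability shortcut.  Only for tiny grids in tests.
    """
    nx, ny = image.shape
    x = grid_coords(nx, voxel_mm)
    y = grid_coords(ny, voxel_mm)
    out = np.zeros(np.asarray(kx).size, dtype=complex)
    for s, (kxs, kys) in enumerate(zip(np.ravel(kx), np.ravel(ky))):
        acc = 0.0 + 0.0j
        for ix in range(nx):
            for iy in range(ny):
                acc += image[ix, iy] * np.exp(-2j * np.pi * (kxs * x[ix] + kys * y[iy]))
        out[s] = acc
    return out / np.sqrt(nx * ny)
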