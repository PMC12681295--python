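"""Non-uniform FFT for 3D radial sampling.

Type-2 (image -> non-Cartesian samples) and its exact adjoint, implemented
as deapodization + zero-padded FFT + sparse Kaiser-Bessel interpolation.
The interpolation matrix is built once per trajectory and stored as CSR, so
arbitrary sample subsets (e.g. the spokes of one temporal frame) are cheap
row slices of the same plan.

Conventions: the image is N^3 with voxel indices r in [-N/2, N/2); sample
coordinates k are in cycles/FOV with |k| <= N/2; the forward model is

    y_j = sum_r x(r) exp(-2 pi i k_j . r / N).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.special import i0

__all__ = ["RadialNufft3D", "dft3_forward", "radial_trajectory"]


def radial_trajectory(directions: np.ndarray, n_readout: int, kmax: float,
                      ) -> np.ndarray:
    """Sample coordinates of diametric radial spokes.

    Readout samples at radii ``(j - n_readout/2) * 2 kmax / n_readout``
    (the k-space center is sampled on every spoke, which anchors the DC
    level of smooth objects).  Returns (n_spokes, n_readout, 3) in
    cycles/FOV.
    """
    kr = (np.arange(n_readout) - n_readout // 2) * (2.0 * kmax / n_readout)
    return directions[:, None, :] * kr[None, :, None]


def _kb_kernel(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    z = 1.0 - (2.0 * u / width) ** 2
    out = np.zeros_like(u)
    ok = z > 0
    out[ok] = i0(beta * np.sqrt(z[ok]))
    return out


class RadialNufft3D:
    """Gridding NUFFT plan for a fixed set of non-Cartesian samples.

    Parameters
    ----------
    traj:
        (M, 3) sample coordinates in cycles/FOV, |k| <= N/2 per axis.
    n:
        Image matrix size N (cubic).
    oversampling:
        Grid oversampling factor (2 recommended; the grid is ``round(sigma N)``).
    width:
        Interpolation kernel width in oversampled grid points.
    """

    def __init__(self, traj: np.ndarray, n: int, oversampling: float = 2.0,
                 width: int = 6):
        traj = np.asarray(traj, dtype=float).reshape(-1, 3)
        if np.any(np.abs(traj) > n / 2 + 1e-9):
            raise ValueError("trajectory coordinates must satisfy |k| <= N/2")
        self.n = int(n)
        self.n_samples = traj.shape[0]
        self.grid = int(round(oversampling * n))
        self.sigma = self.grid / n
        self.width = int(width)
        # Beatty et al. kernel shape parameter
        w, s = self.width, self.sigma
        self.beta = np.pi * np.sqrt((w / s) ** 2 * (s - 0.5) ** 2 - 0.8)
        self._build_interpolator(traj)
        self._build_apodization()

    # -- construction ------------------------------------------------------
    def _build_interpolator(self, traj: np.ndarray) -> None:
        g, w = self.grid, self.width
        u = traj * self.sigma                       # oversampled grid units
        offs = np.arange(w) - (w // 2 - 1)          # kernel support offsets
        nnz_per = w ** 3
        m = traj.shape[0]
        data = np.empty((m, nnz_per))
        cols = np.empty((m, nnz_per), dtype=np.int64)
        # separable 1D weights and neighbor indices per axis
        wts, idxs = [], []
        for ax in range(3):
            base = np.floor(u[:, ax]).astype(np.int64)
            neigh = base[:, None] + offs[None, :]            # (m, w)
            wt = _kb_kernel(u[:, ax][:, None] - neigh, w, self.beta)
            wts.append(wt)
            idxs.append(np.mod(neigh, g))
        wx, wy, wz = wts
        ix, iy, iz = idxs
        data[:] = (wx[:, :, None, None] * wy[:, None, :, None]
                   * wz[:, None, None, :]).reshape(m, nnz_per)
        cols[:] = ((ix[:, :, None, None] * g + iy[:, None, :, None]) * g
                   + iz[:, None, None, :]).reshape(m, nnz_per)
        indptr = np.arange(0, (m + 1) * nnz_per, nnz_per, dtype=np.int64)
        self._interp = sparse.csr_matrix(
            (data.ravel(), cols.ravel(), indptr), shape=(m, g ** 3))
        self._interp_h = None  # built lazily

    def _build_apodization(self) -> None:
        # image-domain correction: continuous FT of the KB kernel,
        # Psi(f) = W sinh(sqrt(beta^2 - (pi W f)^2)) / sqrt(...), at f = r/G
        n, g, w, beta = self.n, self.grid, self.width, self.beta
        r = np.arange(-(n // 2), n - n // 2)
        arg = beta**2 - (np.pi * w * r / g) ** 2
        gam = np.sqrt(np.abs(arg))
        apod1 = w * np.where(arg > 0,
                             np.sinh(gam) / np.maximum(gam, 1e-30),
                             np.sinc(gam / np.pi))
        self._apod = (apod1[:, None, None] * apod1[None, :, None]
                      * apod1[None, None, :])
        # embedding indices: voxel r -> oversampled-grid index r mod G
        self._embed = np.mod(r, g)

    # -- operators ---------------------------------------------------------
    def forward(self, image: np.ndarray, rows: slice | np.ndarray | None = None,
                ) -> np.ndarray:
        """Evaluate the forward model at all samples (or a row subset)."""
        n, g = self.n, self.grid
        if image.shape != (n, n, n):
            raise ValueError(f"image must be {n}^3")
        xp = np.zeros((g, g, g), dtype=complex)
        e = self._embed
        xp[np.ix_(e, e, e)] = image / self._apod
        spec = np.fft.fftn(xp).ravel()
        mat = self._interp if rows is None else self._interp[rows]
        return mat @ spec

    def adjoint(self, samples: np.ndarray,
                rows: slice | np.ndarray | None = None) -> np.ndarray:
        """Exact adjoint of :meth:`forward` (same row subset)."""
        n, g = self.n, self.grid
        mat = self._interp if rows is None else self._interp[rows]
        spec = (mat.conj().T @ samples).reshape(g, g, g)
        xp = np.fft.ifftn(spec) * g ** 3
        e = self._embed
        return xp[np.ix_(e, e, e)] / self._apod

    def subset(self, rows) -> "_NufftView":
        """Operator view restricted to a subset of sample rows."""
        return _NufftView(self, np.asarray(rows))


class _NufftView:
    """Row-subset view of a :class:`RadialNufft3D` plan."""

    def __init__(self, plan: RadialNufft3D, rows: np.ndarray):
        self.plan = plan
        self.rows = rows
        self.n = plan.n
        self.n_samples = rows.size

    def forward(self, image: np.ndarray) -> np.ndarray:
        return self.plan.forward(image, rows=self.rows)

    def adjoint(self, samples: np.ndarray) -> np.ndarray:
        return self.plan.adjoint(samples, rows=self.rows)


def dft3_forward(image: np.ndarray, traj: np.ndarray) -> np.ndarray:
    """Direct (slow) discrete Fourier sum oracle for small problems."""
    n = image.shape[0]
    traj = np.asarray(traj, dtype=float).reshape(-1, 3)
    r = np.arange(-(n // 2), n - n // 2)
    ex = np.exp(-2j * np.pi * np.outer(traj[:, 0], r) / n)
    ey = np.exp(-2j * np.pi * np.outer(traj[:, 1], r) / n)
    ez = np.exp(-2j * np.pi * np.outer(traj[:, 2], r) / n)
    # contract image over z, then y and x per sample
    tmp = np.tensordot(image, ez, axes=([2], [1]))        # (x, y, M)
    out = np.empty(traj.shape[0], dtype=complex)
    for j in range(traj.shape[0]):
        out[j] = ex[j] @ (tmp[:, :, j] @ ey[j])
    return out
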