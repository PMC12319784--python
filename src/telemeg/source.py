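"""Source-space reconstruction: lead fields and the LCMV beamformer.

Sources are current dipoles on a regular grid (default 5 mm spacing) inside
a volume.  The forward model is the closed-form magnetic field of a current
dipole in a homogeneous conducting sphere, which has the physically exact
property that radially oriented dipoles are externally silent; each grid
point therefore keeps only two effective orientation degrees of freedom.
Inversion is a scalar linearly-constrained minimum-variance (LCMV)
beamformer with eigenvalue-truncated covariance regularisation (matching
the rank deficiency that homogeneous field correction introduces) and a
variance-maximising choice of source orientation per point.

Externally computed lead fields (e.g. from a realistic single-shell mesh
model) can be substituted anywhere a :class:`LeadField` is accepted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .preproc import MEGRecording, ProjectionOperator, SensorArray, compensate_leadfield

__all__ = [
    "SourceGrid",
    "LeadField",
    "BeamformerWeights",
    "make_grid",
    "dipole_field_sphere",
    "leadfield_sphere",
    "reduce_rank",
    "regularized_inverse",
    "lcmv_scalar",
    "lcmv_weights",
    "apply_weights",
    "localize_envelope_power",
]

_MU0_4PI = 1e-7    # mu_0 / 4 pi, SI


@dataclass
class SourceGrid:
    """Regular lattice of candidate source locations (metres)."""

    points: np.ndarray             # (n_src, 3)
    spacing: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    radius: float | None = None

    @property
    def n_sources(self) -> int:
        return len(self.points)


@dataclass
class LeadField:
    """Forward fields for every grid point.

    ``matrix`` is (n_src, channels, n_ori); after rank reduction n_ori = 2
    and ``ori_basis`` maps each point's reduced orientation coordinates
    back to 3-space.
    """

    matrix: np.ndarray             # (n_src, channels, n_ori)
    grid: SourceGrid
    model: str = "sphere"
    compensated: bool = False
    ori_basis: np.ndarray | None = None   # (n_src, 3, n_ori)

    @property
    def n_sources(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]


@dataclass
class BeamformerWeights:
    """Scalar LCMV weights: one spatial filter row per grid point."""

    weights: np.ndarray            # (n_src, channels)
    orientations: np.ndarray       # (n_src, 3)
    grid: SourceGrid
    cov_spectrum: np.ndarray | None = None   # full covariance eigenvalues


# ---------------------------------------------------------------------------
# grid and forward model


def make_grid(center, radius: float | None = None, spacing: float = 0.005,
              mask_fn=None) -> SourceGrid:
    """Axis-aligned lattice clipped to a sphere (or arbitrary mask).

    ``mask_fn``, if given, is a vectorised predicate over (n, 3) points and
    overrides the spherical clip.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    center = np.asarray(center, dtype=float)
    if mask_fn is None and radius is None:
        raise ValueError("give a radius or a mask function")
    extent = radius if radius is not None else spacing * 200
    n = int(np.floor(extent / spacing))
    offs = np.arange(-n, n + 1) * spacing
    gx, gy, gz = np.meshgrid(offs, offs, offs, indexing="ij")
    pts = center + np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)
    if mask_fn is not None:
        keep = mask_fn(pts)
    else:
        keep = np.linalg.norm(pts - center, axis=1) <= radius + 1e-12
    pts = pts[keep]
    if len(pts) == 0:
        raise ValueError("empty grid: no lattice point inside the volume")
    return SourceGrid(pts, float(spacing), center, radius)


def dipole_field_sphere(r0: np.ndarray, Q: np.ndarray, sensors: np.ndarray,
                        origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Magnetic field (T) of a current dipole in a conducting sphere.

    Closed-form solution for a homogeneous spherical conductor: the field
    outside the sphere depends only on the dipole position/moment and the
    sphere centre, not on its radius or conductivity.  Radial dipoles
    produce exactly zero external field (the silent radial source).

    Parameters
    ----------
    r0 : (3,) dipole location (m); Q : (3,) dipole moment (A m);
    sensors : (n, 3) field points; origin : sphere centre.
    """
    origin = np.asarray(origin, dtype=float)
    r0 = np.asarray(r0, dtype=float) - origin
    r = np.asarray(sensors, dtype=float) - origin
    if np.linalg.norm(r0) < 1e-12:
        raise ValueError("dipole at the sphere origin is ill-posed")
    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    if (a < 1e-9).any():
        raise ValueError("sensor coincident with the source")
    R = np.linalg.norm(r, axis=1)
    r0_dot_r = r @ r0
    F = a * (R * a + R**2 - r0_dot_r)
    adotr = np.einsum("ij,ij->i", a_vec, r)
    gradF = ((a**2 / R + adotr / a + 2 * a + 2 * R)[:, None] * r
             - (a + 2 * R + adotr / a)[:, None] * r0)
    Qxr0 = np.cross(Q, r0)
    B = _MU0_4PI / F[:, None]**2 * (F[:, None] * Qxr0
                                    - (r @ Qxr0)[:, None] * gradF)
    return B


def leadfield_sphere(grid: SourceGrid, array: SensorArray,
                     origin=(0.0, 0.0, 0.0)) -> LeadField:
    """Lead fields of the 3 cardinal dipole orientations at every grid point,
    projected on the sensors' sensitive axes.  Disabled channels are
    excluded (the channel axis covers enabled channels only)."""
    mask = array.channel_enabled
    pos = array.positions[mask]
    ori = array.orientations[mask]
    n_src = grid.n_sources
    L = np.empty((n_src, int(mask.sum()), 3))
    eye = np.eye(3)
    for s in range(n_src):
        for c in range(3):
            B = dipole_field_sphere(grid.points[s], eye[c], pos, origin)
            L[s, :, c] = np.einsum("ij,ij->i", B, ori)
    return LeadField(L, grid, model="sphere")


def reduce_rank(L_point: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop the (near-silent) weakest orientation of a 3-orientation lead field.

    SVD of the channels x 3 block; the two strongest left singular
    directions (scaled by their singular values) are retained, and the
    corresponding right singular vectors give the 3-space orientation basis
    of the retained components.  Returns (L2 (channels, 2), basis (3, 2)).
    """
    L_point = np.asarray(L_point, dtype=float)
    U, s, Vt = np.linalg.svd(L_point, full_matrices=False)
    if s[1] <= 1e-15 * max(s[0], 1e-300):
        raise ValueError("lead field has rank < 2 at this point")
    L2 = U[:, :2] * s[:2]
    return L2, Vt[:2].T


def reduce_rank_leadfield(L: LeadField) -> LeadField:
    """Apply :func:`reduce_rank` at every grid point."""
    n_src, n_ch, _ = L.matrix.shape
    M = np.empty((n_src, n_ch, 2))
    basis = np.empty((n_src, 3, 2))
    for s in range(n_src):
        M[s], basis[s] = reduce_rank(L.matrix[s])
    return LeadField(M, L.grid, L.model, L.compensated, basis)


# ---------------------------------------------------------------------------
# inverse


def regularized_inverse(cov: np.ndarray, discard: int = 8):
    """Pseudo-inverse of a sensor covariance over its leading eigenspace.

    The ``discard`` smallest eigenpairs are dropped — matching the rank
    deficiency introduced by projecting out the 8 HFC components — and the
    inverse is formed on the retained span.  Returns (C_inv, eigenvalues)
    with eigenvalues in descending order.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    sym_err = np.abs(cov - cov.T).max()
    if sym_err > 1e-8 * max(np.abs(cov).max(), 1e-300):
        raise ValueError(f"covariance not symmetric (max asymmetry {sym_err:g})")
    if not 0 <= discard < cov.shape[0]:
        raise ValueError("discard must be in [0, channels)")
    cov = 0.5 * (cov + cov.T)
    w, V = np.linalg.eigh(cov)          # ascending
    w, V = w[::-1], V[:, ::-1]
    keep = cov.shape[0] - discard
    wk, Vk = w[:keep], V[:, :keep]
    if wk[-1] <= 0:
        raise ValueError("retained eigenvalues must be positive; "
                         "discard more components or check the covariance")
    C_inv = (Vk / wk) @ Vk.T
    return C_inv, w


def lcmv_scalar(C_inv: np.ndarray, L_point: np.ndarray,
                ori_basis: np.ndarray | None = None):
    """Scalar LCMV filter for one grid point.

    Over unit orientations ``u`` in the point's reduced orientation space,
    the noise-normalised output variance (u' L' C+ L u) / (u' L' C+ C+ L u)
    is maximised — a 2x2 generalised eigenproblem — and the unit-gain
    minimum-variance weights w = C+ l / (l' C+ l) are formed for the winning
    orientation l = L u.  Returns (w (channels,), orientation (3,)).
    """
    L_point = np.asarray(L_point, dtype=float)
    A = L_point.T @ C_inv @ L_point
    B = L_point.T @ C_inv @ C_inv @ L_point
    evals, evecs = linalg.eigh(A, B)
    u = evecs[:, -1]                      # largest generalised eigenvalue
    u = u / np.linalg.norm(u)             # eigh returns B-normalised vectors
    ori = ori_basis @ u if ori_basis is not None else u
    ori = ori / np.linalg.norm(ori)
    # fix the arbitrary orientation sign: positive first non-zero component
    nz = np.flatnonzero(np.abs(ori) > 1e-12)
    if nz.size and ori[nz[0]] < 0:
        ori, u = -ori, -u
    l = L_point @ u
    denom = float(l @ C_inv @ l)
    if denom <= 0:
        raise ValueError("l' C+ l <= 0: lead field lies outside the "
                         "retained covariance span")
    w = (C_inv @ l) / denom
    return w, ori


def lcmv_weights(cov: np.ndarray, L: LeadField,
                 discard: int = 8) -> BeamformerWeights:
    """LCMV spatial filters for every grid point of a reduced lead field."""
    if L.matrix.shape[2] != 2:
        raise ValueError("lead field must be rank-reduced (2 orientations) "
                         "before beamforming")
    C_inv, spectrum = regularized_inverse(cov, discard)
    n_src = L.n_sources
    W = np.empty((n_src, L.n_channels))
    oris = np.empty((n_src, 3))
    for s in range(n_src):
        basis = None if L.ori_basis is None else L.ori_basis[s]
        W[s], oris[s] = lcmv_scalar(C_inv, L.matrix[s], basis)
    return BeamformerWeights(W, oris, L.grid, spectrum)


def apply_weights(weights: BeamformerWeights, data: np.ndarray) -> np.ndarray:
    """Source time courses s(t) = W data(t); data is (enabled channels, T)."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] != weights.weights.shape[1]:
        raise ValueError("channel count mismatch between weights and data")
    return weights.weights @ data


def localize_envelope_power(rec_or_data, weights: BeamformerWeights,
                            depth_normalize: bool = False) -> np.ndarray:
    """Per-grid-point output variance map of the beamformed recording.

    With ``depth_normalize`` the variance is divided by w'w (neural
    activity index style), flattening the white-noise floor across depths.
    """
    if isinstance(rec_or_data, MEGRecording):
        data = rec_or_data.data[rec_or_data.array.channel_enabled]
    else:
        data = np.asarray(rec_or_data, dtype=float)
    S = apply_weights(weights, data)
    var = S.var(axis=1)
    if depth_normalize:
        var = var / np.einsum("ij,ij->i", weights.weights, weights.weights)
    return var


def compensate(L: LeadField, op: ProjectionOperator) -> LeadField:
    """HFC-compensated copy of a lead field (see preproc.compensate_leadfield)."""
    M = np.moveaxis(compensate_leadfield(np.moveaxis(L.matrix, 1, 0), op), 0, 1)
    return LeadField(M, L.grid, L.model, True, L.ori_basis)
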