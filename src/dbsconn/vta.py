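"""Stimulation-induced electric fields and volumes of tissue activated.

Two field models are provided:

``efield_analytic``
    Point-source solution in a homogeneous medium,
    ``|E|(r) = I / (4 pi sigma r^2)`` with ``I = V / Z`` per active contact.
    Multi-contact settings superpose the vector fields.  This is the
    closed-form oracle for the numerical solver and the fast default for
    phantom cohorts.

``efield_fdm``
    Finite-difference solution of the quasi-static volume-conductor problem
    ``div(sigma grad phi) = 0`` on the voxel lattice with Dirichlet
    ``phi = amplitude`` on active-contact voxels and ``phi = 0`` on the
    ground surface.  Tissue conductivities are isotropic scalars per voxel
    (grey 0.33 S/m, white 0.14 S/m, CSF/background 2.0 S/m by default).

The binary VTA is the set of voxels where ``|E|`` meets an activation
threshold, 0.2 V/mm by default.

Units: coordinates and voxel sizes in mm, conductivity in S/m, current in A,
fields in V/mm.  The mixed mm/m convention gives
``|E| [V/mm] = 1000 * I / (4 pi sigma r_mm^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .electrode import (
    DEFAULT_IMPEDANCE_OHM,
    LeadModel,
    LeadPlacement,
    StimConfig,
    active_contact_centers,
)
from .volumes import FieldVolume, LabelVolume, sphere_mask

__all__ = [
    "ConductivityModel",
    "VTAMask",
    "FieldSolveError",
    "DEFAULT_THRESHOLD_V_PER_MM",
    "efield_analytic",
    "efield_fdm",
    "binarize_vta",
    "vta_metrics",
    "analytic_vta_radius_mm",
]

DEFAULT_THRESHOLD_V_PER_MM = 0.2

# tissue codes in phantom tissue volumes
CSF, GM, WM = 0, 1, 2


class FieldSolveError(RuntimeError):
    """The iterative field solver failed to reach the requested residual."""


@dataclass(frozen=True)
class ConductivityModel:
    """Isotropic scalar conductivities per tissue class, S/m."""

    sigma_gm: float = 0.33
    sigma_wm: float = 0.14
    sigma_csf: float = 2.0

    def __post_init__(self) -> None:
        if min(self.sigma_gm, self.sigma_wm, self.sigma_csf) <= 0:
            raise ValueError("conductivities must be positive")

    def per_voxel(self, tissue: LabelVolume) -> np.ndarray:
        sigma = np.full(tissue.shape, self.sigma_csf, dtype=float)
        sigma[tissue.data == GM] = self.sigma_gm
        sigma[tissue.data == WM] = self.sigma_wm
        return sigma


@dataclass
class VTAMask:
    """Binary volume of tissue activated plus bookkeeping."""

    mask: LabelVolume  # boolean data
    threshold_v_per_mm: float
    volume_mm3: float

    @property
    def is_empty(self) -> bool:
        return self.mask.count_nonzero() == 0


def analytic_vta_radius_mm(
    amplitude_v: float,
    sigma: float,
    threshold: float = DEFAULT_THRESHOLD_V_PER_MM,
    impedance_ohm: float = DEFAULT_IMPEDANCE_OHM,
) -> float:
    """Radius where the point-source field crosses the activation threshold.

    ``r = sqrt(1000 I / (4 pi sigma e))`` in mm for a single active contact.
    """
    current = amplitude_v / impedance_ohm
    if current == 0:
        return 0.0
    return float(np.sqrt(1000.0 * current / (4.0 * np.pi * sigma * threshold)))


def _grid_world_axes(grid: LabelVolume):
    h = grid.voxel_size
    origin = grid.affine[:3, 3]
    return tuple(
        origin[a] + np.arange(grid.shape[a]) * h[a] for a in range(3)
    )


def efield_analytic(
    stim: StimConfig,
    placement: LeadPlacement,
    model: LeadModel,
    sigma: float,
    grid: LabelVolume,
    impedance_ohm: float = DEFAULT_IMPEDANCE_OHM,
) -> FieldVolume:
    """Closed-form |E| for monopolar point sources in a homogeneous medium.

    Each active contact is an independent current source ``I = V / Z``;
    multiple active contacts superpose as vector fields.  The voxel hosting a
    source (r ~ 0) is assigned the maximum of its 6-neighbours so the field
    stays finite on the lattice.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    xs, ys, zs = _grid_world_axes(grid)
    ex = np.zeros(grid.shape)
    ey = np.zeros(grid.shape)
    ez = np.zeros(grid.shape)
    current = stim.current_a(impedance_ohm)
    centers = active_contact_centers(model, placement, stim) if current > 0 else []
    source_idx = []
    for c in centers:
        dx = (xs - c[0])[:, None, None]
        dy = (ys - c[1])[None, :, None]
        dz = (zs - c[2])[None, None, :]
        r2 = dx**2 + dy**2 + dz**2
        near = r2 < 1e-12
        r2 = np.where(near, np.inf, r2)
        r = np.sqrt(r2)
        # E_vec = 1000 I / (4 pi sigma r^2) * r_hat   [V/mm]
        scale = 1000.0 * current / (4.0 * np.pi * sigma * r2 * r)
        ex += scale * dx
        ey += scale * dy
        ez += scale * dz
        source_idx.extend(np.argwhere(near))
    mag = np.sqrt(ex**2 + ey**2 + ez**2)
    for ijk in source_idx:
        mag[tuple(ijk)] = _max_neighbor(mag, tuple(ijk))
    return FieldVolume(
        mag,
        grid.affine.copy(),
        meta={
            "model": "analytic",
            "sigma_s_per_m": sigma,
            "current_a_per_contact": current,
            "contact_centers_mm": [list(map(float, c)) for c in centers],
        },
    )


def _max_neighbor(vol: np.ndarray, ijk) -> float:
    best = 0.0
    for axis in range(3):
        for step in (-1, 1):
            n = list(ijk)
            n[axis] += step
            if 0 <= n[axis] < vol.shape[axis]:
                v = vol[tuple(n)]
                if np.isfinite(v):
                    best = max(best, float(v))
    return best


def _contact_voxel_mask(
    grid: LabelVolume, centers: np.ndarray, model: LeadModel
) -> np.ndarray:
    """Dirichlet patch: voxels whose centre lies within half a contact length
    (at least one voxel half-diagonal) of an active contact centre."""
    h = float(np.max(grid.voxel_size))
    radius = max(model.contact_length_mm / 2.0, 0.51 * h)
    mask = np.zeros(grid.shape, dtype=bool)
    for c in centers:
        mask |= sphere_mask(grid, c, radius)
    return mask


def efield_fdm(
    stim: StimConfig,
    placement: LeadPlacement,
    model: LeadModel,
    tissue: LabelVolume,
    cond: ConductivityModel,
    rtol: float = 1e-6,
    max_iter: int = 10_000,
    ground: str = "boundary",
    impedance_ohm: float = DEFAULT_IMPEDANCE_OHM,
) -> FieldVolume:
    """Finite-difference volume-conductor field on the tissue lattice.

    Solves ``div(sigma grad phi) = 0`` with a 7-point stencil and harmonic-mean
    face conductivities, ``phi = amplitude`` on the active-contact voxel patch
    and ``phi = 0`` on the ground surface (conjugate gradients, relative
    residual ``rtol``).  ``ground="boundary"`` grounds the outer grid faces;
    ``ground="sphere"`` grounds everything outside the largest inscribed
    sphere, which removes the cubic anisotropy of the far-field return path.

    |E| is the central-difference gradient magnitude of phi in V/mm.
    """
    if stim.amplitude_v == 0:
        return FieldVolume(np.zeros(tissue.shape), tissue.affine.copy(),
                           meta={"model": "fdm", "source_current_a": 0.0})
    centers = active_contact_centers(model, placement, stim)
    if not np.all(tissue.inside(centers)):
        raise ValueError("active contact centre outside the tissue grid")

    sigma = cond.per_voxel(tissue)
    shape = tissue.shape
    h = float(tissue.voxel_size[0])
    if not np.allclose(tissue.voxel_size, h):
        raise ValueError("efield_fdm requires isotropic voxels")

    contact = _contact_voxel_mask(tissue, centers, model)
    groundmask = np.zeros(shape, dtype=bool)
    if ground == "boundary":
        groundmask[0, :, :] = groundmask[-1, :, :] = True
        groundmask[:, 0, :] = groundmask[:, -1, :] = True
        groundmask[:, :, 0] = groundmask[:, :, -1] = True
    elif ground == "sphere":
        center = tissue.voxel_to_world([np.asarray(shape) // 2])[0]
        r = (min(shape) // 2 - 1) * h
        groundmask = ~sphere_mask(tissue, center, r)
    else:
        raise ValueError("ground must be 'boundary' or 'sphere'")
    groundmask &= ~contact

    fixed = contact | groundmask
    phi_fixed = np.zeros(shape)
    phi_fixed[contact] = stim.amplitude_v

    free = ~fixed
    n_free = int(free.sum())
    index = -np.ones(shape, dtype=np.int64)
    index[free] = np.arange(n_free)

    rows, cols, vals = [], [], []
    diag = np.zeros(n_free)
    rhs = np.zeros(n_free)
    free_idx = np.argwhere(free)
    fi = index[free]  # row ids in free order

    for axis in range(3):
        for step in (-1, 1):
            nb = free_idx.copy()
            nb[:, axis] += step
            valid = (nb[:, axis] >= 0) & (nb[:, axis] < shape[axis])
            a = free_idx[valid]
            b = nb[valid]
            s_a = sigma[a[:, 0], a[:, 1], a[:, 2]]
            s_b = sigma[b[:, 0], b[:, 1], b[:, 2]]
            g = 2.0 * s_a * s_b / (s_a + s_b)  # harmonic mean face conductivity
            r_ids = index[a[:, 0], a[:, 1], a[:, 2]]
            nb_free = free[b[:, 0], b[:, 1], b[:, 2]]
            np.add.at(diag, r_ids, g)
            # free neighbour -> off-diagonal; fixed neighbour -> RHS
            rf = r_ids[nb_free]
            bf = b[nb_free]
            rows.append(rf)
            cols.append(index[bf[:, 0], bf[:, 1], bf[:, 2]])
            vals.append(-g[nb_free])
            rx = r_ids[~nb_free]
            bx = b[~nb_free]
            np.add.at(rhs, rx, g[~nb_free] * phi_fixed[bx[:, 0], bx[:, 1], bx[:, 2]])

    rows.append(np.arange(n_free))
    cols.append(np.arange(n_free))
    vals.append(diag)
    A = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_free, n_free),
    )
    M = sp.diags(1.0 / diag)
    x, info = spla.cg(A, rhs, rtol=rtol, maxiter=max_iter, M=M)
    resid = float(np.linalg.norm(A @ x - rhs) / np.linalg.norm(rhs))
    if info > 0:
        raise FieldSolveError(
            f"CG did not converge in {max_iter} iterations (residual {resid:.3e})"
        )

    phi = phi_fixed.copy()
    phi[free] = x

    mag = _gradient_magnitude(phi, h)

    # total current leaving the contact patch: sum of face conductances times
    # potential drops; sigma [S/m] * h [mm] * 1e-3 gives face conductance in S.
    current = 0.0
    cidx = np.argwhere(contact)
    for axis in range(3):
        for step in (-1, 1):
            nb = cidx.copy()
            nb[:, axis] += step
            valid = (nb[:, axis] >= 0) & (nb[:, axis] < shape[axis])
            a = cidx[valid]
            b = nb[valid]
            outside = ~contact[b[:, 0], b[:, 1], b[:, 2]]
            a, b = a[outside], b[outside]
            s_a = sigma[a[:, 0], a[:, 1], a[:, 2]]
            s_b = sigma[b[:, 0], b[:, 1], b[:, 2]]
            g = 2.0 * s_a * s_b / (s_a + s_b) * h * 1e-3
            current += float(
                np.sum(g * (phi[a[:, 0], a[:, 1], a[:, 2]] - phi[b[:, 0], b[:, 1], b[:, 2]]))
            )

    return FieldVolume(
        mag,
        tissue.affine.copy(),
        meta={
            "model": "fdm",
            "ground": ground,
            "residual": resid,
            "source_current_a": current,
            "contact_centers_mm": [list(map(float, c)) for c in centers],
            "phi": phi,
        },
    )


def _gradient_magnitude(phi: np.ndarray, h: float) -> np.ndarray:
    """|grad phi| in V/mm by 4th-order central differences.

    Fourth order matters here: the 1/r^2 curvature of a point-source field
    makes 2nd-order central differences underestimate |E| by (h/r)^2 — over
    10 % within a few voxels of a contact.  Near the array edge the scheme
    falls back to ``np.gradient``'s 2nd-order stencils.
    """
    grads = []
    for axis in range(3):
        g = np.gradient(phi, h, axis=axis)  # 2nd-order fallback everywhere
        # interior 4th-order: (-f[i+2] + 8 f[i+1] - 8 f[i-1] + f[i-2]) / 12h
        sl = [slice(None)] * 3

        def shifted(k, axis=axis, sl=sl):
            s = list(sl)
            n = phi.shape[axis]
            s[axis] = slice(2 + k, n - 2 + k)
            return phi[tuple(s)]

        interior = (
            -shifted(2) + 8.0 * shifted(1) - 8.0 * shifted(-1) + shifted(-2)
        ) / (12.0 * h)
        s = [slice(None)] * 3
        s[axis] = slice(2, phi.shape[axis] - 2)
        g[tuple(s)] = interior
        grads.append(g)
    return np.sqrt(grads[0] ** 2 + grads[1] ** 2 + grads[2] ** 2)


def binarize_vta(
    field: FieldVolume, threshold: float = DEFAULT_THRESHOLD_V_PER_MM
) -> VTAMask:
    """Threshold |E| >= threshold into a binary VTA."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    data = np.asarray(field.data, dtype=float)
    mask = np.isfinite(data) & (data >= threshold)
    vol = float(mask.sum()) * field.voxel_volume
    return VTAMask(
        mask=LabelVolume(mask, field.affine.copy()),
        threshold_v_per_mm=float(threshold),
        volume_mm3=vol,
    )


def vta_metrics(vta: VTAMask, nucleus: LabelVolume) -> dict:
    """Overlap and distance metrics between a VTA and a nucleus mask.

    Returns overlap volume (mm^3), overlap as a fraction of the nucleus,
    the Euclidean distance between mask centroids, and the minimum
    voxel-centre distance (0 when the masks intersect).  An empty VTA yields
    NaN distances with ``flagged=True``; an empty nucleus is an error.
    """
    nmask = nucleus.data != 0
    if not nmask.any():
        raise ValueError("nucleus mask is empty")
    if not np.allclose(vta.mask.affine, nucleus.affine):
        raise ValueError("VTA and nucleus are not on the same grid")
    vmask = vta.mask.data.astype(bool)
    voxvol = nucleus.voxel_volume
    if not vmask.any():
        return {
            "overlap_mm3": 0.0,
            "overlap_fraction_of_nucleus": 0.0,
            "centroid_distance_mm": float("nan"),
            "min_distance_mm": float("nan"),
            "flagged": True,
        }
    inter = int(np.count_nonzero(vmask & nmask))
    overlap_mm3 = inter * voxvol
    c_v = vta.mask.like(vmask).centroid_mm()
    c_n = nucleus.like(nmask).centroid_mm()
    centroid_d = float(np.linalg.norm(c_v - c_n))
    if inter > 0:
        min_d = 0.0
    else:
        dist = ndimage.distance_transform_edt(
            ~nmask, sampling=nucleus.voxel_size
        )
        min_d = float(dist[vmask].min())
    return {
        "overlap_mm3": float(overlap_mm3),
        "overlap_fraction_of_nucleus": float(inter / np.count_nonzero(nmask)),
        "centroid_distance_mm": centroid_d,
        "min_distance_mm": min_d,
        "flagged": False,
    }
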