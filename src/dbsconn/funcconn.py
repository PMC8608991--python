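"""Normative seed-based functional connectivity.

Minimal preprocessing (Gaussian smoothing, nuisance regression, zero-phase
band-pass), VTA-seeded Pearson correlation maps, the Fisher z transform, and
the across-subject one-sample t-map.

Preprocessing order is smooth -> regress -> filter.  The band-pass is a
4th-order Butterworth applied forward-backward (zero phase); nuisance
regression is ordinary least squares against the confound set plus an
intercept.  Mean white-matter and CSF series computed from the phantom
tissue labels serve as the standard confound pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .volumes import LabelVolume

__all__ = [
    "FMRISeries",
    "preprocess_series",
    "tissue_confounds",
    "seed_map",
    "fisher_z",
    "group_tmap",
    "region_summary",
]

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))
_R_CLAMP = 1.0 - 1e-7


@dataclass
class FMRISeries:
    """A 4-D (x, y, z, t) BOLD-like series on a phantom grid."""

    data: np.ndarray
    affine: np.ndarray
    tr: float  # seconds

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("fMRI data must be 4-D (x, y, z, t)")
        if self.data.shape[-1] < 20:
            raise ValueError("need >= 20 frames")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("fMRI data must be finite")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    def grid(self) -> LabelVolume:
        return LabelVolume(np.zeros(self.data.shape[:3], dtype=np.int16), self.affine)


def tissue_confounds(fmri: FMRISeries, tissue: LabelVolume) -> np.ndarray:
    """(t, 2) mean WM and CSF/background series, the standard nuisance pair."""
    if tissue.shape != fmri.data.shape[:3]:
        raise ValueError("tissue map does not match the fMRI grid")
    wm = fmri.data[tissue.data == 2].mean(axis=0)
    csf = fmri.data[tissue.data == 0].mean(axis=0)
    return np.column_stack([wm, csf])


def preprocess_series(
    fmri: FMRISeries,
    confounds: np.ndarray | None = None,
    band: tuple[float, float] = (0.01, 0.08),
    fwhm_mm: float = 6.0,
    filter_order: int = 4,
) -> FMRISeries:
    """Smooth, residualize against confounds, and band-pass a 4-D series.

    ``band`` is (low, high) in Hz and must lie strictly inside (0, Nyquist).
    ``fwhm_mm=0`` skips smoothing; ``confounds=None`` still removes the mean
    (intercept-only regression), so constant series vanish.
    """
    lo, hi = band
    nyq = 0.5 / fmri.tr
    if not 0.0 < lo < hi < nyq:
        raise ValueError(
            f"band {band} must satisfy 0 < low < high < Nyquist ({nyq:.4f} Hz)"
        )
    data = np.asarray(fmri.data, dtype=float)
    n_t = data.shape[-1]

    if fwhm_mm > 0:
        voxel = np.linalg.norm(fmri.affine[:3, :3], axis=0)
        sigma_vox = (fwhm_mm / _FWHM_TO_SIGMA) / voxel
        data = ndimage.gaussian_filter(
            data, sigma=tuple(sigma_vox) + (0.0,), mode="nearest"
        )

    X = np.ones((n_t, 1))
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != n_t:
            if confounds.shape[1] == n_t:
                confounds = confounds.T
            else:
                raise ValueError("confound series length does not match frames")
        X = np.column_stack([X, confounds])
    flat = data.reshape(-1, n_t).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    flat = flat - X @ beta

    sos = signal.butter(
        filter_order, [lo, hi], btype="bandpass", fs=1.0 / fmri.tr, output="sos"
    )
    padlen = min(3 * (2 * filter_order + 1), n_t - 1)
    flat = signal.sosfiltfilt(sos, flat, axis=0, padlen=padlen)

    return FMRISeries(flat.T.reshape(data.shape), fmri.affine.copy(), fmri.tr)


@dataclass
class StatMap:
    """A voxelwise statistic volume (r, z, or t)."""

    data: np.ndarray
    affine: np.ndarray
    kind: str
    n_subjects: int | None = None
    flagged: np.ndarray | None = None  # boolean volume of undefined voxels

    def volume(self) -> LabelVolume:
        return LabelVolume(self.data, self.affine)


def seed_map(fmri: FMRISeries, seed) -> StatMap:
    """Voxelwise Pearson correlation with the mean series over seed voxels.

    Voxels with zero temporal variance get NaN and are flagged.
    """
    seed_data = seed.mask.data if hasattr(seed, "mask") else seed.data
    seed_data = np.asarray(seed_data).astype(bool)
    if seed_data.shape != fmri.data.shape[:3]:
        raise ValueError("seed mask does not match the fMRI grid")
    if not seed_data.any():
        raise ValueError("seed mask is empty")
    ts = np.asarray(fmri.data, dtype=float)
    seed_series = ts[seed_data].mean(axis=0)
    s = seed_series - seed_series.mean()
    s_norm = np.sqrt((s**2).sum())
    if s_norm == 0:
        raise ValueError("seed series has zero variance")
    flat = ts.reshape(-1, ts.shape[-1])
    flat = flat - flat.mean(axis=1, keepdims=True)
    vnorm = np.sqrt((flat**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (flat @ s) / (vnorm * s_norm)
    flagged = vnorm == 0
    r[flagged] = np.nan
    return StatMap(
        r.reshape(ts.shape[:3]),
        fmri.affine.copy(),
        kind="r",
        flagged=flagged.reshape(ts.shape[:3]),
    )


def fisher_z(rmap: StatMap) -> StatMap:
    """z = atanh(r); |r| within 1e-7 of 1 is clamped before the transform."""
    r = np.asarray(rmap.data, dtype=float)
    clamped = np.abs(r) >= _R_CLAMP
    z = np.arctanh(np.clip(r, -_R_CLAMP, _R_CLAMP))
    z[np.isnan(r)] = np.nan
    flagged = clamped | (rmap.flagged if rmap.flagged is not None else False)
    return StatMap(z, rmap.affine, kind="z", flagged=np.asarray(flagged))


def group_tmap(zmaps: list[StatMap]) -> StatMap:
    """One-sample t across subjects per voxel: ``mean(z) * sqrt(n) / sd(z)``.

    Voxels with sd = 0 give t = 0 when the mean is also 0, and a flagged
    signed-infinity sentinel otherwise.
    """
    if len(zmaps) < 3:
        raise ValueError("need >= 3 subjects")
    aff = zmaps[0].affine
    for m in zmaps[1:]:
        if m.data.shape != zmaps[0].data.shape or not np.allclose(m.affine, aff):
            raise ValueError("z-maps are not on a common grid")
    stack = np.stack([m.data for m in zmaps], axis=0)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean * np.sqrt(n) / sd
    # sd "zero" up to float rounding of identical inputs
    degenerate = sd <= 1e-12 * np.maximum(1.0, np.abs(mean))
    zero_mean = np.abs(mean) <= 1e-15
    t[degenerate & zero_mean] = 0.0
    sentinel = degenerate & ~zero_mean
    t[sentinel] = np.sign(mean[sentinel]) * np.inf
    return StatMap(t, aff.copy(), kind="t", n_subjects=n, flagged=sentinel)


def region_summary(
    stat_map: StatMap, parcellation: LabelVolume, region_labels: dict
) -> pd.DataFrame:
    """Mean statistic per parcellation region (finite voxels only)."""
    rows = []
    for name, label in region_labels.items():
        sel = parcellation.data == label
        vals = stat_map.data[sel]
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "region": name,
                "label": label,
                "n_voxels": int(sel.sum()),
                f"mean_{stat_map.kind}": float(vals.mean()) if vals.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
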