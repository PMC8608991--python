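"""VTA-seeded structural connectivity.

A streamline is *connected* to a VTA when any vertex of the streamline,
after resampling to at most half a voxel spacing, falls inside the binary
mask.  Bilateral VTAs of one patient are united into a single mask before
selection, since outcomes are per patient.  An optional dilation radius
exposes proximity-style variants of the selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import stats as _stats
from .tracts import Tractogram, resample_streamline
from .volumes import LabelVolume
from .vta import VTAMask

__all__ = [
    "RegionalProfile",
    "connected_fibers",
    "terminal_regions",
    "regional_profile",
    "profile_outcome_association",
    "bundle_atlas_overlap",
    "union_vta_mask",
]


def _as_mask_volume(mask) -> LabelVolume:
    if isinstance(mask, VTAMask):
        mask = mask.mask
    if not isinstance(mask, LabelVolume):
        raise TypeError("mask must be a VTAMask or LabelVolume")
    return mask.like(mask.data.astype(bool))


def union_vta_mask(vtas) -> LabelVolume:
    """Union several VTA masks (e.g. the two hemispheres of one patient)."""
    vols = [_as_mask_volume(v) for v in vtas]
    data = np.zeros(vols[0].shape, dtype=bool)
    for v in vols:
        if not np.allclose(v.affine, vols[0].affine):
            raise ValueError("VTA masks are not on the same grid")
        data |= v.data
    return vols[0].like(data)


def _any_vertex_inside(batch: np.ndarray, vol: LabelVolume, step: float) -> np.ndarray:
    """Per-streamline traversal test for a (m, p, 3) batch of equal-length
    streamlines: every segment is subdivided into chords of length <= step and
    any subdivided vertex inside the mask selects the streamline."""
    seg = np.diff(batch, axis=1)  # (m, p-1, 3)
    seglen = np.linalg.norm(seg, axis=2)
    f = max(1, int(np.ceil(seglen.max() / step))) if seglen.size else 1
    frac = np.arange(f, dtype=batch.dtype) / f
    pts = batch[:, :-1, None, :] + seg[:, :, None, :] * frac[None, None, :, None]
    pts = np.concatenate(
        [pts.reshape(batch.shape[0], -1, 3), batch[:, -1:, :]], axis=1
    )
    m, n, _ = pts.shape
    hit = vol.sample(pts.reshape(-1, 3), outside=0).reshape(m, n)
    return hit.any(axis=1)


def connected_fibers(
    tractogram: Tractogram,
    mask,
    step: float | None = None,
    dilation_mm: float = 0.0,
    batch_size: int = 4096,
) -> np.ndarray:
    """Indices of streamlines traversing the mask.

    Each streamline segment is subdivided to chord spacing <= ``step``
    (default: half the voxel size) and the streamline is selected iff any
    subdivided vertex lies inside the (optionally dilated) mask.  Selection is
    invariant to point-order reversal and monotone in the mask.  A cheap
    bounding-box prefilter skips streamlines that cannot touch the mask.
    """
    vol = _as_mask_volume(mask)
    if not vol.data.any():
        raise ValueError("mask is empty")
    if dilation_mm > 0:
        dist = ndimage.distance_transform_edt(~vol.data, sampling=vol.voxel_size)
        vol = vol.like(dist <= dilation_mm)
    if step is None:
        step = float(np.min(vol.voxel_size)) / 2.0
    if len(tractogram) == 0:
        return np.array([], dtype=int)

    # bounding box of mask voxel cubes, padded so the prefilter is conservative
    idx = np.argwhere(vol.data)
    lo_w = vol.voxel_to_world(idx.min(axis=0)[None, :])[0] - vol.voxel_size
    hi_w = vol.voxel_to_world(idx.max(axis=0)[None, :])[0] + vol.voxel_size

    lengths = {len(sl) for sl in tractogram.streamlines}
    candidates = [
        i
        for i, sl in enumerate(tractogram)
        if not (np.any(sl.max(axis=0) < lo_w) or np.any(sl.min(axis=0) > hi_w))
    ]
    if not candidates:
        return np.array([], dtype=int)

    selected = []
    if len(lengths) == 1:
        for start in range(0, len(candidates), batch_size):
            chunk = candidates[start : start + batch_size]
            batch = np.stack([tractogram[i] for i in chunk]).astype(np.float64)
            keep = _any_vertex_inside(batch, vol, step)
            selected.extend(int(chunk[j]) for j in np.flatnonzero(keep))
    else:
        for i in candidates:
            batch = tractogram[i][None, :, :].astype(np.float64)
            if _any_vertex_inside(batch, vol, step)[0]:
                selected.append(i)
    return np.asarray(selected, dtype=int)


def terminal_regions(tractogram: Tractogram, parcellation: LabelVolume) -> np.ndarray:
    """(n, 2) array of (start_label, end_label); 0 outside every region."""
    starts, ends = tractogram.endpoints()
    return np.column_stack(
        [
            parcellation.sample(starts, outside=0),
            parcellation.sample(ends, outside=0),
        ]
    )


@dataclass
class RegionalProfile:
    """Per-region streamline counts for one patient's VTA."""

    table: pd.DataFrame  # columns: region, label, raw_count, normalized_count
    n_total_streamlines: int
    flagged: bool = False

    def raw(self, region: str) -> int:
        return int(self.table.set_index("region").loc[region, "raw_count"])

    def normalized(self, region: str) -> float:
        return float(
            self.table.set_index("region").loc[region, "normalized_count"]
        )


def regional_profile(
    tractogram: Tractogram,
    vta,
    parcellation: LabelVolume,
    region_labels: dict,
    step: float | None = None,
    dilation_mm: float = 0.0,
) -> RegionalProfile:
    """Count VTA-connected streamlines by the region of their far endpoint.

    The far endpoint of a connected streamline is the endpoint with the
    larger Euclidean distance from the VTA centroid.  Normalized counts are
    ``raw / (total streamlines * region voxel count)``; raw counts are always
    also reported.  An empty VTA yields an all-zero, flagged profile.
    """
    n_total = len(tractogram)
    vol = _as_mask_volume(vta)
    names = list(region_labels)
    voxcounts = {
        name: int(np.count_nonzero(parcellation.data == region_labels[name]))
        for name in names
    }
    if not vol.data.any():
        table = pd.DataFrame(
            {
                "region": names,
                "label": [region_labels[n] for n in names],
                "raw_count": 0,
                "normalized_count": 0.0,
            }
        )
        return RegionalProfile(table, n_total, flagged=True)

    sel = connected_fibers(tractogram, vol, step=step, dilation_mm=dilation_mm)
    centroid = vol.centroid_mm()
    raw = dict.fromkeys(names, 0)
    if sel.size:
        sub = tractogram.subset(sel)
        starts, ends = sub.endpoints()
        d_start = np.linalg.norm(starts - centroid, axis=1)
        d_end = np.linalg.norm(ends - centroid, axis=1)
        far = np.where(d_end[:, None] >= d_start[:, None], ends, starts)
        far_labels = parcellation.sample(far, outside=0)
        inv = {v: k for k, v in region_labels.items()}
        for lab in far_labels:
            name = inv.get(int(lab))
            if name is not None:
                raw[name] += 1
    table = pd.DataFrame(
        {
            "region": names,
            "label": [region_labels[n] for n in names],
            "raw_count": [raw[n] for n in names],
            "normalized_count": [
                raw[n] / (n_total * voxcounts[n]) if voxcounts[n] else 0.0
                for n in names
            ],
        }
    )
    return RegionalProfile(table, n_total, flagged=False)


def profile_outcome_association(
    profiles: list[RegionalProfile], outcomes
) -> pd.DataFrame:
    """Pearson r and two-sided p between per-patient counts and outcomes.

    Regions with zero count variance across patients are flagged with NaN
    statistics rather than dropped.
    """
    outcomes = np.asarray(outcomes, dtype=float)
    if len(profiles) != len(outcomes):
        raise ValueError("one profile per outcome required")
    if len(profiles) < 3:
        raise ValueError("need >= 3 patients")
    regions = list(profiles[0].table["region"])
    rows = []
    for region in regions:
        counts = np.array([p.raw(region) for p in profiles], dtype=float)
        if np.ptp(counts) == 0 or np.ptp(outcomes) == 0:
            rows.append(
                {"region": region, "r": np.nan, "p": np.nan, "flagged": True}
            )
            continue
        res = _stats.pearson_regression(counts, outcomes)
        rows.append(
            {"region": region, "r": res.r, "p": res.p, "flagged": False}
        )
    return pd.DataFrame(rows)


def bundle_atlas_overlap(
    tractogram: Tractogram,
    atlas: LabelVolume,
    atlas_labels: dict,
    indices=None,
) -> dict:
    """Fraction of selected streamline points inside each atlas label.

    Fractions need not sum to 1 (points may fall outside every label).  An
    empty selection returns all-zero fractions with ``"flagged": True``.
    """
    if indices is not None:
        tractogram = tractogram.subset(indices)
    out = {name: 0.0 for name in atlas_labels}
    if len(tractogram) == 0:
        out["flagged"] = True
        return out
    pts = tractogram.all_points()
    sampled = atlas.sample(pts, outside=0)
    total = len(pts)
    for name, label in atlas_labels.items():
        out[name] = float(np.count_nonzero(sampled == label)) / total
    out["flagged"] = False
    return out
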