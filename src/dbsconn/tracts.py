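"""Streamline container, TRK I/O, and arc-length resampling.

Streamlines are ordered polylines in world RAS millimetres.  Files are
written as TrackVis ``.trk`` through nibabel with an identity
voxel-to-RAS mapping, so points round-trip in world mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from nibabel import streamlines as nibs

__all__ = ["Tractogram", "resample_streamline"]


@dataclass
class Tractogram:
    """A set of streamlines with optional per-streamline integer labels."""

    streamlines: list  # of (m_i, 3) float arrays, m_i >= 2
    labels: np.ndarray | None = None
    scalars: dict = field(default_factory=dict)  # per-streamline float vectors

    def __post_init__(self) -> None:
        sls = []
        for s in self.streamlines:
            a = np.asarray(s, dtype=np.float32)
            if a.ndim != 2 or a.shape[1] != 3 or a.shape[0] < 2:
                raise ValueError("each streamline needs >= 2 finite 3-D points")
            if not np.all(np.isfinite(a)):
                raise ValueError("streamline contains non-finite points")
            sls.append(a)
        self.streamlines = sls
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != len(sls):
                raise ValueError("labels must cover every streamline exactly once")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def __getitem__(self, i) -> np.ndarray:
        return self.streamlines[i]

    def subset(self, indices) -> "Tractogram":
        indices = np.asarray(indices, dtype=int)
        return Tractogram(
            [self.streamlines[i] for i in indices],
            labels=None if self.labels is None else self.labels[indices],
            scalars={k: np.asarray(v)[indices] for k, v in self.scalars.items()},
        )

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """(n, 3) arrays of start and end points."""
        starts = np.array([s[0] for s in self.streamlines])
        ends = np.array([s[-1] for s in self.streamlines])
        return starts, ends

    def all_points(self) -> np.ndarray:
        return np.concatenate(self.streamlines, axis=0)

    # -- I/O ---------------------------------------------------------------

    def save_trk(self, path, grid_shape=(80, 80, 80), voxel_size=1.0) -> None:
        data_per_streamline = {}
        if self.labels is not None:
            data_per_streamline["bundle"] = self.labels.reshape(-1, 1).astype(
                np.float32
            )
        for key, vec in self.scalars.items():
            data_per_streamline[key] = np.asarray(vec).reshape(-1, 1).astype(
                np.float32
            )
        tg = nibs.Tractogram(
            self.streamlines,
            data_per_streamline=data_per_streamline,
            affine_to_rasmm=np.eye(4),
        )
        hdr = {
            "voxel_sizes": (voxel_size,) * 3,
            "dimensions": tuple(int(d) for d in grid_shape),
            "voxel_to_rasmm": np.eye(4),
            "voxel_order": "RAS",
        }
        nibs.save(nibs.trk.TrkFile(tg, header=hdr), str(path))

    @classmethod
    def load_trk(cls, path) -> "Tractogram":
        trk = nibs.load(str(path))
        tg = trk.tractogram
        labels = None
        scalars = {}
        for key in tg.data_per_streamline.keys():
            vec = np.asarray(tg.data_per_streamline[key]).ravel()
            if key == "bundle":
                labels = vec.astype(int)
            else:
                scalars[key] = vec
        return cls(list(tg.streamlines), labels=labels, scalars=scalars)


def resample_streamline(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline to uniform spacing <= ``step`` mm.

    Keeps both endpoints exactly; intermediate vertices are placed by linear
    interpolation along cumulative arc length.
    """
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return pts[[0, -1]].copy()
    n_new = max(2, int(np.ceil(total / step)) + 1)
    t = np.linspace(0.0, total, n_new)
    return np.column_stack([np.interp(t, arc, pts[:, k]) for k in range(3)])
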