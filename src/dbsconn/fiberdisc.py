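"""Discriminative fibertract analysis.

Every streamline is scored by a mass-univariate two-sample t statistic
contrasting the clinical improvement of patients whose (unioned bilateral)
VTA the streamline traverses against the improvement of patients it misses.
Positive t marks fibers predominantly connected to responders.  Only the top
fraction (default 10 %) of defined scores, ranked by signed t, is retained;
no multiple-testing correction is applied — the procedure is descriptive
top-k selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structconn import connected_fibers
from .tracts import Tractogram

__all__ = [
    "ConnectivityMatrix",
    "ScoreVector",
    "connectivity_matrix",
    "fiber_tscores",
    "top_fraction",
    "recovery_metrics",
]


@dataclass
class ConnectivityMatrix:
    """Binary streamlines x patients matrix; entry 1 iff fiber crosses the VTA."""

    data: np.ndarray  # (n_streamlines, n_patients) of {0, 1}
    patient_ids: list
    flagged_patients: list  # patients whose VTA was empty (all-zero column)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("connectivity matrix must be 2-D")
        if not np.isin(self.data, (0, 1)).all():
            raise ValueError("entries must be binary")
        if self.data.shape[1] != len(self.patient_ids):
            raise ValueError("column count must equal cohort size")


@dataclass
class ScoreVector:
    """Per-streamline discriminative t; NaN where the score is undefined."""

    t: np.ndarray
    n_connected: np.ndarray
    n_unconnected: np.ndarray
    min_per_group: int

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.t)

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "streamline_id": np.arange(len(self.t)),
                "t": self.t,
                "n_connected": self.n_connected,
                "n_unconnected": self.n_unconnected,
            }
        )


def connectivity_matrix(
    tractogram: Tractogram,
    vtas: dict,
    step: float | None = None,
    dilation_mm: float = 0.0,
) -> ConnectivityMatrix:
    """Build the fiber x patient traversal matrix.

    ``vtas`` maps patient id -> (unioned bilateral) VTA mask.  A patient with
    an empty VTA contributes an all-zero column and is flagged.
    """
    if len(vtas) < 1:
        raise ValueError("need at least one patient VTA")
    patient_ids = list(vtas)
    M = np.zeros((len(tractogram), len(patient_ids)), dtype=np.int8)
    flagged = []
    for j, pid in enumerate(patient_ids):
        mask = vtas[pid]
        data = mask.mask.data if hasattr(mask, "mask") else mask.data
        if not np.asarray(data).any():
            flagged.append(pid)
            continue
        sel = connected_fibers(tractogram, mask, step=step, dilation_mm=dilation_mm)
        M[sel, j] = 1
    return ConnectivityMatrix(M, patient_ids, flagged)


def fiber_tscores(
    M: ConnectivityMatrix | np.ndarray,
    outcomes,
    min_per_group: int = 2,
    equal_var: bool = True,
) -> ScoreVector:
    """Pooled-variance two-sample t per streamline (Welch via equal_var=False).

    ``t = (mean_connected - mean_unconnected) / (s_p * sqrt(1/n1 + 1/n2))``.
    A score is undefined (NaN, excluded from ranking) when either group has
    fewer than ``min_per_group`` patients or the pooled variance is zero.
    """
    data = M.data if isinstance(M, ConnectivityMatrix) else np.asarray(M)
    y = np.asarray(outcomes, dtype=float)
    if data.shape[1] != len(y):
        raise ValueError("outcomes length must equal patient count")
    conn = data.astype(float)
    unconn = 1.0 - conn
    n1 = conn.sum(axis=1)
    n2 = unconn.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sum1 = conn @ y
        sum2 = unconn @ y
        mean1 = sum1 / n1
        mean2 = sum2 / n2
        ss1 = conn @ (y**2) - n1 * mean1**2
        ss2 = unconn @ (y**2) - n2 * mean2**2
        if equal_var:
            sp2 = (ss1 + ss2) / (n1 + n2 - 2)
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        else:
            v1 = ss1 / (n1 - 1)
            v2 = ss2 / (n2 - 1)
            se = np.sqrt(v1 / n1 + v2 / n2)
        t = (mean1 - mean2) / se
    bad = (n1 < min_per_group) | (n2 < min_per_group) | ~np.isfinite(t)
    t = np.where(bad, np.nan, t)
    return ScoreVector(
        t=t,
        n_connected=n1.astype(int),
        n_unconnected=n2.astype(int),
        min_per_group=min_per_group,
    )


def top_fraction(
    scores: ScoreVector,
    fraction: float = 0.10,
    mode: str = "signed",
) -> np.ndarray:
    """Indices of the top ``floor(fraction * n_defined)`` streamlines.

    Ranking is by signed t descending (positive = connected to responders);
    ``mode="abs"`` ranks by |t| instead.  Ties break toward the lower
    streamline index.  Undefined scores are excluded from the pool, not
    bottom-ranked.  With no defined scores the selection is empty.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if mode not in ("signed", "abs"):
        raise ValueError("mode must be 'signed' or 'abs'")
    defined = np.flatnonzero(scores.defined)
    if defined.size == 0:
        return np.array([], dtype=int)
    key = scores.t[defined]
    if mode == "abs":
        key = np.abs(key)
    # sort by (-t, index): descending score, ties to the lower index
    order = np.lexsort((defined, -key))
    k = int(np.floor(fraction * defined.size))
    return defined[order[:k]]


def recovery_metrics(selected, truth) -> dict:
    """Precision/recall of a selection against the planted bundle.

    ``truth`` is a phantom GroundTruth (or any object with ``bundle_indices``).
    An empty selection has undefined precision (NaN, flagged).
    """
    selected = np.asarray(selected, dtype=int)
    bundle = set(int(i) for i in truth.bundle_indices)
    n_bundle = len(bundle)
    hits = sum(1 for i in selected if int(i) in bundle)
    precision = hits / len(selected) if len(selected) else float("nan")
    recall = hits / n_bundle if n_bundle else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "n_selected": int(len(selected)),
        "n_bundle": int(n_bundle),
        "flagged": len(selected) == 0,
    }
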