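"""Synthetic brain phantom: volumes, tractograms, cohorts, normative fMRI.

The phantom is a spherical "head" generated directly in a common RAS-mm world
space (no registration stage exists).  It carries:

* a three-class tissue map (0 CSF/background, 1 grey, 2 white),
* bilateral centromedian (CM) and parafascicular (Pf) nucleus spheres centred
  on the stereotactic target (+/-9, -9, 0) mm,
* a six-region cortical/subcortical parcellation (brainstem/cerebellum and
  five frontal/sensorimotor bands),
* a whole-brain tractogram with a planted thalamo-brainstem-sensorimotor
  bundle plus distractor curves,
* a synthetic patient cohort whose seizure-frequency improvement is a linear
  function of planted VTA-bundle connectivity,
* a normative resting-state fMRI cohort with a planted seed-coupled network.

Every generator draws from a named PRNG substream derived from the master
seed, so adding one generator never perturbs another's output and identical
spec + seed give bit-identical results.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .electrode import LeadPlacement, StimConfig, build_lead
from .tracts import Tractogram
from .volumes import LabelVolume, make_affine, sphere_mask
from .vta import analytic_vta_radius_mm

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "Cohort",
    "GeometryError",
    "SpecError",
    "DEFAULT_REGION_LABELS",
    "NUCLEUS_LABELS",
    "TIMEPOINTS",
    "make_head_phantom",
    "make_tractogram",
    "make_cohort",
    "make_normative_fmri",
    "iter_normative_fmri",
    "network_masks",
    "seed_for",
]


class GeometryError(ValueError):
    """Phantom geometry is inconsistent (e.g. sphere outside the grid)."""


class SpecError(ValueError):
    """Phantom specification is invalid (e.g. duplicate labels)."""


NUCLEUS_LABELS = {"cm_right": 1, "cm_left": 2, "pf_right": 3, "pf_left": 4}

DEFAULT_REGION_LABELS = {
    "brainstem_cerebellum": 10,
    "postcentral": 11,
    "precentral": 12,
    "SMA": 13,
    "middle_frontal": 14,
    "superior_frontal": 15,
}

# world-mm boxes (x, y, z ranges); each region is box AND brain mask
_REGION_BOXES = {
    "brainstem_cerebellum": ((-14.0, 14.0), (-30.0, 2.0), (-33.0, -18.0)),
    "postcentral": ((-28.0, 28.0), (-26.0, -14.0), (16.0, 30.0)),
    "precentral": ((-28.0, 28.0), (-14.0, -2.0), (16.0, 30.0)),
    "SMA": ((-28.0, 28.0), (-2.0, 8.0), (16.0, 30.0)),
    "middle_frontal": ((-28.0, 28.0), (8.0, 20.0), (16.0, 30.0)),
    "superior_frontal": ((-28.0, 28.0), (20.0, 34.0), (16.0, 30.0)),
}

_BUNDLE_END_REGIONS = ("precentral", "postcentral", "SMA")

TIMEPOINTS = ("baseline", "3mo", "6mo", "12mo", "18mo", "24mo", "last")
PRIMARY_TIMEPOINT = "24mo"
# fraction of the stationary improvement reached at each follow-up visit
_RAMP = {
    "baseline": 0.0,
    "3mo": 0.45,
    "6mo": 0.85,
    "12mo": 0.95,
    "18mo": 1.0,
    "24mo": 1.0,
    "last": 0.95,
}


def seed_for(master_seed: int, name: str) -> np.random.SeedSequence:
    """Named PRNG substream derived from the master seed."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and labelling of the synthetic head.

    ``target`` is the right-hemisphere stereotactic target; the left target
    mirrors x.  ``nucleus_radii`` holds the (CM, Pf) sphere radii in mm.
    """

    grid_shape: tuple[int, int, int] = (80, 80, 80)
    voxel_size: float = 1.0
    target: tuple[float, float, float] = (9.0, -9.0, 0.0)
    nucleus_radii: tuple[float, float] = (2.0, 1.5)
    region_labels: dict = field(
        default_factory=lambda: dict(DEFAULT_REGION_LABELS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.grid_shape):
            raise SpecError("grid_shape must be positive")
        if self.voxel_size <= 0:
            raise SpecError("voxel_size must be positive")
        cm_r, pf_r = self.nucleus_radii
        if cm_r <= 0 or pf_r <= 0:
            raise GeometryError("nucleus radii must be positive (empty nucleus)")
        labels = list(self.region_labels.values())
        if len(set(labels)) != len(labels) or any(v == 0 for v in labels):
            raise SpecError("region labels must be unique and nonzero")
        if set(self.region_labels) != set(DEFAULT_REGION_LABELS):
            raise SpecError(
                f"region_labels must name exactly {sorted(DEFAULT_REGION_LABELS)}"
            )
        lo, hi = self.world_bounds
        for center, radius in self.nucleus_spheres().values():
            c = np.asarray(center)
            if np.any(c - radius < lo) or np.any(c + radius > hi):
                raise GeometryError(f"nucleus sphere at {center} outside grid")

    # -- derived geometry --------------------------------------------------

    @property
    def affine(self) -> np.ndarray:
        return make_affine(self.grid_shape, self.voxel_size)

    @property
    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lo, hi) world coordinates of the extreme voxel centres."""
        lo = self.affine[:3, 3]
        hi = lo + (np.asarray(self.grid_shape) - 1) * self.voxel_size
        return lo, hi

    @property
    def brain_radius(self) -> float:
        """Radius of the spherical brain, leaving a CSF margin to the grid edge."""
        return self.voxel_size * min(self.grid_shape) / 2.0 - 6.0

    def targets(self) -> dict:
        t = np.asarray(self.target, dtype=float)
        return {"right": t, "left": t * np.array([-1.0, 1.0, 1.0])}

    def nucleus_spheres(self) -> dict:
        """name -> (centre, radius) for the four nucleus spheres."""
        cm_r, pf_r = self.nucleus_radii
        tx, ty, tz = self.target
        out = {}
        for hemi, sign in (("right", 1.0), ("left", -1.0)):
            out[f"cm_{hemi}"] = (np.array([sign * tx, ty, tz]), cm_r)
            out[f"pf_{hemi}"] = (np.array([sign * (tx - 3.5), ty - 1.0, tz]), pf_r)
        return out

    def template(self) -> LabelVolume:
        return LabelVolume(np.zeros(self.grid_shape, dtype=np.int16), self.affine)


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery testing."""

    bundle_labels: np.ndarray  # 0 = distractor, k > 0 = planted bundle id
    true_effect: float = 0.0  # improvement units per connected bundle fiber
    noise_sd: float = 0.0  # improvement units
    planted_connectivity: np.ndarray | None = None  # per-patient fiber count

    def __post_init__(self) -> None:
        self.bundle_labels = np.asarray(self.bundle_labels, dtype=int)
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be >= 0")

    @property
    def bundle_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bundle_labels > 0)

    def to_json(self, path) -> None:
        payload = {
            "bundle_labels": self.bundle_labels.tolist(),
            "true_effect": self.true_effect,
            "noise_sd": self.noise_sd,
            "planted_connectivity": (
                None
                if self.planted_connectivity is None
                else np.asarray(self.planted_connectivity).tolist()
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        pc = payload["planted_connectivity"]
        return cls(
            bundle_labels=np.asarray(payload["bundle_labels"], dtype=int),
            true_effect=payload["true_effect"],
            noise_sd=payload["noise_sd"],
            planted_connectivity=None if pc is None else np.asarray(pc, float),
        )


# ---------------------------------------------------------------------------
# head volumes
# ---------------------------------------------------------------------------


def make_head_phantom(spec: PhantomSpec):
    """Generate (tissue, nuclei, parcellation) on the spec grid.

    The brain is a sphere; grey matter is the outer 20 % shell plus the
    nucleus spheres, white matter fills the core, everything else is
    CSF/background.  Regions are world-space boxes intersected with the brain.
    """
    template = spec.template()
    lo = spec.affine[:3, 3]
    h = spec.voxel_size
    xs = lo[0] + np.arange(spec.grid_shape[0]) * h
    ys = lo[1] + np.arange(spec.grid_shape[1]) * h
    zs = lo[2] + np.arange(spec.grid_shape[2]) * h
    r2 = (
        xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2
    )
    R = spec.brain_radius
    brain = r2 <= R**2
    wm = r2 <= (0.8 * R) ** 2

    tissue = np.zeros(spec.grid_shape, dtype=np.int16)
    tissue[brain] = 1  # GM shell
    tissue[wm] = 2

    nuclei = np.zeros(spec.grid_shape, dtype=np.int16)
    for name, (center, radius) in spec.nucleus_spheres().items():
        mask = sphere_mask(template, center, radius)
        if not mask.any():
            raise GeometryError(f"nucleus {name} contains no voxels at this grid")
        nuclei[mask] = NUCLEUS_LABELS[name]
        tissue[mask] = 1  # deep grey

    parc = np.zeros(spec.grid_shape, dtype=np.int16)
    for name, label in spec.region_labels.items():
        (x0, x1), (y0, y1), (z0, z1) = _REGION_BOXES[name]
        box = (
            (xs >= x0)[:, None, None]
            & (xs <= x1)[:, None, None]
            & (ys >= y0)[None, :, None]
            & (ys <= y1)[None, :, None]
            & (zs >= z0)[None, None, :]
            & (zs <= z1)[None, None, :]
        )
        parc[box & brain] = label

    aff = spec.affine
    return (
        LabelVolume(tissue, aff),
        LabelVolume(nuclei, aff),
        LabelVolume(parc, aff),
    )


# ---------------------------------------------------------------------------
# tractogram
# ---------------------------------------------------------------------------

_N_POINTS = 49  # 3 Catmull-Rom segments x 16 samples + 1; knots land on-grid


@lru_cache(maxsize=4)
def _catmull_rom_basis(n_samples: int = _N_POINTS) -> np.ndarray:
    """(n_samples, 4) matrix mapping 4 control points to curve samples.

    Uniform Catmull-Rom through the controls with duplicated end controls, so
    the curve interpolates all four control points; sample parameters include
    the knots.
    """
    n_seg = 3
    ts = np.linspace(0.0, n_seg, n_samples)
    B = np.zeros((n_samples, 4))
    # padded control index sequence: [0, 0, 1, 2, 3, 3]
    padded = [0, 0, 1, 2, 3, 3]
    for i, t in enumerate(ts):
        s = min(int(np.floor(t)), n_seg - 1)
        u = t - s
        w = np.array(
            [
                0.5 * (-u + 2 * u**2 - u**3),
                0.5 * (2 - 5 * u**2 + 3 * u**3),
                0.5 * (u + 4 * u**2 - 3 * u**3),
                0.5 * (-(u**2) + u**3),
            ]
        )
        for j in range(4):
            B[i, padded[s + j]] += w[j]
    return B


def _eval_curves(controls: np.ndarray) -> np.ndarray:
    """(n, 4, 3) control points -> (n, _N_POINTS, 3) curves."""
    B = _catmull_rom_basis()
    return np.einsum("sk,nkd->nsd", B, controls)


def _truncated_normal(rng, sd: float, trunc: float, size: int) -> np.ndarray:
    """(size, 3) isotropic Gaussian offsets with norm <= trunc."""
    out = np.empty((size, 3))
    need = np.arange(size)
    while need.size:
        draw = rng.normal(0.0, sd, size=(need.size, 3))
        ok = np.linalg.norm(draw, axis=1) <= trunc
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def _uniform_ball(rng, r_lo: float, r_hi: float, size: int) -> np.ndarray:
    """Uniform points in the spherical shell [r_lo, r_hi]."""
    d = rng.normal(size=(size, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    u = rng.uniform(size=size)
    r = (r_lo**3 + u * (r_hi**3 - r_lo**3)) ** (1.0 / 3.0)
    return d * r[:, None]


def _min_nucleus_clearance(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Per-curve minimum of (distance to nucleus centre - nucleus radius)."""
    clear = np.full(points.shape[0], np.inf)
    for center, radius in spec.nucleus_spheres().values():
        d = np.linalg.norm(points - center[None, None, :], axis=2)
        clear = np.minimum(clear, d.min(axis=1) - radius)
    return clear


def _sample_bundle_controls(
    rng,
    spec: PhantomSpec,
    n: int,
    spread_sd: float,
    spread_trunc: float,
    offset: tuple[float, float, float],
) -> np.ndarray:
    targets = spec.targets()
    R = spec.brain_radius
    hemi = rng.choice((-1.0, 1.0), size=n)
    # brainstem origin, deep and inferior, kept inside the brain sphere
    p0 = np.empty((n, 3))
    need = np.arange(n)
    while need.size:
        k = need.size
        cand = np.column_stack(
            [
                hemi[need] * rng.uniform(1.0, 8.0, k),
                rng.uniform(-16.0, -6.0, k),
                rng.uniform(-30.0, -26.0, k),
            ]
        )
        ok = np.linalg.norm(cand, axis=1) <= R - 1.5
        p0[need[ok]] = cand[ok]
        need = need[~ok]
    # thalamic waypoint: corridor centre (target + mirrored offset) plus
    # truncated Gaussian scatter
    off = np.asarray(offset, dtype=float)
    base = np.where(
        hemi[:, None] > 0,
        (targets["right"] + off)[None, :],
        (targets["left"] + off * np.array([-1.0, 1.0, 1.0]))[None, :],
    )
    p1 = base + _truncated_normal(rng, spread_sd, spread_trunc, n)
    # cortical terminal in a sensorimotor region, kept inside the brain
    region = rng.integers(0, len(_BUNDLE_END_REGIONS), size=n)
    p3 = np.empty((n, 3))
    need = np.arange(n)
    while need.size:
        k = need.size
        ybounds = np.array(
            [_REGION_BOXES[_BUNDLE_END_REGIONS[r]][1] for r in region[need]]
        )
        cand = np.column_stack(
            [
                hemi[need] * rng.uniform(2.0, 14.0, k),
                rng.uniform(ybounds[:, 0] + 1.0, ybounds[:, 1] - 1.0),
                rng.uniform(17.0, 22.0, k),
            ]
        )
        ok = np.linalg.norm(cand, axis=1) <= R - 1.5
        p3[need[ok]] = cand[ok]
        need = need[~ok]
    p2 = 0.6 * p1 + 0.4 * p3 + rng.normal(0.0, 1.5, size=(n, 3))
    return np.stack([p0, p1, p2, p3], axis=1)


def _sample_distractor_controls(
    rng, spec: PhantomSpec, n: int, near: np.ndarray, shell: tuple[float, float]
) -> np.ndarray:
    """Control points for distractors; ``near`` marks near-miss corridor curves."""
    R = spec.brain_radius
    targets = spec.targets()
    p0 = _uniform_ball(rng, 0.35 * R, 0.9 * R, n)
    p3 = _uniform_ball(rng, 0.35 * R, 0.9 * R, n)
    mid = _uniform_ball(rng, 0.0, 0.6 * R, 2 * n).reshape(n, 2, 3)
    controls = np.stack([p0, mid[:, 0], mid[:, 1], p3], axis=1)
    # near-miss curves get a waypoint in a shell around a random target
    idx = np.flatnonzero(near)
    if idx.size:
        hemi = rng.choice(("right", "left"), size=idx.size)
        base = np.array([targets[hname] for hname in hemi])
        d = rng.normal(size=(idx.size, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        r = rng.uniform(shell[0], shell[1], size=idx.size)
        controls[idx, 1] = base + d * r[:, None]
        controls[idx, 2] = 0.5 * (controls[idx, 1] + controls[idx, 3])
    return controls


def make_tractogram(
    spec: PhantomSpec,
    n_streamlines: int = 200_000,
    bundle_fraction: float = 0.10,
    bundle_spread_sd: float = 2.8,
    bundle_spread_trunc: float = 4.5,
    bundle_offset: tuple[float, float, float] = (-3.0, -0.5, 0.0),
    near_miss_fraction: float = 0.05,
    near_miss_shell: tuple[float, float] = (4.0, 6.5),
    exclusion_mm: float = 1.0,
) -> tuple[Tractogram, GroundTruth]:
    """Whole-brain synthetic tractogram with a planted discriminative bundle.

    ``round(bundle_fraction * n)`` streamlines form the planted bundle: smooth
    curves from the brainstem through a thalamic waypoint scattered around the
    stimulation target (truncated Gaussian, sd ``bundle_spread_sd``, cut at
    ``bundle_spread_trunc``) and on to a sensorimotor cortical region.  The
    remainder are distractor curves that never come within ``exclusion_mm`` of
    a nucleus sphere; a ``near_miss_fraction`` of them are routed through a
    3.2-6 mm shell around a target to emulate fiber-dense thalamic
    surroundings without touching the nuclei.
    """
    if n_streamlines < 1:
        raise ValueError("n_streamlines must be >= 1")
    if not 0.0 <= bundle_fraction <= 1.0:
        raise ValueError("bundle_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed_for(spec.seed, "tractogram"))
    n_bundle = int(round(bundle_fraction * n_streamlines))
    n_dist = n_streamlines - n_bundle

    curves = np.empty((n_streamlines, _N_POINTS, 3), dtype=np.float64)
    if n_bundle:
        controls = _sample_bundle_controls(
            rng, spec, n_bundle, bundle_spread_sd, bundle_spread_trunc,
            bundle_offset,
        )
        curves[:n_bundle] = _eval_curves(controls)

    cm_r = spec.nucleus_radii[0]
    shell = (max(near_miss_shell[0], cm_r + exclusion_mm + 0.2), near_miss_shell[1])
    if n_dist:
        near = rng.uniform(size=n_dist) < near_miss_fraction
        pending = np.arange(n_bundle, n_streamlines)
        pending_near = near.copy()
        while pending.size:
            controls = _sample_distractor_controls(
                rng, spec, pending.size, pending_near, shell
            )
            cand = _eval_curves(controls)
            ok = _min_nucleus_clearance(cand, spec) >= exclusion_mm
            curves[pending[ok]] = cand[ok]
            pending = pending[~ok]
            pending_near = pending_near[~ok]

    lo, hi = spec.world_bounds
    np.clip(curves, lo[None, None, :], hi[None, None, :], out=curves)

    labels = np.zeros(n_streamlines, dtype=int)
    labels[:n_bundle] = 1
    curves32 = curves.astype(np.float32)
    tractogram = Tractogram(list(curves32), labels=labels)
    return tractogram, GroundTruth(bundle_labels=labels)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Per-patient lead placements, stimulation settings, and outcomes."""

    placements: pd.DataFrame  # one row per (patient, hemisphere)
    outcomes: pd.DataFrame  # index patient_id, columns improvement_pct_<tp>
    lead_name: str = "medtronic3389"

    @property
    def patient_ids(self) -> list:
        return list(self.outcomes.index)

    @property
    def n_patients(self) -> int:
        return len(self.outcomes)

    def placement_for(self, patient_id, hemisphere: str) -> LeadPlacement:
        row = self.placements[
            (self.placements.patient_id == patient_id)
            & (self.placements.hemisphere == hemisphere)
        ].iloc[0]
        return LeadPlacement(
            tip=(row.tip_x, row.tip_y, row.tip_z),
            direction=(row.dir_x, row.dir_y, row.dir_z),
            hemisphere=hemisphere,
        )

    def stim_for(self, patient_id, hemisphere: str) -> StimConfig:
        row = self.placements[
            (self.placements.patient_id == patient_id)
            & (self.placements.hemisphere == hemisphere)
        ].iloc[0]
        contacts = tuple(
            int(c.lstrip("C")) for c in str(row.active_contacts).split("+")
        )
        return StimConfig(
            active_contacts=contacts,
            amplitude_v=float(row.amplitude_V),
            frequency_hz=float(row.frequency_Hz),
            pulse_width_us=float(row.pulse_us),
        )

    def outcome(self, timepoint: str = PRIMARY_TIMEPOINT) -> pd.Series:
        return self.outcomes[f"improvement_pct_{timepoint}"]

    def outcome_matrix(self) -> pd.DataFrame:
        """Patients x timepoints improvement table for the stats module."""
        cols = [f"improvement_pct_{tp}" for tp in TIMEPOINTS]
        mat = self.outcomes[cols].copy()
        mat.columns = list(TIMEPOINTS)
        return mat

    def to_csv(self, path) -> None:
        merged = self.placements.merge(
            self.outcomes.reset_index(), on="patient_id", how="left"
        )
        merged.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, lead_name: str = "medtronic3389") -> "Cohort":
        merged = pd.read_csv(path)
        out_cols = [c for c in merged.columns if c.startswith("improvement_pct_")]
        placements = merged.drop(columns=out_cols)
        outcomes = (
            merged[["patient_id"] + out_cols]
            .drop_duplicates("patient_id")
            .set_index("patient_id")
        )
        return cls(placements=placements, outcomes=outcomes, lead_name=lead_name)


def make_cohort(
    spec: PhantomSpec,
    tractogram: Tractogram,
    truth: GroundTruth,
    n_patients: int = 10,
    jitter_sd: float = 1.5,
    jitter_trunc: float = 3.0,
    effect: float = 5.0,
    noise_sd: float = 5.0,
    amplitudes=(1.0, 2.0, 3.0, 4.0, 5.0),
    sigma: float = 0.33,
    threshold: float = 0.2,
    impedance_ohm: float = 1000.0,
    lead_name: str = "medtronic3389",
) -> tuple[Cohort, GroundTruth]:
    """Synthetic DBS cohort whose outcome tracks planted VTA-bundle connectivity.

    Each patient receives bilateral leads at the mirrored targets plus
    truncated Gaussian placement jitter, one random active contact, and an
    amplitude drawn from ``amplitudes`` at 60 Hz / 90 us.  The planted
    connectivity is the number of bundle streamlines with a vertex inside the
    patient's bilateral analytic VTA spheres; the stationary improvement is
    ``effect * connectivity + N(0, noise_sd^2)`` truncated to [-100, 100] and
    rolled out over follow-up visits by a fixed saturation ramp.
    """
    if n_patients < 3:
        raise SpecError("n_patients must be >= 3")
    rng = np.random.default_rng(seed_for(spec.seed, "cohort"))
    lead = build_lead(lead_name)
    targets = spec.targets()

    bundle_idx = truth.bundle_indices
    bundle_pts = (
        np.stack([tractogram[i] for i in bundle_idx], axis=0).astype(float)
        if bundle_idx.size
        else np.zeros((0, 2, 3))
    )

    rows = []
    connectivity = np.zeros(n_patients)
    improvements = np.zeros(n_patients)
    for p in range(n_patients):
        amp = float(rng.choice(amplitudes))
        contact = int(rng.integers(0, lead.n_contacts))
        r_vta = analytic_vta_radius_mm(amp, sigma, threshold, impedance_ohm)
        hit = np.zeros(len(bundle_idx), dtype=bool)
        for hemi in ("right", "left"):
            delta = _truncated_normal(rng, jitter_sd, jitter_trunc, 1)[0]
            center = targets[hemi] + delta
            tip = center - lead.contact_offsets_mm()[contact] * np.array(
                [0.0, 0.0, 1.0]
            )
            rows.append(
                {
                    "patient_id": f"P{p:02d}",
                    "hemisphere": hemi,
                    "tip_x": tip[0],
                    "tip_y": tip[1],
                    "tip_z": tip[2],
                    "dir_x": 0.0,
                    "dir_y": 0.0,
                    "dir_z": 1.0,
                    "active_contacts": f"C{contact}",
                    "amplitude_V": amp,
                    "frequency_Hz": 60.0,
                    "pulse_us": 90.0,
                }
            )
            if len(bundle_idx):
                d2 = np.sum((bundle_pts - center[None, None, :]) ** 2, axis=2)
                hit |= (d2 <= r_vta**2).any(axis=1)
        connectivity[p] = hit.sum()
        improvements[p] = np.clip(
            effect * connectivity[p] + rng.normal(0.0, noise_sd), -100.0, 100.0
        )

    out = {}
    for tp in TIMEPOINTS:
        ramp = _RAMP[tp]
        if tp in ("baseline", PRIMARY_TIMEPOINT):
            vals = ramp * improvements
        else:
            vals = ramp * improvements + rng.normal(
                0.0, noise_sd / 2.0, size=n_patients
            )
        out[f"improvement_pct_{tp}"] = np.clip(vals, -100.0, 100.0)
    outcomes = pd.DataFrame(
        out, index=pd.Index([f"P{p:02d}" for p in range(n_patients)], name="patient_id")
    )
    cohort = Cohort(
        placements=pd.DataFrame(rows), outcomes=outcomes, lead_name=lead_name
    )
    new_truth = GroundTruth(
        bundle_labels=truth.bundle_labels,
        true_effect=effect,
        noise_sd=noise_sd,
        planted_connectivity=connectivity,
    )
    return cohort, new_truth


# ---------------------------------------------------------------------------
# normative fMRI
# ---------------------------------------------------------------------------

_NETWORK_REGIONS = ("brainstem_cerebellum", "precentral", "postcentral", "SMA")
_SEED_REGION_RADIUS_MM = 4.0


def network_masks(spec: PhantomSpec) -> dict:
    """Ground-truth masks of the planted functional network on the spec grid."""
    tissue, nuclei, parc = make_head_phantom(spec)
    template = spec.template()
    seed_core = np.zeros(spec.grid_shape, dtype=bool)
    for t in spec.targets().values():
        seed_core |= sphere_mask(template, t, _SEED_REGION_RADIUS_MM)
    network = seed_core.copy()
    for name in _NETWORK_REGIONS:
        network |= parc.data == spec.region_labels[name]
    return {
        "seed_core": seed_core,
        "network": network,
        "gm": tissue.data == 1,
        "wm": tissue.data == 2,
        "brain": tissue.data != 0,
        "tissue": tissue,
        "parcellation": parc,
    }


def _ar1(rng, shape, phi: float) -> np.ndarray:
    """Stationary unit-variance AR(1) noise along the last axis."""
    w = rng.normal(size=shape)
    out = np.empty(shape)
    out[..., 0] = w[..., 0]
    s = np.sqrt(1.0 - phi**2)
    for t in range(1, shape[-1]):
        out[..., t] = phi * out[..., t - 1] + s * w[..., t]
    return out


def _loading_map(spec: PhantomSpec, coupling: float, global_frac: float,
                 seed_sigma: float) -> np.ndarray:
    masks = network_masks(spec)
    a = np.zeros(spec.grid_shape)
    a[masks["gm"]] = global_frac * coupling
    a[masks["network"]] = coupling
    a[masks["seed_core"]] = np.sqrt(1.0 - seed_sigma**2) * np.sign(coupling or 1.0)
    return a


def iter_normative_fmri(
    spec: PhantomSpec,
    n_subjects: int = 20,
    n_timepoints: int = 124,
    tr: float = 3.0,
    coupling: float = 0.6,
    ar_phi: float = 0.3,
    global_frac: float = 0.15,
    seed_sigma: float = 0.1,
):
    """Yield synthetic resting-state subjects one at a time (memory-friendly).

    Voxel series are AR(1) noise plus a shared AR(1) latent signal loaded onto
    the planted network (seed neighbourhood, brainstem/cerebellum and
    sensorimotor labels) with loading ``coupling``; other grey-matter voxels
    carry a weak global loading ``global_frac * coupling``; white matter, CSF
    and background are pure noise.  With matching signal/noise spectra the
    expected seed-network correlation is ~``coupling`` and survives band-pass
    filtering.
    """
    from .funcconn import FMRISeries  # local import to avoid a cycle

    if n_timepoints < 20:
        raise ValueError("n_timepoints must be >= 20")
    if not -1.0 < coupling < 1.0:
        raise ValueError("coupling must lie in (-1, 1)")
    a = _loading_map(spec, coupling, global_frac, seed_sigma)
    b = np.sqrt(1.0 - a**2)
    children = seed_for(spec.seed, "fmri").spawn(n_subjects)
    for child in children:
        rng = np.random.default_rng(child)
        u = _ar1(rng, (n_timepoints,), ar_phi)
        eps = _ar1(rng, spec.grid_shape + (n_timepoints,), ar_phi)
        data = 100.0 + 5.0 * (a[..., None] * u[None, None, None, :] + b[..., None] * eps)
        yield FMRISeries(data.astype(np.float32), spec.affine, tr=tr)


def make_normative_fmri(
    spec: PhantomSpec,
    n_subjects: int = 20,
    n_timepoints: int = 124,
    tr: float = 3.0,
    coupling: float = 0.6,
    **kwargs,
) -> list:
    """Materialized list of synthetic normative subjects (see iter_normative_fmri)."""
    return list(
        iter_normative_fmri(
            spec, n_subjects, n_timepoints, tr, coupling, **kwargs
        )
    )
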