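import numpy as np
import pytest
from scipy import ndimage

from dbsconn import phantom
from dbsconn.phantom import (
    GeometryError,
    PhantomSpec,
    SpecError,
    make_cohort,
    make_head_phantom,
    make_normative_fmri,
    make_tractogram,
)
from dbsconn.volumes import LabelVolume


class TestSpec:
    def test_zero_nucleus_radius_rejected(self):
        with pytest.raises(GeometryError):
            PhantomSpec(nucleus_radii=(0.0, 1.5))

    def test_duplicate_region_labels_rejected(self):
        labels = dict(phantom.DEFAULT_REGION_LABELS)
        labels["postcentral"] = labels["precentral"]
        with pytest.raises(SpecError):
            PhantomSpec(region_labels=labels)

    def test_sphere_outside_grid_rejected(self):
        with pytest.raises(GeometryError):
            PhantomSpec(grid_shape=(10, 10, 10))

    def test_targets_mirror_x(self, spec):
        t = spec.targets()
        assert np.allclose(t["right"], (9, -9, 0))
        assert np.allclose(t["left"], (-9, -9, 0))


class TestHeadPhantom:
    def test_cm_centroid_on_target(self, spec, head):
        cm = head["nuclei"].like(
            head["nuclei"].data == phantom.NUCLEUS_LABELS["cm_right"]
        )
        assert np.linalg.norm(cm.centroid_mm() - (9, -9, 0)) <= spec.voxel_size

    def test_volumes_coregistered(self, head):
        assert head["tissue"].shape == head["nuclei"].shape == head["parc"].shape
        assert np.allclose(head["tissue"].affine, head["parc"].affine)

    def test_tissue_codes(self, head):
        assert set(np.unique(head["tissue"].data)) == {0, 1, 2}

    def test_all_regions_present(self, spec, head):
        for name, label in spec.region_labels.items():
            assert (head["parc"].data == label).any(), name

    def test_determinism(self, spec):
        a = make_head_phantom(spec)
        b = make_head_phantom(PhantomSpec(seed=spec.seed))
        for x, y in zip(a, b):
            assert np.array_equal(x.data, y.data)


class TestTractogram:
    def test_bundle_count_forced_by_rounding(self, spec):
        tract, truth = make_tractogram(spec, 10, bundle_fraction=0.5)
        assert len(tract) == 10
        assert truth.bundle_indices.size == 5

    def test_zero_streamlines_rejected(self, spec):
        with pytest.raises(ValueError):
            make_tractogram(spec, 0)

    def test_bundle_has_vertex_in_dilated_cm(self, spec, head, tract_truth):
        """Every planted fiber passes through the CM neighbourhood: a vertex
        falls inside the CM mask dilated to cover the corridor scatter."""
        tract, truth = tract_truth
        cm = np.isin(head["nuclei"].data,
                     [phantom.NUCLEUS_LABELS["cm_right"],
                      phantom.NUCLEUS_LABELS["cm_left"]])
        # corridor offset (3.04 mm) + waypoint truncation (4.5 mm) - CM radius
        dil = ndimage.distance_transform_edt(~cm) <= 5.6
        vol = head["nuclei"].like(dil)
        for i in truth.bundle_indices:
            assert vol.sample(tract[i]).any()

    def test_distractors_avoid_nucleus_neighbourhood(self, spec, tract_truth):
        tract, truth = tract_truth
        distractors = np.flatnonzero(truth.bundle_labels == 0)
        spheres = spec.nucleus_spheres().values()
        pts = np.stack([tract[i] for i in distractors]).astype(float)
        clearance = np.full(len(distractors), np.inf)
        for center, radius in spheres:
            d = np.linalg.norm(pts - center[None, None, :], axis=2).min(axis=1)
            clearance = np.minimum(clearance, d - radius)
        assert clearance.min() >= 1.0 - 1e-6

    def test_geometry_closure(self, spec, tract_truth):
        tract, _ = tract_truth
        lo, hi = spec.world_bounds
        pts = tract.all_points()
        assert np.all(pts >= lo - 1e-5) and np.all(pts <= hi + 1e-5)

    def test_labels_cover_every_streamline(self, tract_truth):
        tract, truth = tract_truth
        assert truth.bundle_labels.shape == (len(tract),)

    def test_determinism(self, spec):
        a, _ = make_tractogram(spec, 50)
        b, _ = make_tractogram(PhantomSpec(seed=spec.seed), 50)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1, s2)


class TestCohort:
    def test_amplitudes_within_protocol(self, cohort_truth):
        cohort, _ = cohort_truth
        assert (cohort.placements["amplitude_V"] <= 5.0).all()
        assert (cohort.placements["amplitude_V"] >= 1.0).all()
        assert (cohort.placements["frequency_Hz"] == 60.0).all()
        assert (cohort.placements["pulse_us"] == 90.0).all()

    def test_noise_free_outcome_tracks_connectivity(self, spec, tract_truth):
        """With zero noise and a small positive effect, improvement rank order
        equals planted-connectivity rank order (monotone map, no truncation)."""
        tract, truth = tract_truth
        cohort, truth2 = make_cohort(spec, tract, truth, effect=1.0, noise_sd=0.0)
        y = cohort.outcome().to_numpy()
        conn = truth2.planted_connectivity
        assert y.max() < 100.0  # truncation not binding at this effect size
        assert np.allclose(y, 1.0 * conn)
        order = np.argsort(conn, kind="stable")
        assert np.all(np.diff(y[order]) >= 0)

    def test_too_few_patients_rejected(self, spec, tract_truth):
        tract, truth = tract_truth
        with pytest.raises(SpecError):
            make_cohort(spec, tract, truth, n_patients=2)

    def test_determinism(self, spec, tract_truth):
        tract, truth = tract_truth
        a, _ = make_cohort(spec, tract, truth)
        b, _ = make_cohort(PhantomSpec(seed=spec.seed), tract, truth)
        assert a.placements.equals(b.placements)
        assert a.outcomes.equals(b.outcomes)

    def test_csv_round_trip(self, tmp_path, cohort_truth):
        cohort, _ = cohort_truth
        path = tmp_path / "cohort.csv"
        cohort.to_csv(path)
        back = phantom.Cohort.from_csv(path)
        assert back.patient_ids == cohort.patient_ids
        assert np.allclose(back.outcomes.to_numpy(), cohort.outcomes.to_numpy())
        p = cohort.placement_for("P00", "right")
        q = back.placement_for("P00", "right")
        assert np.allclose(p.tip, q.tip)

    def test_ground_truth_json_round_trip(self, tmp_path, cohort_truth):
        _, truth = cohort_truth
        path = tmp_path / "truth.json"
        truth.to_json(path)
        back = phantom.GroundTruth.from_json(path)
        assert np.array_equal(back.bundle_labels, truth.bundle_labels)
        assert np.allclose(back.planted_connectivity, truth.planted_connectivity)


@pytest.fixture(scope="module")
def fmri_spec():
    return PhantomSpec(grid_shape=(27, 27, 27), voxel_size=3.0, seed=5)


class TestNormativeFMRI:
    def test_frame_count_default(self, fmri_spec):
        series = make_normative_fmri(fmri_spec, n_subjects=1)
        assert series[0].n_frames == 124
        assert series[0].tr == 3.0

    def test_coupling_out_of_range_rejected(self, fmri_spec):
        with pytest.raises(ValueError):
            make_normative_fmri(fmri_spec, n_subjects=1, coupling=1.0)

    def test_too_few_frames_rejected(self, fmri_spec):
        with pytest.raises(ValueError):
            make_normative_fmri(fmri_spec, n_subjects=1, n_timepoints=10)

    def test_null_coupling_gives_null_correlation(self, fmri_spec):
        from dbsconn import funcconn

        masks = phantom.network_masks(fmri_spec)
        seed_vol = LabelVolume(masks["seed_core"], fmri_spec.affine)
        net = masks["network"] & ~masks["seed_core"]
        rs = []
        for series in phantom.iter_normative_fmri(
            fmri_spec, n_subjects=12, coupling=0.0
        ):
            rs.append(np.nanmean(funcconn.seed_map(series, seed_vol).data[net]))
        se = np.std(rs, ddof=1) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) <= 3 * max(se, 1e-3)

    def test_coupling_calibration(self, fmri_spec):
        """Mean sample seed-network correlation ~ coupling (Monte Carlo)."""
        from dbsconn import funcconn

        masks = phantom.network_masks(fmri_spec)
        seed_vol = LabelVolume(masks["seed_core"], fmri_spec.affine)
        net = masks["network"] & ~masks["seed_core"]
        rs = [
            np.nanmean(funcconn.seed_map(series, seed_vol).data[net])
            for series in phantom.iter_normative_fmri(
                fmri_spec, n_subjects=50, coupling=0.6
            )
        ]
        assert abs(np.mean(rs) - 0.6) <= 0.1

    def test_coupling_converges_with_frames(self, fmri_spec):
        """The empirical correlation approaches the target as frames grow."""
        from dbsconn import funcconn

        masks = phantom.network_masks(fmri_spec)
        seed_vol = LabelVolume(masks["seed_core"], fmri_spec.affine)
        net = masks["network"] & ~masks["seed_core"]

        def mean_r(n_frames, n_subjects=6):
            vals = [
                np.nanmean(funcconn.seed_map(s, seed_vol).data[net])
                for s in phantom.iter_normative_fmri(
                    fmri_spec, n_subjects=n_subjects,
                    n_timepoints=n_frames, coupling=0.6,
                )
            ]
            return np.mean(vals)

        err_short = abs(mean_r(124) - 0.6)
        err_long = abs(mean_r(1000) - 0.6)
        assert err_long <= err_short + 0.02

    def test_determinism(self, fmri_spec):
        a = make_normative_fmri(fmri_spec, n_subjects=2, n_timepoints=30)
        b = make_normative_fmri(
            PhantomSpec(grid_shape=(27, 27, 27), voxel_size=3.0, seed=5),
            n_subjects=2, n_timepoints=30,
        )
        for x, y in zip(a, b):
            assert np.array_equal(x.data, y.data)
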