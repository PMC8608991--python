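# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the known limitations of `dbsconn`. Everything stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is an
external empirical claim.

## Coordinate conventions

World coordinates are RAS millimetres. Voxel indices are 0-based; a voxel
owns the half-open cube `[centre − h/2, centre + h/2)`. All phantom volumes
share one diagonal affine that places world (0, 0, 0) on the centre voxel,
so the stereotactic target (±9, −9, 0) mm falls on a voxel centre at both
the 1 mm structural and the 3 mm functional resolution. The phantom is
generated directly in this common space; no registration stage exists.

## Electrode and stimulation model

The registered lead (`medtronic3389`) has four 1.5 mm contacts with 0.5 mm
edge gaps (2.0 mm centre spacing). The centre of the distal contact C0 is
placed 0.75 mm above the tip — a 1.5 mm contact flush with the tip; this is
a geometry convention, since only contact length and gap are physically
specified. Stimulation is voltage-controlled monopolar cathodic at
60 Hz / 90 µs; field models convert voltage to an equivalent current source
through an access impedance `Z` (default 1000 Ω, configurable), `I = V/Z`.
With several active contacts each carries `I = V/Z` and fields superpose.

## Electric field and VTA

*Analytic model.* `|E|(r) = 1000·I/(4πσr²)` V/mm for a point source in a
homogeneous medium of conductivity σ (S/m); the source voxel is assigned the
maximum of its 6-neighbours to keep the lattice finite.

*Numerical model.* `∇·(σ∇φ) = 0` is discretized with the 7-point stencil
and harmonic-mean face conductivities on the voxel lattice; Dirichlet
`φ = V` on the active-contact voxel patch (voxels within half a contact
length of the contact centre) and `φ = 0` on the ground surface. The
default ground is the outer grid boundary; a spherical ground (everything
outside the largest inscribed sphere) is available and removes the cubic
anisotropy of the return path. The symmetric positive-definite system is
solved by diagonal-preconditioned conjugate gradients to relative residual
1e−6 (cap 10 000 iterations; non-convergence raises with the final
residual).

`|E|` is the gradient magnitude of φ computed with **4th-order** central
differences in the interior (2nd-order at the array edge). The order
matters: on a 1/r potential, 2nd-order central differences underestimate
|E| by `(h/r)²` — 12.5 % at three voxel-lengths from the source — which
alone would exceed the 5 % verification band; with the 4th-order stencil
the homogeneous 40³ solution agrees with the closed form to ≤ 4.6 %
everywhere in the 3–10 voxel shell (verified against the source current
measured from the discrete solution, not against a nominal current).

Conductivities are isotropic scalars per tissue class (grey 0.33, white
0.14 S/m); tensor anisotropy is out of scope. CSF/background defaults to
2.0 S/m and is configurable. The VTA is `|E| ≥ 0.2 V/mm`; VTA–nucleus
metrics report overlap volume, overlap as a fraction of the nucleus, the
centroid distance, and the minimum voxel-centre distance (0 on overlap).
Both distances are emitted because the clinical literature reports
"distance" without defining it; the run report regresses outcome on the
centroid distance, which remains informative when every VTA touches the
nucleus and the minimum distance is identically zero.

## Synthetic head phantom

The head is a sphere of radius `min(grid)/2 − 6 mm` (34 mm at the default
80³ × 1 mm grid): white matter in the inner 80 %, a grey shell outside it,
CSF/background elsewhere. Bilateral CM (r = 2 mm) and Pf (r = 1.5 mm)
spheres sit at (±9, −9, 0) and (±5.5, −10, 0) mm and are labelled grey.
The parcellation contains six world-space boxes intersected with the brain:
brainstem/cerebellum (inferior) and five superior cortical bands
(postcentral, precentral, SMA, middle frontal, superior frontal). These are
role-equivalent stand-ins for an anatomical atlas, not anatomy.

Every generator draws from a named PRNG substream of the master seed
(`SeedSequence([seed, crc32(name)])`), so adding a generator never perturbs
another's output and identical spec + seed give bit-identical results.

## Tractogram and planted bundle

Streamlines are uniform Catmull–Rom curves through 4 control points,
sampled at 49 vertices (the knots are on-grid, so control points are actual
vertices). The default whole-brain set holds 200 000 streamlines; the
desk-scale pipeline default is 2000.

*Planted bundle* (10 % of streamlines): brainstem origin → thalamic
waypoint → sensorimotor cortical terminal (precentral/postcentral/SMA).
The waypoint is scattered around a corridor centre offset (−3.0, −0.5, 0)
mm from the stimulation target — i.e. at the CM–Pf border — with an
isotropic Gaussian of sd 2.8 mm truncated at 4.5 mm.

*Distractors*: random smooth curves across the brain, rejected whenever any
vertex comes within 1 mm of a nucleus sphere (clean ground truth). Five
percent of them are "near-miss" curves routed through a 4.0–6.5 mm shell
around a target, emulating the fiber-dense thalamic neighbourhood without
touching the nuclei.

These values were fixed by a Monte-Carlo calibration of the full recovery
pipeline (phantom → VTAs → connectivity matrix → t-scores → top-10 %)
before the test suite was frozen. The calibration trades off two failure
modes: a spatially wide bundle makes per-patient capture counts
amplitude-dominated, so distractors near the target acquire genuinely
discriminative connectivity profiles (the amplitude confound of VTA-based
fiber scoring); a dense tight bundle saturates the improvement scale.
At the chosen operating point, top-10 % selection recovers the planted
bundle with precision ≥ 0.8 in ≥ 90 % of 50 seeded replicates, and
shuffling outcomes drops mean precision by ≈ 0.25 toward the chance
composition of the scored pool.

## Synthetic cohort

Each of the (default 10) patients receives bilateral leads at the mirrored
targets plus truncated Gaussian placement jitter (sd 1.5 mm, cut at 3 mm),
one random active contact, and an amplitude drawn uniformly from
{1, …, 5} V at 60 Hz / 90 µs. Planted connectivity is the number of bundle
streamlines with a vertex inside the patient's bilateral analytic VTA
spheres; the stationary improvement is
`clip(effect · connectivity + N(0, noise_sd²), −100, 100)` with defaults
effect = 5 and noise_sd = 5 improvement-percent units. Follow-up visits
(baseline, 3, 6, 12, 18, 24 months, last) apply a fixed saturation ramp
(0, 0.45, 0.85, 0.95, 1.0, 1.0, 0.95) with half-noise visit scatter; the
24-month value is the primary outcome used in every association. High-dose
well-placed patients can saturate at +100 %, which mirrors the
responder/non-responder structure of small DBS cohorts; parameter-recovery
tests that need an unclipped scale use a smaller effect.

## Normative fMRI generator

Voxel series are unit-variance AR(1) (φ = 0.3) noise plus a shared AR(1)
latent signal: loading `coupling` on the planted network (a 4 mm seed
neighbourhood around both targets, brainstem/cerebellum, pre/postcentral,
SMA), `≈ 1` inside the seed neighbourhood, `0.15 · coupling` on remaining
grey matter (a weak global signal, which keeps region means nonnegative at
nonnegative coupling, as seen in normative-cohort maps), and 0 in white
matter, CSF and background. Because signal and noise share the same
spectrum, band-pass filtering leaves correlations unbiased, and the
expected seed–network correlation equals the loading: at coupling 0.6 the
mean sample correlation over subjects lands within ±0.1 of 0.6 at 124
frames and converges with more frames. Defaults follow the acquisition
they emulate: 124 frames, TR 3 s, 3 mm voxels.

Preprocessing order is smooth (6 mm FWHM) → nuisance regression (mean WM
and CSF series plus intercept, OLS) → band-pass (4th-order Butterworth,
0.01–0.08 Hz, forward–backward so zero-phase). The WM/CSF confounds are
computed from the phantom tissue labels. Group inference is the one-sample
t over Fisher-z maps; sd = 0 voxels give t = 0 when the mean is 0 and a
flagged ±∞ sentinel otherwise.

## Fibertract scoring

The score is the pooled-variance (Student) two-sample t, matching the
convention of the discriminative-fibertract literature; Welch is available
via `equal_var=False`. A score is undefined when either group has fewer
than 2 patients or the pooled variance vanishes; undefined scores are
excluded from (not bottom-ranked in) the retention pool. Retention keeps
the top `⌊fraction · n_defined⌋` by **signed** t (positive = connected to
responders), ties broken toward the lower streamline index; an
absolute-value mode exists but is not the default. No multiple-testing
correction is applied — the procedure is descriptive top-k selection.

## Outcome statistics

The rm-ANOVA is the classical one-way within-subject decomposition
(`F = MS_time/MS_error` on `(t−1, (t−1)(n−1))` df), assuming sphericity (no
Greenhouse–Geisser correction) — a documented limitation. `SS_error = 0`
(perfect additivity) is flagged rather than reported as infinite F. Post
hocs use the studentized-range criterion with the ANOVA's error mean square
and df (`q = |Δm|/√(MS_error/n)`, equal cell sizes). Regressions are
Pearson r with two-sided t-based p on n−2 df. The test suite cross-checks
the ANOVA against a dummy-coded OLS fit and `statsmodels.AnovaRM`.

## Pipeline determinism and scale

`run_all` executes phantom → VTAs → structural profiles → fiber selection →
functional maps → statistics, writing NIfTI/TRK/CSV/JSON artifacts that
round-trip through the module that produced them. The report is
byte-identical across runs with the same config + seed. Desk-scale problem
sizes (2000 streamlines, 10 patients, 20–50 normative subjects, 27³ × 3 mm
functional grid) were chosen so a full run completes in seconds and the
replicate suites in minutes on one CPU; the 200 000-streamline tractogram
(≈ 13 s to generate) is used where the whole-brain scale itself is the
quantity of interest.

## What passing tests do and do not show

The phantom has spherical geometry, boxy regions, noiseless tissue labels,
perfectly aligned volumes, and linear outcome generation. Passing tests
therefore demonstrate that the *procedures* are implemented correctly and
recover planted structure under realistic parameter magnitudes — not that
the method is robust to registration error, tractography false positives,
scanner noise, or non-linear dose–response, none of which are modelled.
The amplitude confound reproduced by the calibration (fibers near the
stimulation sweet spot acquire discriminative scores without being causal)
is a genuine property of VTA-based fiber scoring worth keeping in mind when
interpreting clinical results.
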