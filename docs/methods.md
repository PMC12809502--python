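# Methods

This note documents the statistical models, algorithms and default
parameters implemented in `edbatch`, the assumptions behind the synthetic
data generator, and the numerical choices made where the design was open.

## Symmetry model

All statistics are Laue-group statistics: intensities are assumed to obey
the crystal point group plus Friedel inversion, and anomalous signal is
ignored throughout. Twelve named operator sets cover the 11 Laue classes
(both trigonal settings -3m1 and -31m are provided, on hexagonal axes
only). Operator sets are generated at import time by closure from
hand-coded generators and asserted against the known group orders; the
space-group-number → Laue class/centring lookup and Niggli cell reduction
are delegated to `gemmi`.

The canonical asymmetric-unit representative of an index is the
lexicographically greatest image under all operators. This convention is
trivially correct for every group with no per-group boundary tables, at
the cost of a non-contiguous asu footprint — irrelevant here because the
representative is only ever used as a grouping key. Centring extinctions
(A, B, C, I, F, and R in the hexagonal obverse setting) are applied when
enumerating the theoretical unique set; the index bounds |h| ≤ a/d_min etc.
follow exactly from projecting the scattering vector on each cell vector,
so the enumeration is exhaustive for any triclinic cell.

## Merging statistics

**R factors.** R_int sums |I − ⟨I⟩| over groups with ≥ 2 observations,
normalized by the summed intensity of those same observations; singletons
are excluded from both sums. R_meas multiplies each group's numerator by
√(n/(n−1)). Negative intensities are kept everywhere — truncation would
bias the sums.

**CC1/2** is computed by literal random half-splitting: within each
multiply-observed group the observations are split into two halves (odd
counts: the extra observation goes to a random half), and CC1/2 is the
Pearson correlation of the two half-mean vectors over groups with both
halves non-empty. The split seed defaults to 17 and is carried through all
public entry points, so identical inputs give identical tables.
Significance is a one-sided test of CC > 0 with n−2 degrees of freedom at
α = 0.01. The analytic σ-τ variant is deliberately not implemented; the
half-split definition is the one being emulated, and its calibration is
tested against the closed-form Pearson expectation
CC ≈ σ_s²/(σ_s² + σ_n²) on planted variances.

**Error model / ISa.** The variance model σ′² = a(σ² + b I²) is fitted to
the within-group sample variance of equivalents. Groups are pooled into 10
equal-count bins by mean intensity; bin-averaged variance V is regressed on
bin-averaged σ² and I² with non-negative least squares (the model is linear
in (a, a·b)). Two numerical details matter in practice: the intensity-
squared regressor uses ⟨I⟩² − var/n (since E[⟨I⟩²] = I² + var/n, the raw
moment systematically deflates a·b), and bins are weighted by relative
precision √dof/V (the sd of a variance estimate scales with V, and the
high-intensity bins carry nearly all the information about b). With these
two corrections the fit recovers planted ISa ∈ {20, 33.3, 100} within 10%
at 5×10⁴ observations; without them it misses by ~20%. A fit driving a or
b to zero reports ISa as missing with a diagnostic rather than a number.

**Shells and resolution.** Shells are equal-volume in 1/d³ between the
data's own d_max and d_min (default 10 shells), which balances observation
counts under approximately uniform reciprocal-space coverage. The
resolution cutoff scans shells from low to high resolution and returns the
d_min of the last shell before the first failure of: CC1/2 ≥ 30% and
significant, ⟨I/σ⟩ ≥ 1, R_int defined. Both thresholds are configuration
keys; the scan-from-inside rule makes the estimate monotone in the CC1/2
threshold. If no shell fails, the data's own d_min is returned; if the
first shell fails, the low-resolution limit is returned with a warning.

## Laue-group estimation

Four indicators per candidate group: (1) R_meas under the candidate,
(2) its ratio to the Friedel-only R_meas, (3) CC1/2 under the candidate
with its significance, and (4) the Pearson correlation between
candidate-merged and Friedel-only-merged mean intensities on common
uniques. A candidate is rejected when the R_meas ratio exceeds 2 or its
CC1/2 is not statistically significant; the Friedel-only reference always
survives. Among accepted candidates whose CC1/2 lies within 5 percentage
points of the best, the highest-symmetry group ranks first. The quartet is
isolated behind one function so a different indicator set can be swapped in
without touching callers.

## Clustering

Cell clustering uses the Euclidean distance between feature vectors
(a, b, c, w·α, w·β, w·γ) of Niggli-reduced cells with w = 0.5 Å/degree — a
weight that balances typical ED cell-length and angle errors and is
configurable. Correlation clustering merges each dataset internally to
unique means, computes pairwise Pearson CC over common uniques (pairs with
fewer than 20 common reflections are missing, not zero), and clusters on
d = √(1 − CC²) with missing pairs imputed to the maximal distance 1.
Both clusterings use average linkage; cutting at threshold X yields groups
named `disX-clsY` with Y assigned by descending group size. Nested cuts at
increasing thresholds produce nested groups (a property test).

## Scaling and merging

The scaling model is k_i·exp(−2 B_i s²) per dataset with s = 1/(2d) —
deliberately the smallest model supporting the workflow; no resolution-
dependent local scaling. Alternating least squares iterates merged-mean and
per-dataset-parameter updates to a relative change < 1e−6 (max 100
iterations), with the gauge fixed to geometric-mean k = 1 and mean B = 0.
The k-update is exact weighted least squares; the B-update is a weighted
log-linear regression, so only planted B *differences* are identified.
Datasets must form one connected graph under pairwise common-unique counts
≥ 20 (union-find); silent disconnection would corrupt the gauge.

Outlier frames are found from per-frame relative scales (median ratio of a
frame's observations to their group means). The log-scale series is
detrended by a 21-frame running median with shrinking edge windows, so
smooth dose decay survives; residuals beyond 3 robust (MAD-based) standard
deviations are excluded and merged into contiguous ranges. The robust sd
is floored at 0.15 log units: the smallest detectable anomaly is then
about a ×0.6 scale jump, far below genuinely problematic frames (the test
fixtures plant ×0.1) but above the median scatter of weak, dose-decayed
small-wedge data, which at a 0.05 floor produced false positives.

Merging scales observations by 1/(k g), drops excluded frames, fits the
pooled error model, inflates sigmas with it, and reduces each unique index
to the inverse-variance weighted mean with σ_merged = √(1/Σw). Shell
statistics are computed on the scaled unmerged pool. All merging
statistics are invariant under a global intensity scale (tested).

## Geometry

Pixels are 0-based with centers at integers, x the fast axis; the beam
runs along +z; the rotation axis lies in the detector plane at an azimuth
measured counter-clockwise from +x, with a configurable handedness flag.

Beam-center finding without a beamstop takes the intensity-weighted
centroid of the median-filtered brightest connected blob. With a beamstop
it uses Friedel symmetry: the autoconvolution C(u) = Σ I(x)I(u−x) of the
shadow-masked, mean-subtracted pattern peaks at u = 2·center; the search is
normalized by the mask-overlap count, restricted to ±64 px around the
geometric center, and refined to sub-pixel by parabolic interpolation.

Rotation-axis refinement scores each candidate azimuth by the negative
Shannon entropy of the 2-D cylindrical histogram (azimuth × elevation
about the axis, 2° bins) of the back-rotated scattering vectors, scanning
a 1° coarse grid then a 0.02° fine grid. The 2-D form is essential: for
electrons the Ewald sphere is nearly flat, so the lab-frame azimuth about
*any* in-plane axis is ≈ ±90° − φ and a 1-D azimuthal histogram carries no
signal; the discriminating feature is the coincidence of repeat
observations of the same reciprocal lattice point, which only survives in
fine 2-D bins. Recovery on synthetic spot lists is ≤ 0.2° with 0.3 px
centroid jitter and ≤ 0.005° without; only the in-plane azimuth is
refined, never the out-of-plane tilt.

## Real-time monitor

A polling state machine (injectable clock, so tests are deterministic and
fast). A dataset directory is complete when its file names and sizes are
unchanged for a quiescence interval (default 10 s) or a sentinel file
appears; each dataset is processed exactly once. Screening mode appends
per-dataset indicator rows only. Merging mode (requires known cell and
Laue group) admits datasets passing CC1/2 > 90% and ISa > 5, re-scales and
re-merges the whole valid set from scratch each iteration — correctness
over speed at the scale of tens of datasets — and appends merged
completeness (within a fixed low-resolution/stop-resolution window, so the
history is non-decreasing), CC1/2 and resolution to an append-only
history. The stop condition fires when merged completeness at the preset
resolution (default 1.3 Å) reaches its target (default 95%). State
persists as a JSON sidecar; a resumed run reaches statistics identical to
an uninterrupted one. Once invalid, a dataset is not revisited (a manual
rescan is the escape hatch); eviction of previously valid datasets is not
implemented.

## Synthetic data

The generator emulates small-molecule / small-wedge 3D ED practice: 200 kV
electrons (λ = 0.0251 Å), 0.23°/frame, Wilson (exponential) true
intensities with mean 1000 on an arbitrary detector scale, one value per
asu orbit, counting-statistics sigmas σ² = I + 100, and a default planted
error model a = 1, b = 0.0025 (ISa = 20, a typical good ED dataset).
Observation sets come from an exact Ewald sweep: the crossing condition
|R(φ)v + k_in|² = 1/λ² is sinusoidal in φ and solved in closed form, so
completeness oracles are exact (verified against an independent
dense-sampling sign-change detector). Planted distortions cover
per-dataset scale and B, outlier frames (×0.1), exponential dose decay,
random orbit thinning, mis-indexing operators, and two-group cluster
structure; beam images and jittered spot lists carry their planted center
and axis azimuth as ground truth.

What the generator does **not** emulate — and hence what passing tests do
not certify on real data: dynamical (multiple) scattering, which inflates
R factors well beyond kinematical expectations; profile-integration
artefacts and partiality; detector point-spread and gain nonuniformity;
crystal mosaicity and mid-wedge orientation drift; twinning; anomalous
signal. The statistics are exact for the data model; their behaviour under
these real-world effects is exactly what the indicator thresholds exist to
absorb, and the defaults follow accepted ED practice rather than anything
derived here.

## Defaults at a glance

| Parameter | Default | Unit / note |
|---|---|---|
| batch selection | ISa > 5, CC1/2 > 95, completeness > 80 | per-dataset gates |
| real-time filter | CC1/2 > 90, ISa > 5 | no completeness gate |
| resolution rule | CC1/2 ≥ 30 (significant), ⟨I/σ⟩ ≥ 1 | per shell |
| shells | 10, equal volume in 1/d³ | |
| CC1/2 split seed | 17 | reported in output |
| cell-distance angle weight | 0.5 | Å per degree |
| CC distance | √(1 − CC²), min 20 common | missing → 1.0 |
| linkage | average | single/complete/ward configurable |
| scaling convergence | 1e−6 relative, ≤ 100 iterations | gauge: geo-mean k = 1 |
| outlier frames | 21-frame running median, 3 robust sd, floor 0.15 | log units |
| quiescence / stop | 10 s; 95% at 1.3 Å | real-time |

## Problem sizes used in tests

The test suite and the acceptance script run on deliberately small
studies: an orthorhombic 916 Å³ cell to 0.8 Å (1152 unique reflections in
mmm), wedges of 15–130° (≈ 800–6000 observations), batches of 10–12
datasets, 512² synthetic images, and ≈ 2500-spot lists over 800 frames.
These sizes make every oracle exhaustive and the whole suite fast while
leaving each statistic in its asymptotic regime; nothing in the
implementation is specific to them.
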