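# edbatch

Batch and real-time data reduction for 3D electron diffraction (3D ED /
microED). `edbatch` computes crystallographic quality statistics natively
from unmerged reflection files, estimates Laue groups, clusters datasets by
unit cell and by intensity correlation, scales and merges batches of
small-wedge datasets, refines detector geometry, and monitors a live
acquisition directory — all without any external processing engine, and all
testable on synthetic data with known ground truth.

## Who this is for

3D ED/microED experiments routinely collect tens of rotation datasets
("wedges") from different sub-micrometre crystals in one session. Deciding
which datasets are usable, whether they share a lattice and symmetry, which
subsets merge well, and when enough data have been collected is the daily
bottleneck. `edbatch` automates exactly that decision layer: it consumes
XDS_ASCII-style reflection files (h, k, l, I, σ(I), frame) and produces
indicator tables, dendrograms, merged reflection lists and static HTML
reports.

## What it computes

With observations grouped by symmetry-equivalent (Laue + Friedel) unique
index, the per-dataset and per-shell indicators are

- **R_int** = Σ_hkl Σ_i |I_i − ⟨I⟩| / Σ_hkl Σ_i I_i over multiply-observed
  groups, and **R_meas**, the redundancy-independent variant with each
  group's numerator scaled by √(n/(n−1));
- **CC1/2**: the Pearson correlation between mean intensities of two random
  halves of the observations, with a one-sided t-test for CC > 0 at
  α = 0.01;
- **ISa**: the asymptotic signal-to-noise of the two-parameter error model
  σ′²(I) = a·(σ² + b·I²), ISa = 1/√(a·b), fitted to the within-group
  variance of equivalents across intensity bins;
- **completeness** against the exhaustively enumerated theoretical unique
  set for the cell, Laue class, centring and resolution window;
- a **resolution cutoff**: the d_min of the outermost shell still passing
  CC1/2 ≥ 30% (significant) and ⟨I/σ⟩ ≥ 1, scanning shells of equal
  reciprocal volume from low to high resolution.

Around these sit dataset selection (defaults ISa > 5, CC1/2 > 95%,
completeness > 80%), inter-dataset scaling I ≈ k_i·exp(−2B_i s²)·⟨I⟩ by
alternating least squares, robust outlier-frame exclusion, average-linkage
clustering on Niggli-reduced cell parameters and on d = √(1 − CC²)
correlation distances (groups named `disX-clsY`), beam-center finding on
SMV images (directly or through Friedel autocorrelation behind a beamstop),
rotation-axis azimuth refinement, and a polling real-time monitor with a
completeness-based stop rule.

## Worked example

Simulate four orthorhombic wedge datasets and tabulate their indicators:

```sh
$ edbatch simulate data --n-datasets 4 --seed 21 --wedge 100
wrote 4 dataset(s) under data
$ edbatch summarize data -o summary.csv --space-group 16
4 dataset(s) -> summary.csv
$ cat summary.csv
dataset_id,space_group,a,b,c,alpha,beta,gamma,volume,isa,r_meas,cc_half,completeness,resolution
exp01,1,6.0,7.027,21.718,90.0,90.0,90.0,915.67,19.73,0.0488,99.65,77.2,0.8
exp02,1,6.0,7.027,21.718,90.0,90.0,90.0,915.67,19.22,0.0495,99.51,91.58,0.8
exp03,1,6.0,7.027,21.718,90.0,90.0,90.0,915.67,21.58,0.0464,99.7,83.62,0.8
exp04,1,6.0,7.027,21.718,90.0,90.0,90.0,915.67,21.75,0.0461,99.64,97.91,0.8
```

Each row is one dataset: unit cell and volume, fitted ISa (the generator
plants an error model with ISa = 20 — rows recover 19–22), R_meas ≈ 0.05
and CC1/2 ≈ 99.6% (consistent with modest counting noise), geometric
completeness of a 100° wedge in mmm (77–98% depending on orientation), and
a resolution estimate that runs to the simulation's 0.8 Å limit because
every shell passes the CC1/2 criterion.

The same building blocks run as a whole pipeline (`edbatch run --config
run.toml`: summarize → filter → scale/merge → cluster → report) or as
single stages (`estimate-laue`, `cluster-cells`, `cluster-cc`,
`scale-merge`, `filter`, `report`, `watch` for the real-time monitor).
Python users can drive everything through the library:

```python
from edbatch import (read_xds_ascii, laue_group_for_space_group,
                     dataset_summary)
rec = read_xds_ascii("data/exp01/exp01.HKL")
row = dataset_summary(rec, laue=laue_group_for_space_group(19))
print(row.cc_half, row.isa, row.completeness)
```

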