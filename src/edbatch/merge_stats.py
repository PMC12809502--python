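"""Merging-quality statistics for unmerged reflection data.

Implements every indicator the batch pipeline tabulates per dataset and per
merged cluster:

* ``Rint`` (Rmerge) and the redundancy-independent ``Rmeas``
  (Diederichs & Karplus),
* ``CC1/2`` — Pearson correlation between mean intensities of two random
  halves of the observations, with a one-sided significance test,
* the two-parameter error model sigma'^2 = a*(sigma^2 + b*I^2) and the
  asymptotic signal-to-noise ISa = 1/sqrt(a*b),
* completeness against the theoretical unique set,
* equal-volume resolution shells and the CC1/2-anchored resolution cutoff.

All statistics merge Friedel pairs (Laue-group statistics); negative
intensities are kept in every sum so the estimates stay unbiased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .formats import DatasetRecord, SummaryRow, UnitCell
from .symmetry import (LaueGroup, count_theoretical_unique,
                       laue_group_for_space_group, map_to_asu)

__all__ = [
    "EquivalentGroups", "ShellStats", "ErrorModel", "group_equivalents",
    "r_int", "r_meas", "cc_half", "fit_error_model", "completeness",
    "bin_shells", "estimate_resolution", "dataset_summary",
    "DEFAULT_CC_HALF_MIN", "DEFAULT_I_OVER_SIGMA_MIN", "DEFAULT_N_SHELLS",
]

DEFAULT_CC_HALF_MIN = 30.0      # percent; resolution-cutoff criterion
DEFAULT_I_OVER_SIGMA_MIN = 1.0
DEFAULT_N_SHELLS = 10
DEFAULT_CC_SEED = 17            # fixed half-split seed, reported in output


class StatisticUndefined(ValueError):
    """Raised when a statistic's preconditions are not met; callers that
    assemble summary tables convert this into a missing field."""


@dataclass
class EquivalentGroups:
    """Observations grouped by symmetry-unique (asu) index.

    ``inverse[i]`` is the group number of observation ``i``; observation
    order within a group follows input order.
    """

    unique_hkl: np.ndarray     # (U, 3)
    inverse: np.ndarray        # (N,)
    intensity: np.ndarray      # (N,)
    sigma: np.ndarray          # (N,)

    @property
    def n_unique(self) -> int:
        return len(self.unique_hkl)

    @property
    def n_obs(self) -> int:
        return len(self.intensity)

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.inverse, minlength=self.n_unique)

    def group_means(self) -> np.ndarray:
        return (np.bincount(self.inverse, weights=self.intensity,
                            minlength=self.n_unique) / self.sizes)


def group_equivalents(reflections: pd.DataFrame, laue: LaueGroup
                      ) -> EquivalentGroups:
    """Group observations by their canonical asu representative."""
    hkl = reflections[["h", "k", "l"]].to_numpy(dtype=np.int64)
    asu = map_to_asu(hkl, laue)
    unique, inverse = np.unique(asu, axis=0, return_inverse=True)
    return EquivalentGroups(
        unique_hkl=unique, inverse=inverse.ravel(),
        intensity=reflections["intensity"].to_numpy(dtype=float),
        sigma=reflections["sigma"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# R factors
# ---------------------------------------------------------------------------

def _r_factor(groups: EquivalentGroups, redundancy_independent: bool) -> float:
    sizes = groups.sizes
    multi = sizes >= 2
    if not multi.any():
        raise StatisticUndefined("no multiply-observed unique reflection")
    means = groups.group_means()
    obs_multi = multi[groups.inverse]
    dev = np.abs(groups.intensity - means[groups.inverse])
    if redundancy_independent:
        factor = np.sqrt(sizes / np.maximum(sizes - 1, 1))
        dev = dev * factor[groups.inverse]
    num = dev[obs_multi].sum()
    den = groups.intensity[obs_multi].sum()
    if den == 0:
        raise StatisticUndefined("zero intensity sum in R-factor denominator")
    return float(num / den)


def r_int(groups: EquivalentGroups) -> float:
    """Rint = sum |I_i - <I>| / sum I_i over multiply-observed groups."""
    return _r_factor(groups, redundancy_independent=False)


def r_meas(groups: EquivalentGroups) -> float:
    """Rmeas: as Rint, each group's numerator scaled by sqrt(n/(n-1))."""
    return _r_factor(groups, redundancy_independent=True)


# ---------------------------------------------------------------------------
# CC1/2
# ---------------------------------------------------------------------------

def cc_half(groups: EquivalentGroups, seed: int = DEFAULT_CC_SEED,
            alpha: float = 0.01) -> tuple[float, bool]:
    """CC1/2 in percent by literal random half-splitting, plus significance.

    Each multiply-observed group's observations are split at random into
    two halves (odd counts: the extra observation goes to a random half);
    CC1/2 is the Pearson correlation of the two half-mean vectors.
    Significance is a one-sided test of CC > 0 at ``alpha`` with n-2
    degrees of freedom.
    """
    rng = np.random.default_rng(seed)
    sizes = groups.sizes
    multi = sizes >= 2
    if multi.sum() < 3:
        raise StatisticUndefined("CC1/2 needs >= 3 multiply-observed groups")

    # random within-group order: rank observations by a random key
    key = rng.random(groups.n_obs)
    order = np.lexsort((key, groups.inverse))
    rank = np.empty(groups.n_obs, dtype=np.int64)
    start = np.concatenate(([0], np.cumsum(sizes)))
    rank[order] = np.arange(groups.n_obs) - start[groups.inverse[order]]

    # half-1 target size per group; odd group: extra goes to a random half
    half1_size = sizes // 2 + (sizes % 2) * rng.integers(0, 2, size=len(sizes))
    in_half1 = rank < half1_size[groups.inverse]

    n1 = np.bincount(groups.inverse[in_half1], minlength=groups.n_unique)
    n2 = sizes - n1
    s1 = np.bincount(groups.inverse[in_half1],
                     weights=groups.intensity[in_half1],
                     minlength=groups.n_unique)
    s2 = (np.bincount(groups.inverse, weights=groups.intensity,
                      minlength=groups.n_unique) - s1)
    ok = (n1 > 0) & (n2 > 0)
    if ok.sum() < 3:
        raise StatisticUndefined("CC1/2: fewer than 3 non-empty half pairs")
    m1, m2 = s1[ok] / n1[ok], s2[ok] / n2[ok]
    if np.allclose(m1, m1[0]) or np.allclose(m2, m2[0]):
        # no variance in one half-vector: perfectly flat data
        cc = 1.0 if np.allclose(m1, m2) else 0.0
    else:
        cc = float(np.corrcoef(m1, m2)[0, 1])
    n = int(ok.sum())
    if abs(cc) >= 1.0:
        significant = cc > 0
    else:
        t = cc * np.sqrt((n - 2) / (1.0 - cc * cc))
        significant = bool(stats.t.sf(t, df=n - 2) < alpha) and cc > 0
    return 100.0 * cc, significant


# ---------------------------------------------------------------------------
# Error model / ISa
# ---------------------------------------------------------------------------

@dataclass
class ErrorModel:
    """sigma'^2 = a*(sigma^2 + b*I^2); ISa = 1/sqrt(a*b)."""

    a: float
    b: float
    diagnostic: str = ""

    @property
    def isa(self) -> float | None:
        if self.a > 0 and self.b > 0:
            return float(1.0 / np.sqrt(self.a * self.b))
        return None

    def inflate_sigma(self, intensity: np.ndarray, sigma: np.ndarray
                      ) -> np.ndarray:
        if self.a <= 0 or self.b < 0:
            return np.asarray(sigma, dtype=float)
        return np.sqrt(self.a * (np.asarray(sigma, dtype=float) ** 2
                                 + self.b * np.asarray(intensity, dtype=float) ** 2))


def fit_error_model(groups: EquivalentGroups, n_bins: int = 10) -> ErrorModel:
    """Fit (a, b) so the within-group sample variance of equivalents matches
    a*(sigma^2 + b*<I>^2) across equal-count intensity bins.

    The model is linear in (a, a*b); non-negative least squares keeps both
    coefficients physical.  A degenerate fit (either coefficient zero)
    reports ISa as missing with a diagnostic.
    """
    sizes = groups.sizes
    multi = np.flatnonzero(sizes >= 2)
    if len(multi) < 10:
        raise StatisticUndefined("error-model fit needs >= 10 multiply-observed"
                                 " groups")
    inv = groups.inverse
    n = sizes
    sum_i = np.bincount(inv, weights=groups.intensity, minlength=groups.n_unique)
    sum_i2 = np.bincount(inv, weights=groups.intensity ** 2,
                         minlength=groups.n_unique)
    sum_s2 = np.bincount(inv, weights=groups.sigma ** 2,
                         minlength=groups.n_unique)
    mean = sum_i[multi] / n[multi]
    var = (sum_i2[multi] - n[multi] * mean ** 2) / (n[multi] - 1)
    mean_s2 = sum_s2[multi] / n[multi]

    if np.all(var <= 1e-12 * np.maximum(mean ** 2, 1.0)):
        return ErrorModel(0.0, 0.0, diagnostic="noise-free equivalents: "
                          "zero within-group variance, fit degenerate")

    n_bins = min(n_bins, max(len(multi) // 5, 1))
    order = np.argsort(mean)
    bins = np.array_split(order, n_bins)
    # E[<I>²] = I² + var/n: debias the intensity-squared regressor with the
    # group's own variance estimate, else a*b is systematically deflated
    m2 = np.maximum(mean ** 2 - var / n[multi], 0.0)
    V = np.array([var[b].mean() for b in bins])
    S = np.array([mean_s2[b].mean() for b in bins])
    M = np.array([m2[b].mean() for b in bins])
    # sd of a pooled variance estimate scales as V/sqrt(dof): weight rows
    # by relative precision so the information-rich high-intensity bins
    # (which carry the b signal) are not drowned by absolute residuals
    dof = np.array([np.sum(n[multi][b] - 1) for b in bins], dtype=float)
    w_row = np.sqrt(dof) / np.maximum(V, 1e-300)
    design = np.column_stack([S, M]) * w_row[:, None]
    coef, _ = optimize.nnls(design, V * w_row)
    a, ab = float(coef[0]), float(coef[1])
    if a <= 0 or ab <= 0:
        return ErrorModel(a, 0.0 if a <= 0 else ab / a,
                          diagnostic=f"degenerate error-model fit: a={a:g}, "
                                     f"a*b={ab:g}")
    return ErrorModel(a, ab / a)


# ---------------------------------------------------------------------------
# Completeness
# ---------------------------------------------------------------------------

def completeness(groups: EquivalentGroups, cell: UnitCell, laue: LaueGroup,
                 d_max: float, d_min: float) -> float:
    """Observed fraction (percent) of the theoretical unique set in
    [d_min, d_max]."""
    theo = count_theoretical_unique(cell, laue, d_max, d_min)
    if theo == 0:
        raise StatisticUndefined(f"no theoretical reflections in "
                                 f"({d_max}, {d_min}) Å")
    d = cell.d_spacing(groups.unique_hkl)
    n_obs_unique = int(np.count_nonzero((d >= d_min) & (d <= d_max)))
    return 100.0 * n_obs_unique / theo


# ---------------------------------------------------------------------------
# Resolution shells
# ---------------------------------------------------------------------------

@dataclass
class ShellStats:
    """Merging statistics of one resolution shell (or the overall row)."""

    d_max: float
    d_min: float
    n_obs: int = 0
    n_unique: int = 0
    multiplicity: float | None = None
    completeness: float | None = None       # percent
    r_int: float | None = None              # fraction
    r_meas: float | None = None             # fraction
    cc_half: float | None = None            # percent
    cc_significant: bool = False
    mean_i_over_sigma: float | None = None
    overall: bool = False


def _shell_stats(df: pd.DataFrame, cell: UnitCell, laue: LaueGroup,
                 d_max: float, d_min: float, seed: int,
                 overall: bool = False) -> ShellStats:
    st = ShellStats(d_max=d_max, d_min=d_min, n_obs=len(df), overall=overall)
    if len(df) == 0:
        return st
    groups = group_equivalents(df, laue)
    st.n_unique = groups.n_unique
    st.multiplicity = groups.n_obs / groups.n_unique
    st.mean_i_over_sigma = float(np.mean(df["intensity"].to_numpy()
                                         / df["sigma"].to_numpy()))
    for name, fn in (("r_int", r_int), ("r_meas", r_meas)):
        try:
            setattr(st, name, fn(groups))
        except StatisticUndefined:
            pass
    try:
        st.cc_half, st.cc_significant = cc_half(groups, seed=seed)
    except StatisticUndefined:
        pass
    try:
        st.completeness = completeness(groups, cell, laue, d_max, d_min)
    except StatisticUndefined:
        pass
    return st


def bin_shells(reflections: pd.DataFrame, cell: UnitCell, laue: LaueGroup,
               n_shells: int = DEFAULT_N_SHELLS,
               seed: int = DEFAULT_CC_SEED) -> list[ShellStats]:
    """Split the data into shells of equal reciprocal volume (linear in
    1/d^3) between the data's own d_max and d_min; the overall row is
    appended last."""
    if n_shells < 1:
        raise ValueError("need at least one shell")
    if len(reflections) == 0:
        raise StatisticUndefined("no reflections to bin")
    d = cell.d_spacing(reflections[["h", "k", "l"]].to_numpy(dtype=np.int64))
    d_max_data, d_min_data = float(d.max()), float(d.min())
    if d_max_data == d_min_data:
        edges_d = np.array([d_max_data * (1 + 1e-9), d_min_data * (1 - 1e-9)])
        n_shells = 1
    else:
        s3 = np.linspace(d_max_data ** -3, d_min_data ** -3, n_shells + 1)
        edges_d = s3 ** (-1.0 / 3.0)
    shell_idx = np.clip(np.searchsorted(-edges_d, -d, side="right") - 1,
                        0, n_shells - 1)
    shells = []
    for i in range(n_shells):
        sub = reflections.iloc[np.flatnonzero(shell_idx == i)]
        shells.append(_shell_stats(sub, cell, laue,
                                   float(edges_d[i]), float(edges_d[i + 1]),
                                   seed=seed))
    shells.append(_shell_stats(reflections, cell, laue,
                               d_max_data, d_min_data, seed=seed, overall=True))
    return shells


def shells_to_frame(shells: list[ShellStats]) -> pd.DataFrame:
    return pd.DataFrame([{
        "d_max": s.d_max, "d_min": s.d_min, "n_obs": s.n_obs,
        "n_unique": s.n_unique, "multiplicity": s.multiplicity,
        "completeness": s.completeness, "r_int": s.r_int, "r_meas": s.r_meas,
        "cc_half": s.cc_half, "cc_significant": s.cc_significant,
        "mean_i_over_sigma": s.mean_i_over_sigma, "overall": s.overall,
    } for s in shells])


def estimate_resolution(shells: list[ShellStats],
                        cc_half_min: float = DEFAULT_CC_HALF_MIN,
                        i_over_sigma_min: float = DEFAULT_I_OVER_SIGMA_MIN
                        ) -> float:
    """Resolution cutoff from the shell table.

    Shells are scanned from low to high resolution; a shell passes when its
    CC1/2 is defined, >= ``cc_half_min`` percent and statistically
    significant, its mean I/sigma >= ``i_over_sigma_min``, and its Rint is
    defined.  The first failing shell terminates the scan and the cutoff is
    the d_min of the last passing shell.  If every shell passes the data's
    own d_min is returned; if the first shell already fails, the innermost
    shell's d_max is returned with a warning.
    """
    per_shell = [s for s in shells if not s.overall]
    defined = [s for s in per_shell if s.cc_half is not None]
    if len(defined) < 3:
        raise StatisticUndefined("resolution estimate needs >= 3 shells with "
                                 "defined CC1/2")
    last_pass = None
    for s in per_shell:
        ok = (s.cc_half is not None and s.cc_half >= cc_half_min
              and s.cc_significant
              and s.mean_i_over_sigma is not None
              and s.mean_i_over_sigma >= i_over_sigma_min
              and s.r_int is not None)
        if not ok:
            break
        last_pass = s
    if last_pass is None:
        warnings.warn("no resolution shell passes the cutoff criteria; "
                      "returning the low-resolution limit", stacklevel=2)
        return per_shell[0].d_max
    return last_pass.d_min


# ---------------------------------------------------------------------------
# Per-dataset summary
# ---------------------------------------------------------------------------

def dataset_summary(record: DatasetRecord, laue: LaueGroup | None = None,
                    n_shells: int = DEFAULT_N_SHELLS,
                    seed: int = DEFAULT_CC_SEED) -> SummaryRow:
    """Populate every summary indicator for one dataset.

    Individual statistic failures leave that field missing; the batch never
    aborts on a single bad dataset.
    """
    header = record.header
    if laue is None:
        laue = laue_group_for_space_group(header.space_group_number)
    row = SummaryRow(dataset_id=record.dataset_id,
                     space_group_number=header.space_group_number,
                     unit_cell=header.unit_cell)
    if record.n_obs == 0:
        return row
    try:
        groups = group_equivalents(record.reflections, laue)
    except Exception:
        return row
    try:
        row.r_meas = r_meas(groups)
    except StatisticUndefined:
        pass
    try:
        row.cc_half = cc_half(groups, seed=seed)[0]
    except StatisticUndefined:
        pass
    try:
        row.isa = fit_error_model(groups).isa
    except StatisticUndefined:
        pass
    cell = header.unit_cell
    d = cell.d_spacing(record.hkl_array())
    d_max_data, d_min_data = float(d.max()), float(d.min())
    try:
        row.completeness = completeness(groups, cell, laue,
                                        d_max_data, d_min_data)
    except StatisticUndefined:
        pass
    try:
        shells = bin_shells(record.reflections, cell, laue,
                            n_shells=n_shells, seed=seed)
        row.resolution_estimate = estimate_resolution(shells)
    except StatisticUndefined:
        pass
    record.summary = row
    return row
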