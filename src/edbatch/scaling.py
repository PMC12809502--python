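"""Dataset selection, inter-dataset scaling and merging.

The scaling model per dataset i is ``I_obs = k_i * exp(-2 B_i s^2) * <I>_u``
with s = 1/(2d) — the zero-dimensional scale plus an optional isotropic
B-factor, fitted by alternating weighted least squares against the current
merged means and gauge-fixed to geometric-mean(k) = 1 (and mean B = 0 when
B is refined).  Outlier frames are detected from per-frame relative scales
(median observation/group-mean ratio) after running-median detrending, so
smooth beam-damage decay is not flagged.  Merging uses inverse-variance
weights with the fitted error model inflating sigmas.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import DatasetRecord, SummaryRow
from .merge_stats import (ShellStats, StatisticUndefined, bin_shells,
                          fit_error_model, group_equivalents)
from .symmetry import LaueGroup

logger = logging.getLogger("edbatch")

__all__ = [
    "FilterThresholds", "ScaleSolution", "filter_datasets", "fit_scales",
    "exclude_outlier_frames", "merge",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Quality gates for dataset selection.

    Batch defaults: ISa > 5, CC1/2 > 95%, completeness > 80% mark a dataset
    promising for single-dataset structure determination; the real-time
    profile relaxes to CC1/2 > 90% with no completeness gate (small-wedge
    data are individually incomplete by design).
    """

    isa_min: float = 5.0
    cc_half_min: float = 95.0       # percent
    completeness_min: float = 80.0  # percent

    @classmethod
    def realtime(cls) -> "FilterThresholds":
        return cls(isa_min=5.0, cc_half_min=90.0, completeness_min=0.0)


@dataclass
class ScaleSolution:
    dataset_ids: list[str]
    k: np.ndarray                 # per-dataset scale, geometric mean 1
    b: np.ndarray                 # per-dataset isotropic B (Å²)
    excluded_frames: dict = field(default_factory=dict)  # id -> [(lo, hi)]
    n_iter: int = 0
    converged: bool = True

    def scale_of(self, dataset_id: str) -> tuple[float, float]:
        i = self.dataset_ids.index(dataset_id)
        return float(self.k[i]), float(self.b[i])


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def filter_datasets(rows: list[SummaryRow],
                    thresholds: FilterThresholds = FilterThresholds()
                    ) -> tuple[list[str], list[tuple[str, str]]]:
    """Split summary rows into picked ids and (id, reason) rejections.

    A missing indicator fails its gate — a dataset is never picked on
    absent evidence.  Input order is preserved.
    """
    if not rows:
        raise ValueError("no summary rows to filter")
    picked: list[str] = []
    rejected: list[tuple[str, str]] = []
    for row in rows:
        reasons = []
        if thresholds.isa_min > 0:
            if row.isa is None:
                reasons.append("ISa missing")
            elif row.isa < thresholds.isa_min:
                reasons.append(f"ISa<{thresholds.isa_min:g}")
        if thresholds.cc_half_min > 0:
            if row.cc_half is None:
                reasons.append("CC1/2 missing")
            elif row.cc_half < thresholds.cc_half_min:
                reasons.append(f"CC1/2<{thresholds.cc_half_min:g}")
        if thresholds.completeness_min > 0:
            if row.completeness is None:
                reasons.append("completeness missing")
            elif row.completeness < thresholds.completeness_min:
                reasons.append(f"completeness<{thresholds.completeness_min:g}")
        if reasons:
            rejected.append((row.dataset_id, "; ".join(reasons)))
        else:
            picked.append(row.dataset_id)
    return picked, rejected


# ---------------------------------------------------------------------------
# Scale refinement
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def _assemble(datasets: list[DatasetRecord], laue: LaueGroup):
    """Concatenate observations with global unique-index labels."""
    from .clustering import _encode
    keys, intens, sigmas, dset_idx, d_spacings = [], [], [], [], []
    for i, rec in enumerate(datasets):
        grp = group_equivalents(rec.reflections, laue)
        asu_keys = _encode(grp.unique_hkl)[grp.inverse]
        keys.append(asu_keys)
        intens.append(grp.intensity)
        sigmas.append(grp.sigma)
        dset_idx.append(np.full(len(asu_keys), i, dtype=np.int64))
        d_spacings.append(rec.header.unit_cell.d_spacing(rec.hkl_array()))
    keys = np.concatenate(keys)
    uniq, inv = np.unique(keys, return_inverse=True)
    return (inv.ravel(), len(uniq), np.concatenate(intens),
            np.concatenate(sigmas), np.concatenate(dset_idx),
            np.concatenate(d_spacings))


def _check_connectivity(inv: np.ndarray, dset: np.ndarray, n_sets: int,
                        ids: list[str], min_common: int) -> None:
    per_set = [set(inv[dset == i].tolist()) for i in range(n_sets)]
    uf = _UnionFind(n_sets)
    for i in range(n_sets):
        for j in range(i + 1, n_sets):
            if len(per_set[i] & per_set[j]) >= min_common:
                uf.union(i, j)
    roots = {uf.find(i) for i in range(n_sets)}
    if len(roots) > 1:
        comps: dict[int, list[str]] = {}
        for i in range(n_sets):
            comps.setdefault(uf.find(i), []).append(ids[i])
        raise ValueError("datasets do not form one connected scaling graph: "
                         + " | ".join(",".join(c) for c in comps.values()))


def fit_scales(datasets: list[DatasetRecord], laue: LaueGroup,
               with_b: bool = False, min_common: int = 20,
               tol: float = 1e-6, max_iter: int = 100) -> ScaleSolution:
    """Fit per-dataset scales (and optional B) by alternating least squares.

    Iterates merged-mean and scale updates until the largest relative
    parameter change drops below ``tol``; non-convergence returns the best
    solution with a warning.  Disconnected dataset graphs (pairwise common
    uniques below ``min_common``) are an error naming the components.
    """
    if len(datasets) < 2:
        raise ValueError("scaling needs at least two datasets")
    ids = [d.dataset_id for d in datasets]
    inv, n_uniq, I, sig, dset, d_sp = _assemble(datasets, laue)
    _check_connectivity(inv, dset, len(datasets), ids, min_common)

    s2 = 1.0 / (4.0 * d_sp ** 2)
    w = 1.0 / sig ** 2
    k = np.ones(len(datasets))
    B = np.zeros(len(datasets))
    converged = False
    for it in range(1, max_iter + 1):
        g = k[dset] * np.exp(-2.0 * B[dset] * s2)
        # merged means given scales: LS of I ≈ g·M per unique index
        num = np.bincount(inv, weights=w * g * I, minlength=n_uniq)
        den = np.bincount(inv, weights=w * g * g, minlength=n_uniq)
        M = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)

        k_new = np.empty_like(k)
        B_new = B.copy()
        Mo = M[inv]
        for i in range(len(datasets)):
            sel = dset == i
            if with_b:
                ok = sel & (I > 0) & (Mo > 0)
                if ok.sum() < 3:
                    k_new[i], B_new[i] = k[i], B[i]
                    continue
                y = np.log(I[ok] / Mo[ok])
                x = s2[ok]
                wt = np.clip((I[ok] / sig[ok]) ** 2, 0, None)
                W = wt.sum()
                xm, ym = (wt * x).sum() / W, (wt * y).sum() / W
                sxx = (wt * (x - xm) ** 2).sum()
                slope = 0.0 if sxx == 0 else (wt * (x - xm) * (y - ym)).sum() / sxx
                B_new[i] = -slope / 2.0
                k_new[i] = float(np.exp(ym - slope * xm))
            else:
                gm = Mo[sel]   # B fixed at 0: model I = k·M
                den_i = (w[sel] * gm * gm).sum()
                k_new[i] = ((w[sel] * I[sel] * gm).sum()
                            / max(den_i, 1e-300))
        # gauge: geometric mean of k = 1, mean B = 0
        k_new = np.clip(k_new, 1e-12, None)
        k_new /= np.exp(np.mean(np.log(k_new)))
        if with_b:
            B_new -= B_new.mean()
        delta = max(np.max(np.abs(k_new - k) / np.maximum(k, 1e-12)),
                    np.max(np.abs(B_new - B)) if with_b else 0.0)
        k, B = k_new, B_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"scale refinement did not converge in {max_iter} "
                      "iterations; returning best solution", stacklevel=2)
    return ScaleSolution(dataset_ids=ids, k=k, b=B, n_iter=it,
                         converged=converged)


# ---------------------------------------------------------------------------
# Outlier frames
# ---------------------------------------------------------------------------

def exclude_outlier_frames(record: DatasetRecord, laue: LaueGroup,
                           window: int = 21, n_sigma: float = 3.0,
                           min_robust_sd: float = 0.15
                           ) -> list[tuple[int, int]]:
    """Contiguous frame ranges whose relative scale is anomalous.

    Per-frame relative scale = median ratio of that frame's observations to
    their group means; the log-scale series is detrended by a running
    median of ``window`` frames (shrinking at the edges), so smooth decay
    survives while step anomalies are flagged when the residual exceeds
    ``n_sigma`` robust (MAD-based) standard deviations.  The robust sd is
    floored at ``min_robust_sd`` log units, so the smallest detectable
    anomaly is about a ×0.6 scale jump — per-frame medians of weak,
    dose-decayed data scatter well below that, while genuinely problematic
    frames (blocked beam, grid bars) fall far outside.
    """
    if record.frameless:
        warnings.warn(f"{record.dataset_id}: no frame coordinates; outlier-"
                      "frame exclusion skipped", stacklevel=2)
        return []
    frames_int = np.floor(record.reflections["frame"].to_numpy()).astype(int)
    unique_frames = np.unique(frames_int)
    if len(unique_frames) < 20:
        warnings.warn(f"{record.dataset_id}: fewer than 20 frames; outlier-"
                      "frame exclusion skipped", stacklevel=2)
        return []
    grp = group_equivalents(record.reflections, laue)
    means = grp.group_means()[grp.inverse]
    ok = (grp.sizes[grp.inverse] >= 2) & (means > 0)
    if ok.sum() == 0:
        return []
    ratio = grp.intensity[ok] / means[ok]
    fr = frames_int[ok]

    scale = np.full(len(unique_frames), np.nan)
    for i, f in enumerate(unique_frames):
        r = ratio[fr == f]
        if r.size:
            scale[i] = np.median(r)
    valid = np.isfinite(scale) & (scale > 0)
    log_s = np.full(len(unique_frames), np.nan)
    log_s[valid] = np.log(scale[valid])

    hw = window // 2
    idx_valid = np.flatnonzero(valid)
    trend = np.full_like(log_s, np.nan)
    for pos, i in enumerate(idx_valid):
        lo, hi = max(0, pos - hw), min(len(idx_valid), pos + hw + 1)
        trend[i] = np.median(log_s[idx_valid[lo:hi]])
    resid = log_s - trend
    mad = np.nanmedian(np.abs(resid - np.nanmedian(resid)))
    robust_sd = max(1.4826 * float(mad), min_robust_sd)
    bad = valid & (np.abs(resid) > n_sigma * robust_sd)

    ranges: list[tuple[int, int]] = []
    for f in unique_frames[bad]:
        if ranges and f == ranges[-1][1] + 1:
            ranges[-1] = (ranges[-1][0], int(f))
        else:
            ranges.append((int(f), int(f)))
    if ranges:
        logger.info("%s: excluding frame ranges %s", record.dataset_id, ranges)
    return ranges


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def _drop_excluded(df: pd.DataFrame, ranges: list[tuple[int, int]]
                   ) -> pd.DataFrame:
    if not ranges:
        return df
    f = np.floor(df["frame"].to_numpy()).astype(int)
    keep = np.ones(len(df), dtype=bool)
    for lo, hi in ranges:
        keep &= ~((f >= lo) & (f <= hi))
    return df.iloc[np.flatnonzero(keep)]


def merge(datasets: list[DatasetRecord], solution: ScaleSolution | None,
          laue: LaueGroup, n_shells: int = 10, seed: int = 17
          ) -> tuple[DatasetRecord, list[ShellStats]]:
    """Scale, pool and merge datasets to a unique reflection list.

    With ``solution=None`` (or unit scales) this is a pure equivalence
    merge.  Observations are divided by k_i*exp(-2 B_i s^2), excluded
    frames dropped, and each unique index reduced to the inverse-variance
    weighted mean with sigma inflated by the pooled error model.  Shell
    statistics are computed on the scaled unmerged observations.
    """
    if not datasets:
        raise ValueError("nothing to merge")
    scaled = []
    for rec in datasets:
        df = rec.reflections.copy()
        if solution is not None:
            ki, bi = solution.scale_of(rec.dataset_id)
            s2 = 1.0 / (4.0 * rec.header.unit_cell.d_spacing(
                rec.hkl_array()) ** 2)
            g = ki * np.exp(-2.0 * bi * s2)
            df["intensity"] = df["intensity"].to_numpy() / g
            df["sigma"] = df["sigma"].to_numpy() / g
            df = _drop_excluded(df, solution.excluded_frames.get(
                rec.dataset_id, []))
        scaled.append(df)
    pooled = pd.concat(scaled, ignore_index=True)
    if len(pooled) == 0:
        raise ValueError("all observations excluded")

    grp = group_equivalents(pooled, laue)
    try:
        model = fit_error_model(grp)
        sig_eff = model.inflate_sigma(grp.intensity, grp.sigma)
        if not np.all(sig_eff > 0):
            sig_eff = grp.sigma
    except StatisticUndefined:
        sig_eff = grp.sigma
    w = 1.0 / sig_eff ** 2
    sw = np.bincount(grp.inverse, weights=w, minlength=grp.n_unique)
    swi = np.bincount(grp.inverse, weights=w * grp.intensity,
                      minlength=grp.n_unique)
    merged_i = swi / sw
    merged_sig = np.sqrt(1.0 / sw)

    header = datasets[0].header
    mid_frame = 0.5 * (header.frame_range[0] + header.frame_range[1])
    merged_df = pd.DataFrame({
        "h": grp.unique_hkl[:, 0], "k": grp.unique_hkl[:, 1],
        "l": grp.unique_hkl[:, 2],
        "intensity": merged_i, "sigma": merged_sig,
        "frame": mid_frame,
    })
    merged_rec = DatasetRecord(
        dataset_id="merged", header=header, reflections=merged_df,
        merged=True, frameless=True)
    shells = bin_shells(pooled, header.unit_cell, laue,
                        n_shells=n_shells, seed=seed)
    return merged_rec, shells
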