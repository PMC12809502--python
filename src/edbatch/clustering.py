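"""Grouping of diffraction datasets.

Two complementary clusterings drive dataset selection in batch work:

* by unit-cell similarity — Euclidean distance between Niggli-reduced cell
  parameter vectors (angles weighted in Å/degree), used to separate
  polymorphs and mis-indexed cells before any intensity comparison;
* by pairwise intensity correlation — datasets merged internally to unique
  means, Pearson CC over common indices, distance d = sqrt(1 - CC^2)
  (the convention of correlation-based diffraction-dataset clustering).

Both use average-linkage hierarchical clustering; cutting the dendrogram at
a threshold X yields groups named ``disX-clsY`` with Y numbered by
descending group size.  The module also ranks candidate Laue groups for a
dataset using four merging-statistic indicators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .formats import CorrelationTable, DatasetRecord, UnitCell
from .merge_stats import (EquivalentGroups, StatisticUndefined, cc_half,
                          group_equivalents, r_meas)
from .symmetry import LAUE_NAMES, LaueGroup, laue_operators, map_to_asu

__all__ = [
    "DistanceMatrix", "ClusterResult", "LaueScore", "niggli_reduce",
    "cell_distance_matrix", "cluster_cells", "estimate_laue",
    "pairwise_cc_matrix", "cc_cluster",
    "DEFAULT_ANGLE_WEIGHT", "DEFAULT_MIN_COMMON",
]

DEFAULT_ANGLE_WEIGHT = 0.5   # Å per degree in the cell feature vector
DEFAULT_MIN_COMMON = 20      # Pearson CC unstable below this overlap


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape must match ids")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance diagonal must be zero")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")


@dataclass
class ClusterResult:
    ids: list[str]
    linkage: np.ndarray          # scipy (n-1, 4) merge table
    threshold: float
    groups: list[list[str]]      # largest first
    names: list[str]             # disX-clsY, aligned with groups

    def group_of(self, dataset_id: str) -> str:
        for name, members in zip(self.names, self.groups):
            if dataset_id in members:
                return name
        raise KeyError(dataset_id)


@dataclass
class LaueScore:
    candidate: LaueGroup
    r_meas: float | None = None
    r_meas_ratio: float | None = None     # vs Friedel-only
    cc_half: float | None = None          # percent
    cc_significant: bool = False
    cc_vs_friedel: float | None = None    # candidate-merged vs Friedel-merged
    composite: float = -np.inf
    accepted: bool = False
    reason: str = ""


# ---------------------------------------------------------------------------
# Cell clustering
# ---------------------------------------------------------------------------

def niggli_reduce(cell: UnitCell) -> UnitCell:
    """Niggli-reduced primitive setting of a cell (via gemmi)."""
    import gemmi
    gv = gemmi.GruberVector(cell.to_gemmi(), None)
    gv.niggli_reduce()
    return UnitCell(*gv.cell_parameters())


def cell_distance_matrix(cells: list[UnitCell], ids: list[str] | None = None,
                         w_angle: float = DEFAULT_ANGLE_WEIGHT,
                         reduce: bool = True) -> DistanceMatrix:
    """Euclidean distance between cell feature vectors
    (a, b, c, w*alpha, w*beta, w*gamma) of Niggli-reduced cells."""
    if len(cells) < 2:
        raise ValueError("need at least two cells")
    if ids is None:
        ids = [str(i) for i in range(len(cells))]
    feats = []
    for cell in cells:
        c = niggli_reduce(cell) if reduce else cell
        feats.append([c.a, c.b, c.c,
                      w_angle * c.alpha, w_angle * c.beta, w_angle * c.gamma])
    feats = np.asarray(feats)
    diff = feats[:, None, :] - feats[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=2))
    return DistanceMatrix(ids=list(ids), d=d)


def _cut_and_name(ids: list[str], link: np.ndarray, threshold: float
                  ) -> tuple[list[list[str]], list[str]]:
    labels = hierarchy.fcluster(link, t=threshold, criterion="distance")
    groups: dict[int, list[str]] = {}
    for lab, ds in zip(labels, ids):
        groups.setdefault(int(lab), []).append(ds)
    # largest first; ties broken by first appearance for determinism
    ordered = sorted(groups.values(), key=lambda g: (-len(g), ids.index(g[0])))
    x = f"{threshold:g}"
    names = [f"dis{x}-cls{y}" for y in range(1, len(ordered) + 1)]
    return ordered, names


def cluster_cells(matrix: DistanceMatrix, threshold: float) -> ClusterResult:
    """Average-linkage clustering of the cell distance matrix, cut at
    ``threshold`` (same units as the distances, Å)."""
    link = hierarchy.linkage(squareform(matrix.d, checks=False),
                             method="average")
    groups, names = _cut_and_name(matrix.ids, link, threshold)
    return ClusterResult(ids=list(matrix.ids), linkage=link,
                         threshold=threshold, groups=groups, names=names)


# ---------------------------------------------------------------------------
# Laue-group estimation
# ---------------------------------------------------------------------------

def _merged_means(groups: EquivalentGroups) -> dict[tuple, float]:
    means = groups.group_means()
    return {tuple(hkl): float(m)
            for hkl, m in zip(groups.unique_hkl, means)}


def estimate_laue(record: DatasetRecord,
                  candidates: list[str] | None = None,
                  rmeas_ratio_max: float = 2.0,
                  cc_tolerance: float = 5.0,
                  seed: int = 17) -> list[LaueScore]:
    """Score candidate Laue groups for a dataset, best first.

    Four indicators per candidate: (1) Rmeas under the candidate,
    (2) its ratio to the Friedel-only Rmeas, (3) CC1/2 under the candidate
    with significance, (4) Pearson CC between candidate-merged and
    Friedel-only-merged mean intensities over common unique indices.
    A candidate is rejected when the Rmeas ratio exceeds
    ``rmeas_ratio_max`` or its CC1/2 is not significant; -1 (Friedel only)
    is the reference and always survives.  Survivors are ranked highest
    symmetry first among those whose CC1/2 is within ``cc_tolerance``
    percentage points of the best.
    """
    if candidates is None:
        candidates = list(LAUE_NAMES)
    if "-1" not in candidates:
        candidates = ["-1"] + list(candidates)
    ref = laue_operators("-1")
    ref_groups = group_equivalents(record.reflections, ref)
    try:
        rmeas_ref = r_meas(ref_groups)
    except StatisticUndefined:
        raise StatisticUndefined("Laue estimation needs multiply-observed "
                                 "Friedel pairs")
    ref_means = _merged_means(ref_groups)

    scores: list[LaueScore] = []
    for name in candidates:
        laue = laue_operators(name)
        score = LaueScore(candidate=laue)
        try:
            grp = group_equivalents(record.reflections, laue)
            score.r_meas = r_meas(grp)
            score.r_meas_ratio = (score.r_meas / rmeas_ref
                                  if rmeas_ref > 0 else 1.0)
        except StatisticUndefined:
            score.reason = "no multiply-observed groups under candidate"
            scores.append(score)
            continue
        try:
            score.cc_half, score.cc_significant = cc_half(grp, seed=seed)
        except StatisticUndefined:
            pass
        # indicator 4: agreement of candidate merge with Friedel-only merge
        cand_means = grp.group_means()
        cand_of_ref = map_to_asu(
            np.array(list(ref_means.keys()), dtype=np.int64), laue)
        lookup = {tuple(hkl): i for i, hkl in enumerate(grp.unique_hkl)}
        xs, ys = [], []
        for ref_hkl, cand_hkl in zip(ref_means, cand_of_ref):
            i = lookup.get(tuple(cand_hkl))
            if i is not None:
                xs.append(ref_means[ref_hkl])
                ys.append(cand_means[i])
        if len(xs) >= 3 and np.std(xs) > 0 and np.std(ys) > 0:
            score.cc_vs_friedel = float(np.corrcoef(xs, ys)[0, 1])

        if name == "-1":
            score.accepted = True
        elif score.r_meas_ratio is not None and \
                score.r_meas_ratio > rmeas_ratio_max:
            score.reason = (f"Rmeas ratio {score.r_meas_ratio:.2f} > "
                            f"{rmeas_ratio_max}")
        elif score.cc_half is None or not score.cc_significant:
            score.reason = "CC1/2 not significant under candidate"
        else:
            score.accepted = True
        scores.append(score)

    accepted = [s for s in scores if s.accepted and s.cc_half is not None]
    best_cc = max((s.cc_half for s in accepted), default=0.0)
    for s in scores:
        if s.accepted and s.cc_half is not None:
            within = s.cc_half >= best_cc - cc_tolerance
            s.composite = (1000.0 * s.candidate.order if within else 0.0) \
                + s.cc_half
        elif s.accepted:
            s.composite = 0.0
    scores.sort(key=lambda s: (-int(s.accepted), -s.composite))
    return scores


# ---------------------------------------------------------------------------
# Intensity-correlation clustering
# ---------------------------------------------------------------------------

def _encode(hkl: np.ndarray) -> np.ndarray:
    # pack (h,k,l) with |index| < 512 into one int64 key
    return ((hkl[:, 0] + 512) * 1048576 + (hkl[:, 1] + 512) * 1024
            + (hkl[:, 2] + 512))


def pairwise_cc_matrix(datasets: list[DatasetRecord], laue: LaueGroup,
                       min_common: int = DEFAULT_MIN_COMMON
                       ) -> CorrelationTable:
    """Pearson correlation of merged unique intensities for every dataset
    pair; pairs with fewer than ``min_common`` common uniques are NaN."""
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    keys, means = [], []
    for rec in datasets:
        grp = group_equivalents(rec.reflections, laue)
        keys.append(_encode(grp.unique_hkl))
        means.append(grp.group_means())
    n = len(datasets)
    cc = np.full((n, n), np.nan)
    np.fill_diagonal(cc, 1.0)
    n_common = np.zeros((n, n), dtype=np.int64)
    np.fill_diagonal(n_common, [len(k) for k in keys])
    for i in range(n):
        for j in range(i + 1, n):
            common, ia, ib = np.intersect1d(keys[i], keys[j],
                                            return_indices=True)
            n_common[i, j] = n_common[j, i] = len(common)
            if len(common) < min_common:
                continue
            x, y = means[i][ia], means[j][ib]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            cc[i, j] = cc[j, i] = float(np.corrcoef(x, y)[0, 1])
    return CorrelationTable([d.dataset_id for d in datasets], cc, n_common)


def cc_cluster(table: CorrelationTable, threshold: float) -> ClusterResult:
    """Average-linkage clustering on d = sqrt(1 - CC^2) (CC clamped to
    [0, 1]; missing pairs imputed to the maximal distance 1)."""
    cc = np.clip(np.nan_to_num(table.cc, nan=0.0), 0.0, 1.0)
    d = np.sqrt(1.0 - cc ** 2)
    np.fill_diagonal(d, 0.0)
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    groups, names = _cut_and_name(table.dataset_ids, link, threshold)
    return ClusterResult(ids=list(table.dataset_ids), linkage=link,
                         threshold=threshold, groups=groups, names=names)
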