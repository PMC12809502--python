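"""Laue-group machinery.

Diffraction intensities obey the crystal point group plus Friedel inversion
— one of 11 Laue classes (12 named settings here, since the two trigonal
settings -3m1 and -31m act differently on hexagonal indices).  Operator
sets are built once by closure from hand-coded generators, with Friedel
inversion always included: every merging statistic in this package is a
Laue-group statistic and anomalous signal is ignored.

The canonical asymmetric-unit representative of an index is the
lexicographically greatest image under all operators — correct for every
group without per-group boundary tables.  Centring extinctions are applied
when enumerating the theoretically measurable unique set (the completeness
denominator).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .formats import DatasetRecord, UnitCell

__all__ = [
    "LaueGroup", "ReindexOp", "laue_operators", "laue_group_for_space_group",
    "map_to_asu", "reindex", "screen_absences", "count_theoretical_unique",
    "enumerate_unique", "LAUE_NAMES",
]

LAUE_NAMES = ("-1", "2/m", "mmm", "4/m", "4/mmm", "-3", "-3m1", "-31m",
              "6/m", "6/mmm", "m-3", "m-3m")

# Generators of the rotation part of each Laue class, acting on column
# vectors (h,k,l); -I is added before closure.  2/m uses unique axis b.
_GENERATORS: dict[str, list[list[list[int]]]] = {
    "-1":    [],
    "2/m":   [[[-1, 0, 0], [0, 1, 0], [0, 0, -1]]],
    "mmm":   [[[-1, 0, 0], [0, 1, 0], [0, 0, -1]],
              [[1, 0, 0], [0, -1, 0], [0, 0, -1]]],
    "4/m":   [[[0, -1, 0], [1, 0, 0], [0, 0, 1]]],
    "4/mmm": [[[0, -1, 0], [1, 0, 0], [0, 0, 1]],
              [[1, 0, 0], [0, -1, 0], [0, 0, -1]]],
    "-3":    [[[0, -1, 0], [1, -1, 0], [0, 0, 1]]],
    "-3m1":  [[[0, -1, 0], [1, -1, 0], [0, 0, 1]],
              [[0, 1, 0], [1, 0, 0], [0, 0, -1]]],
    "-31m":  [[[0, -1, 0], [1, -1, 0], [0, 0, 1]],
              [[0, -1, 0], [-1, 0, 0], [0, 0, -1]]],
    "6/m":   [[[1, -1, 0], [1, 0, 0], [0, 0, 1]]],
    "6/mmm": [[[1, -1, 0], [1, 0, 0], [0, 0, 1]],
              [[0, 1, 0], [1, 0, 0], [0, 0, -1]]],
    "m-3":   [[[0, 0, 1], [1, 0, 0], [0, 1, 0]],
              [[-1, 0, 0], [0, 1, 0], [0, 0, -1]],
              [[1, 0, 0], [0, -1, 0], [0, 0, -1]]],
    "m-3m":  [[[0, 0, 1], [1, 0, 0], [0, 1, 0]],
              [[0, -1, 0], [1, 0, 0], [0, 0, 1]],
              [[1, 0, 0], [0, -1, 0], [0, 0, -1]]],
}

_EXPECTED_ORDER = {"-1": 2, "2/m": 4, "mmm": 8, "4/m": 8, "4/mmm": 16,
                   "-3": 6, "-3m1": 12, "-31m": 12, "6/m": 12, "6/mmm": 24,
                   "m-3": 24, "m-3m": 48}


@dataclass(frozen=True)
class LaueGroup:
    name: str
    operators: np.ndarray      # (n_ops, 3, 3) integer matrices on (h,k,l)
    centering: str = "P"

    @property
    def order(self) -> int:
        return len(self.operators)

    def with_centering(self, centering: str) -> "LaueGroup":
        if centering not in "PABCIFR":
            raise ValueError(f"unknown centring {centering!r}")
        return replace(self, centering=centering)

    def __repr__(self) -> str:  # pragma: no cover
        return f"LaueGroup({self.name!r}, |G|={self.order}, {self.centering})"


@dataclass(frozen=True)
class ReindexOp:
    """Unimodular change of basis acting on Miller indices."""

    matrix: tuple  # 3x3 nested tuple of ints

    def __post_init__(self) -> None:
        m = self.as_array()
        det = round(float(np.linalg.det(m)))
        if abs(det) != 1:
            raise ValueError(f"re-indexing matrix must have |det|=1, got {det}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=np.int64)

    def inverse(self) -> "ReindexOp":
        inv = np.linalg.inv(self.as_array())
        return ReindexOp(tuple(map(tuple, np.rint(inv).astype(np.int64))))

    @classmethod
    def identity(cls) -> "ReindexOp":
        return cls(((1, 0, 0), (0, 1, 0), (0, 0, 1)))


def _close_group(generators: list[np.ndarray]) -> np.ndarray:
    eye = np.eye(3, dtype=np.int64)
    ops = {eye.tobytes(): eye, (-eye).tobytes(): -eye}
    for g in generators:
        ops[g.tobytes()] = g
    changed = True
    while changed:
        changed = False
        current = list(ops.values())
        for a, b in itertools.product(current, current):
            c = a @ b
            key = c.tobytes()
            if key not in ops:
                ops[key] = c
                changed = True
    return np.stack(sorted(ops.values(), key=lambda m: tuple(m.ravel())))


@lru_cache(maxsize=None)
def _operators_cached(name: str) -> np.ndarray:
    if name not in _GENERATORS:
        raise ValueError(f"unknown Laue group {name!r}; "
                         f"supported: {', '.join(LAUE_NAMES)}")
    gens = [np.asarray(g, dtype=np.int64) for g in _GENERATORS[name]]
    ops = _close_group(gens)
    assert len(ops) == _EXPECTED_ORDER[name], \
        f"{name}: closure gave {len(ops)} operators"
    ops.setflags(write=False)
    return ops


def laue_operators(name: str, centering: str = "P") -> LaueGroup:
    """Full operator set (including Friedel inversion) of a Laue class."""
    return LaueGroup(name=name, operators=_operators_cached(name),
                     centering=centering)


def laue_group_for_space_group(number: int) -> LaueGroup:
    """Laue class and centring of space group 1–230 (hexagonal axes for
    trigonal/rhombohedral groups)."""
    import gemmi
    sg = gemmi.find_spacegroup_by_number(number)
    if sg is None:
        raise ValueError(f"unknown space group number {number}")
    name = sg.laue_str()
    if name == "-3m":
        # distinguish the two trigonal settings from the H-M symbol: the
        # secondary position after the 3 axis is '1' for -31m groups
        tokens = sg.hm.split()
        secondary = tokens[2] if len(tokens) > 2 else ""
        name = "-31m" if secondary.startswith("1") else "-3m1"
    centering = sg.centring_type()
    if centering == "H":
        centering = "R"
    return laue_operators(name, centering)


def map_to_asu(hkl: np.ndarray, laue: LaueGroup) -> np.ndarray:
    """Canonical (lexicographically greatest) symmetry image of each index.

    Accepts a single (3,) index or an (N, 3) array; vectorized over all
    group operators.
    """
    arr = np.asarray(hkl, dtype=np.int64)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    best = arr @ laue.operators[0].T
    for op in laue.operators[1:]:
        img = arr @ op.T
        better = (
            (img[:, 0] > best[:, 0])
            | ((img[:, 0] == best[:, 0]) & (img[:, 1] > best[:, 1]))
            | ((img[:, 0] == best[:, 0]) & (img[:, 1] == best[:, 1])
               & (img[:, 2] > best[:, 2]))
        )
        best[better] = img[better]
    return best[0] if single else best


def reindex(record: DatasetRecord, op: ReindexOp) -> DatasetRecord:
    """Apply a change of basis to every Miller index and to the unit cell.

    Intensities and sigmas are untouched.  With h' = M h, the real-space
    cell vectors transform as A' = A Mᵀ, which preserves every scattering
    vector.
    """
    m = op.as_array()
    new = record.copy()
    hkl = new.hkl_array() @ m.T
    new.reflections[["h", "k", "l"]] = hkl
    A = record.header.unit_cell.orthogonalization_matrix()
    Ap = A @ m.T.astype(float)
    G = Ap.T @ Ap
    a, b, c = np.sqrt(np.diag(G))
    alpha = np.degrees(np.arccos(G[1, 2] / (b * c)))
    beta = np.degrees(np.arccos(G[0, 2] / (a * c)))
    gamma = np.degrees(np.arccos(G[0, 1] / (a * b)))
    new.header.unit_cell = UnitCell(a, b, c, alpha, beta, gamma)
    return new


# ---------------------------------------------------------------------------
# Systematic absences
# ---------------------------------------------------------------------------

_AXIAL_CLASSES = {
    "h00": (0, lambda h, k, l: (k == 0) & (l == 0) & (h != 0)),
    "0k0": (1, lambda h, k, l: (h == 0) & (l == 0) & (k != 0)),
    "00l": (2, lambda h, k, l: (h == 0) & (k == 0) & (l != 0)),
}


def screen_absences(reflections, i_over_sigma_max: float = 2.0,
                    ratio_max: float = 0.1) -> dict:
    """Screen axial reflection classes for 2₁-screw systematic absences.

    For each of h00, 0k0, 00l the odd-index (candidate-absent) and
    even-index (candidate-present) observations are compared by mean I/σ.
    Verdict ``"absent"`` requires the odd class to be weak both absolutely
    (mean I/σ < ``i_over_sigma_max``) and relative to the even class
    (< ``ratio_max`` of its mean I/σ).  An empty class yields
    ``"insufficient data"`` — never a guess.
    """
    h = reflections["h"].to_numpy(dtype=np.int64)
    k = reflections["k"].to_numpy(dtype=np.int64)
    l = reflections["l"].to_numpy(dtype=np.int64)
    i_sig = reflections["intensity"].to_numpy() / reflections["sigma"].to_numpy()
    report = {}
    for cls, (axis_idx, selector) in _AXIAL_CLASSES.items():
        mask = selector(h, k, l)
        idx = (h, k, l)[axis_idx][mask]
        vals = i_sig[mask]
        odd = vals[np.abs(idx) % 2 == 1]
        even = vals[np.abs(idx) % 2 == 0]
        if odd.size == 0 or even.size == 0:
            report[cls] = {"verdict": "insufficient data",
                           "n_odd": int(odd.size), "n_even": int(even.size)}
            continue
        mean_odd = float(np.mean(odd))
        mean_even = float(np.mean(even))
        absent = (mean_odd < i_over_sigma_max
                  and mean_even > 0
                  and mean_odd < ratio_max * mean_even)
        report[cls] = {
            "verdict": "absent" if absent else "present",
            "mean_i_over_sigma_odd": mean_odd,
            "mean_i_over_sigma_even": mean_even,
            "n_odd": int(odd.size), "n_even": int(even.size),
        }
    return report


# ---------------------------------------------------------------------------
# Theoretical unique set
# ---------------------------------------------------------------------------

def _centering_allowed(hkl: np.ndarray, centering: str) -> np.ndarray:
    h, k, l = hkl[:, 0], hkl[:, 1], hkl[:, 2]
    if centering == "P":
        return np.ones(len(hkl), dtype=bool)
    if centering == "A":
        return (k + l) % 2 == 0
    if centering == "B":
        return (h + l) % 2 == 0
    if centering == "C":
        return (h + k) % 2 == 0
    if centering == "I":
        return (h + k + l) % 2 == 0
    if centering == "F":
        return ((h + k) % 2 == 0) & ((k + l) % 2 == 0)
    if centering == "R":  # hexagonal axes, obverse setting
        return (-h + k + l) % 3 == 0
    raise ValueError(f"unknown centring {centering!r}")


def enumerate_unique(cell: UnitCell, laue: LaueGroup,
                     d_max: float, d_min: float) -> np.ndarray:
    """All distinct asu representatives with d in [d_min, d_max].

    Excludes (0,0,0) and centring-extinct indices.  Index bounds follow
    from |h| ≤ a/d (projection of the scattering vector on each cell
    vector), exact for any triclinic cell.
    """
    if not d_max > d_min > 0:
        raise ValueError(f"invalid resolution window ({d_max}, {d_min})")
    hmax = int(cell.a / d_min) + 1
    kmax = int(cell.b / d_min) + 1
    lmax = int(cell.c / d_min) + 1
    grid = np.mgrid[-hmax:hmax + 1, -kmax:kmax + 1, -lmax:lmax + 1]
    hkl = grid.reshape(3, -1).T.astype(np.int64)
    hkl = hkl[hkl.any(axis=1)]
    d = cell.d_spacing(hkl)
    hkl = hkl[(d >= d_min) & (d <= d_max)]
    hkl = hkl[_centering_allowed(hkl, laue.centering)]
    if len(hkl) == 0:
        return hkl.reshape(0, 3)
    return np.unique(map_to_asu(hkl, laue), axis=0)


def count_theoretical_unique(cell: UnitCell, laue: LaueGroup,
                             d_max: float, d_min: float) -> int:
    """Size of the theoretically measurable unique set — the completeness
    denominator."""
    return len(enumerate_unique(cell, laue, d_max, d_min))
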