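"""On-disk artefacts of the reduction pipeline.

Readers and writers for the four file families the pipeline touches:

* XDS_ASCII-style unmerged/merged reflection files (``!``-prefixed header
  with ``ITEM_`` column declarations followed by whitespace-separated
  records),
* the inter-dataset correlation block of an XSCALE.LP log,
* SMV (ADSC) images: a brace-delimited text header padded to a multiple of
  512 bytes followed by a 16-bit unsigned pixel block,
* CSV summary tables mirroring the per-dataset indicator spreadsheet.

Reflections are held as a :class:`pandas.DataFrame` with columns
``h, k, l, intensity, sigma, frame`` — the canonical in-memory container
for every statistic downstream.
"""

from __future__ import annotations

import io
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("edbatch")

REFLECTION_COLUMNS = ["h", "k", "l", "intensity", "sigma", "frame"]

#: fixed column order of the summary CSV (the xdsrunner-table analogue)
SUMMARY_COLUMNS = [
    "dataset_id", "space_group", "a", "b", "c", "alpha", "beta", "gamma",
    "volume", "isa", "r_meas", "cc_half", "completeness", "resolution",
]


class FormatError(ValueError):
    """A file does not conform to its declared on-disk format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Triclinic unit cell: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError(f"cell lengths must be positive: {self}")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angles must lie in (0, 180): {self}")
        # metric tensor must be positive definite
        if self._cos_term() <= 0:
            raise ValueError(f"degenerate cell (non-positive metric): {self}")

    def _cos_term(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        return 1 - ca * ca - cb * cb - cg * cg + 2 * ca * cb * cg

    @property
    def volume(self) -> float:
        """Closed-form triclinic volume in Å³."""
        return self.a * self.b * self.c * math.sqrt(self._cos_term())

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    def orthogonalization_matrix(self) -> np.ndarray:
        """3x3 matrix whose columns are the cell vectors a, b, c (Å)."""
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        cz = math.sqrt(max(self._cos_term(), 0.0)) / sg
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * cz],
        ])

    def reciprocal_metric(self) -> np.ndarray:
        """Reciprocal-space metric G*; 1/d² = hᵀ G* h."""
        A = self.orthogonalization_matrix()
        G = A.T @ A
        return np.linalg.inv(G)

    def d_spacing(self, hkl: np.ndarray) -> np.ndarray:
        """Resolution d (Å) for an (N, 3) array of Miller indices."""
        hkl = np.atleast_2d(np.asarray(hkl, dtype=float))
        inv_d2 = np.einsum("ni,ij,nj->n", hkl, self.reciprocal_metric(), hkl)
        with np.errstate(divide="ignore"):
            return 1.0 / np.sqrt(inv_d2)

    @classmethod
    def from_gemmi(cls, cell) -> "UnitCell":
        return cls(cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)

    def to_gemmi(self):
        import gemmi
        return gemmi.UnitCell(*self.parameters)


@dataclass
class DatasetHeader:
    """Experiment metadata carried by a reflection file."""

    unit_cell: UnitCell
    space_group_number: int = 1
    wavelength: float = 0.0251          # Å (200 kV electrons)
    oscillation_per_frame: float = 0.23  # degrees/frame
    frame_range: tuple[int, int] = (1, 1)
    detector_distance: float = 958.0    # mm
    pixel_size: float = 0.055           # mm
    beam_center: tuple[float, float] = (0.0, 0.0)  # pixels
    rotation_axis_azimuth: float = 0.0  # degrees in the detector plane
    extra: dict = field(default_factory=dict)  # unknown keys, kept for round-trip

    def __post_init__(self) -> None:
        if not 1 <= self.space_group_number <= 230:
            raise ValueError(f"space group number out of range: {self.space_group_number}")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.oscillation_per_frame == 0:
            raise ValueError("oscillation per frame must be non-zero")
        if self.frame_range[1] < self.frame_range[0]:
            raise ValueError(f"empty frame range: {self.frame_range}")


@dataclass
class DatasetRecord:
    """One processed dataset: header, unmerged reflections, optional summary."""

    dataset_id: str
    header: DatasetHeader
    reflections: pd.DataFrame
    merged: bool = False
    frameless: bool = False   # no per-observation rotation coordinate
    summary: "SummaryRow | None" = None

    def __post_init__(self) -> None:
        validate_reflections(self.reflections)

    @property
    def n_obs(self) -> int:
        return len(self.reflections)

    def hkl_array(self) -> np.ndarray:
        return self.reflections[["h", "k", "l"]].to_numpy(dtype=np.int64)

    def copy(self) -> "DatasetRecord":
        return replace(self, header=replace(self.header),
                       reflections=self.reflections.copy(),
                       summary=self.summary)


@dataclass
class SummaryRow:
    """Per-dataset quality indicators; ``None`` marks an indicator that could
    not be computed (never silently zero)."""

    dataset_id: str
    space_group_number: int | None = None
    unit_cell: UnitCell | None = None
    isa: float | None = None
    r_meas: float | None = None            # fraction
    cc_half: float | None = None           # percent
    completeness: float | None = None      # percent
    resolution_estimate: float | None = None  # Å

    @property
    def volume(self) -> float | None:
        return self.unit_cell.volume if self.unit_cell is not None else None


@dataclass
class CorrelationTable:
    """Pairwise intensity correlations between datasets.

    ``cc`` is symmetric with unit diagonal; entries that could not be
    computed (insufficient common reflections) are NaN, never 0.
    """

    dataset_ids: list[str]
    cc: np.ndarray
    n_common: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.dataset_ids)
        self.cc = np.asarray(self.cc, dtype=float)
        self.n_common = np.asarray(self.n_common, dtype=np.int64)
        if self.cc.shape != (n, n) or self.n_common.shape != (n, n):
            raise ValueError("correlation matrices must be square over dataset_ids")
        if not np.allclose(np.diag(self.cc), 1.0, equal_nan=False):
            raise ValueError("correlation diagonal must be 1")
        finite = np.isfinite(self.cc)
        if not np.array_equal(finite, finite.T) or not np.allclose(
                self.cc[finite & finite.T], self.cc.T[finite & finite.T]):
            raise ValueError("correlation matrix must be symmetric")


@dataclass
class SmvImage:
    """SMV (ADSC) image: text header block + unsigned 16-bit pixels."""

    header: dict
    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("SMV pixel block must be 2-D")


def validate_reflections(df: pd.DataFrame) -> None:
    missing = [c for c in REFLECTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"reflection table lacks columns {missing}")
    if len(df) == 0:
        return
    bad_sigma = np.flatnonzero(~(df["sigma"].to_numpy() > 0))
    if bad_sigma.size:
        raise FormatError(f"sigma must be > 0 (first bad row: {bad_sigma[0]})")
    hkl = df[["h", "k", "l"]].to_numpy()
    zero = np.flatnonzero(~hkl.any(axis=1))
    if zero.size:
        raise FormatError(f"(0,0,0) index not allowed (first bad row: {zero[0]})")


# ---------------------------------------------------------------------------
# XDS_ASCII reflection files
# ---------------------------------------------------------------------------

_MANDATORY_ITEMS = ("H", "K", "L", "IOBS", "SIGMA(IOBS)")


def read_xds_ascii(path: str | Path) -> DatasetRecord:
    """Parse an XDS_ASCII-style reflection file.

    Column layout is taken solely from the ``!ITEM_*=`` declarations, so
    permuted columns parse identically.  Records after ``!END_OF_DATA`` are
    ignored with a warning (acquisition software frequently appends junk).
    """
    path = Path(path)
    header_keys: dict[str, str] = {}
    items: dict[str, int] = {}
    data_lines: list[tuple[int, str]] = []
    in_data = False
    ended = False
    trailing = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("!"):
                body = line[1:].strip()
                if body == "END_OF_HEADER":
                    in_data = True
                    continue
                if body == "END_OF_DATA":
                    ended = True
                    continue
                if "=" in body and not in_data:
                    # a line may carry several KEY=VALUE pairs (ORGX/ORGY style)
                    for key, value in _split_header_pairs(body):
                        if key.startswith("ITEM_"):
                            items[key[5:]] = int(value)
                        else:
                            header_keys[key] = value
                continue
            if ended:
                trailing += 1
                continue
            if not in_data:
                raise FormatError(f"{path}: data record before END_OF_HEADER "
                                  f"at line {lineno}")
            data_lines.append((lineno, line))
    if trailing:
        warnings.warn(f"{path}: ignored {trailing} line(s) after END_OF_DATA",
                      stacklevel=2)

    for name in _MANDATORY_ITEMS:
        if name not in items:
            raise FormatError(f"{path}: missing mandatory !ITEM_{name} declaration")

    ncol = int(header_keys.get("NUMBER_OF_ITEMS_IN_EACH_DATA_RECORD",
                              max(items.values())))
    rows = np.empty((len(data_lines), ncol))
    for i, (lineno, line) in enumerate(data_lines):
        parts = line.split()
        if len(parts) < ncol:
            raise FormatError(f"{path}: line {lineno}: expected {ncol} fields, "
                              f"got {len(parts)}")
        try:
            rows[i] = [float(p) for p in parts[:ncol]]
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: non-numeric record "
                              f"({exc})") from None

    col = {name: items[name] - 1 for name in items}
    frameless = "ZD" not in items
    merged = header_keys.get("MERGE", "FALSE").upper() == "TRUE"
    header = _header_from_keys(header_keys)
    if rows.shape[0]:
        df = pd.DataFrame({
            "h": rows[:, col["H"]].astype(np.int64),
            "k": rows[:, col["K"]].astype(np.int64),
            "l": rows[:, col["L"]].astype(np.int64),
            "intensity": rows[:, col["IOBS"]],
            "sigma": rows[:, col["SIGMA(IOBS)"]],
        })
        if frameless:
            df["frame"] = 0.5 * (header.frame_range[0] + header.frame_range[1])
        else:
            df["frame"] = rows[:, col["ZD"]]
    else:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in REFLECTION_COLUMNS})
    dataset_id = header_keys.get("DATASET_ID", path.stem)
    if frameless and not merged:
        logger.info("%s: no ZD column; dataset flagged frameless", path)
    return DatasetRecord(dataset_id=dataset_id, header=header, reflections=df,
                         merged=merged, frameless=frameless)


def _split_header_pairs(body: str) -> list[tuple[str, str]]:
    # "ORGX=  255.00  ORGY=  255.00" → [("ORGX","255.00"), ("ORGY","255.00")]
    tokens = body.split("=")
    if len(tokens) == 2:
        return [(tokens[0].strip().lstrip("!"), tokens[1].strip())]
    pairs = []
    key = tokens[0].strip()
    for chunk in tokens[1:-1]:
        parts = chunk.rsplit(None, 1)
        if len(parts) != 2:
            return [(key.lstrip("!"), "=".join(tokens[1:]).strip())]
        pairs.append((key.lstrip("!"), parts[0].strip()))
        key = parts[1].strip()
    pairs.append((key.lstrip("!"), tokens[-1].strip()))
    return pairs


_KNOWN_HEADER_KEYS = {
    "FORMAT", "MERGE", "FRIEDEL'S_LAW", "SPACE_GROUP_NUMBER",
    "UNIT_CELL_CONSTANTS", "X-RAY_WAVELENGTH", "OSCILLATION_RANGE",
    "DATA_RANGE", "DETECTOR_DISTANCE", "QX", "QY", "ORGX", "ORGY",
    "ROTATION_AXIS_AZIMUTH", "DATASET_ID",
    "NUMBER_OF_ITEMS_IN_EACH_DATA_RECORD",
}


def _header_from_keys(keys: dict[str, str]) -> DatasetHeader:
    cell_vals = [float(x) for x in keys.get(
        "UNIT_CELL_CONSTANTS", "10 10 10 90 90 90").split()]
    rng = keys.get("DATA_RANGE", "1 1").split()
    extra = {k: v for k, v in keys.items() if k not in _KNOWN_HEADER_KEYS}
    return DatasetHeader(
        unit_cell=UnitCell(*cell_vals),
        space_group_number=int(keys.get("SPACE_GROUP_NUMBER", 1)),
        wavelength=float(keys.get("X-RAY_WAVELENGTH", 0.0251)),
        oscillation_per_frame=float(keys.get("OSCILLATION_RANGE", 0.23)),
        frame_range=(int(rng[0]), int(rng[1])),
        detector_distance=float(keys.get("DETECTOR_DISTANCE", 958.0)),
        pixel_size=float(keys.get("QX", 0.055)),
        beam_center=(float(keys.get("ORGX", 0.0)), float(keys.get("ORGY", 0.0))),
        rotation_axis_azimuth=float(keys.get("ROTATION_AXIS_AZIMUTH", 0.0)),
        extra=extra,
    )


def write_xds_ascii(record: DatasetRecord, path: str | Path,
                    merged: bool | None = None) -> None:
    """Write a reflection file re-readable by :func:`read_xds_ascii`.

    ``merged=True`` sets the MERGE header key and drops the frame column.
    """
    if merged is None:
        merged = record.merged
    validate_reflections(record.reflections)
    h = record.header
    lines = [
        f"!FORMAT=XDS_ASCII    MERGE={'TRUE' if merged else 'FALSE'}"
        "    FRIEDEL'S_LAW=TRUE",
        f"!SPACE_GROUP_NUMBER= {h.space_group_number}",
        "!UNIT_CELL_CONSTANTS= " + " ".join(
            f"{v:10.4f}" for v in h.unit_cell.parameters),
        f"!X-RAY_WAVELENGTH= {h.wavelength:.6f}",
        f"!OSCILLATION_RANGE= {h.oscillation_per_frame:.6f}",
        f"!DATA_RANGE= {h.frame_range[0]} {h.frame_range[1]}",
        f"!DETECTOR_DISTANCE= {h.detector_distance:.2f}",
        f"!QX= {h.pixel_size:.6f}  !QY= {h.pixel_size:.6f}",
        f"!ORGX= {h.beam_center[0]:.2f}  !ORGY= {h.beam_center[1]:.2f}",
        f"!ROTATION_AXIS_AZIMUTH= {h.rotation_axis_azimuth:.4f}",
        f"!DATASET_ID= {record.dataset_id}",
    ]
    for key, value in h.extra.items():
        lines.append(f"!{key}= {value}")
    ncol = 5 if merged else 6
    lines.append(f"!NUMBER_OF_ITEMS_IN_EACH_DATA_RECORD={ncol}")
    for i, name in enumerate(_MANDATORY_ITEMS, start=1):
        lines.append(f"!ITEM_{name}={i}")
    if not merged:
        lines.append("!ITEM_ZD=6")
    lines.append("!END_OF_HEADER")

    df = record.reflections
    out = io.StringIO()
    out.write("\n".join(lines) + "\n")
    for row in df.itertuples(index=False):
        out.write(f"{int(row.h):5d}{int(row.k):5d}{int(row.l):5d}"
                  f" {row.intensity:13.4e} {row.sigma:13.4e}")
        if not merged:
            out.write(f" {row.frame:9.2f}")
        out.write("\n")
    out.write("!END_OF_DATA\n")
    Path(path).write_text(out.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# XSCALE.LP correlation block
# ---------------------------------------------------------------------------

def read_xscale_lp_correlations(path: str | Path) -> CorrelationTable:
    """Extract the inter-dataset correlation table from an XSCALE.LP log.

    The block lists one row per dataset pair: ``#i  #j  n_common  cc``.
    Pairs absent from the block are left NaN (insufficient overlap).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8", errors="replace")
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if "CORRELATIONS BETWEEN INPUT DATA SETS" in line:
            start = i
            break
    if start is None:
        raise FormatError(f"{path}: correlation block not found")

    pairs: dict[tuple[int, int], tuple[int, float]] = {}
    seen_rows = False
    for line in lines[start + 1:]:
        parts = line.split()
        if len(parts) >= 4:
            try:
                i, j, n = int(parts[0]), int(parts[1]), int(parts[2])
                cc = float(parts[3])
            except ValueError:
                if seen_rows:
                    break
                continue
            key = (min(i, j), max(i, j))
            if key in pairs and not math.isclose(pairs[key][1], cc,
                                                 abs_tol=1e-9):
                raise FormatError(f"{path}: conflicting CC for pair {key}: "
                                  f"{pairs[key][1]} vs {cc}")
            pairs[key] = (n, cc)
            seen_rows = True
        elif seen_rows and line.strip():
            break
    if not pairs:
        raise FormatError(f"{path}: correlation block contains no pair rows")

    labels = sorted({i for p in pairs for i in p})
    index = {lab: k for k, lab in enumerate(labels)}
    n = len(labels)
    cc = np.full((n, n), np.nan)
    np.fill_diagonal(cc, 1.0)
    n_common = np.zeros((n, n), dtype=np.int64)
    for (i, j), (cnt, val) in pairs.items():
        a, b = index[i], index[j]
        cc[a, b] = cc[b, a] = val
        n_common[a, b] = n_common[b, a] = cnt
    return CorrelationTable([str(lab) for lab in labels], cc, n_common)


# ---------------------------------------------------------------------------
# SMV images
# ---------------------------------------------------------------------------

def read_smv(path: str | Path) -> SmvImage:
    """Read an SMV image (text header + uint16 pixel block)."""
    path = Path(path)
    raw = path.read_bytes()
    if not raw.startswith(b"{"):
        raise FormatError(f"{path}: SMV header must start with '{{'")
    brace_end = raw.find(b"}")
    if brace_end < 0:
        raise FormatError(f"{path}: unterminated SMV header")
    header: dict[str, str] = {}
    for line in raw[1:brace_end].decode("ascii", errors="replace").splitlines():
        line = line.strip()
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        header[key.strip()] = value.strip().rstrip(";")
    try:
        header_bytes = int(header["HEADER_BYTES"])
        size1, size2 = int(header["SIZE1"]), int(header["SIZE2"])
    except KeyError as exc:
        raise FormatError(f"{path}: missing SMV key {exc}") from None
    byte_order = header.get("BYTE_ORDER", "little_endian")
    dtype = "<u2" if byte_order == "little_endian" else ">u2"
    expected = size1 * size2 * 2
    block = raw[header_bytes:header_bytes + expected]
    if len(block) != expected:
        raise IOError(f"{path}: truncated pixel block: expected {expected} "
                      f"bytes, got {len(block)}")
    # SIZE1 = fast (x) dimension, SIZE2 = slow (y): array shape (SIZE2, SIZE1)
    pixels = np.frombuffer(block, dtype=dtype).reshape(size2, size1)
    return SmvImage(header=header, pixels=pixels.astype(np.uint16))


def write_smv(image: SmvImage, path: str | Path) -> None:
    """Write SMV in the 512-byte-padded dialect, little-endian.

    Pixel values above 65535 are clamped, with the clamp count logged.
    """
    pixels = np.asarray(image.pixels)
    over = int(np.count_nonzero(pixels > 65535))
    if over:
        logger.warning("write_smv: clamping %d pixel(s) above 65535", over)
        pixels = np.minimum(pixels, 65535)
    pixels = pixels.astype("<u2")

    header = dict(image.header)
    header["SIZE1"] = str(pixels.shape[1])
    header["SIZE2"] = str(pixels.shape[0])
    header["BYTE_ORDER"] = "little_endian"
    header["TYPE"] = header.get("TYPE", "unsigned_short")
    header.pop("HEADER_BYTES", None)

    def render(hbytes: int) -> bytes:
        lines = ["{", f"HEADER_BYTES={hbytes:5d};"]
        lines += [f"{k}={v};" for k, v in header.items()]
        lines.append("}")
        body = ("\n".join(lines) + "\n").encode("ascii")
        return body

    hbytes = 512
    while len(render(hbytes)) > hbytes:
        hbytes += 512
    body = render(hbytes)
    padded = body + b"\0" * (hbytes - len(body))
    Path(path).write_bytes(padded + pixels.tobytes())


# ---------------------------------------------------------------------------
# Summary CSV
# ---------------------------------------------------------------------------

def summary_to_frame(rows: Sequence[SummaryRow]) -> pd.DataFrame:
    """Summary rows as a DataFrame in the canonical column order."""
    records = []
    for r in rows:
        cell = r.unit_cell
        records.append({
            "dataset_id": r.dataset_id,
            "space_group": r.space_group_number,
            "a": None if cell is None else round(cell.a, 4),
            "b": None if cell is None else round(cell.b, 4),
            "c": None if cell is None else round(cell.c, 4),
            "alpha": None if cell is None else round(cell.alpha, 4),
            "beta": None if cell is None else round(cell.beta, 4),
            "gamma": None if cell is None else round(cell.gamma, 4),
            "volume": None if cell is None else round(cell.volume, 2),
            "isa": None if r.isa is None else round(r.isa, 2),
            "r_meas": None if r.r_meas is None else round(r.r_meas, 4),
            "cc_half": None if r.cc_half is None else round(r.cc_half, 2),
            "completeness": None if r.completeness is None
                            else round(r.completeness, 2),
            "resolution": None if r.resolution_estimate is None
                          else round(r.resolution_estimate, 2),
        })
    return pd.DataFrame(records, columns=SUMMARY_COLUMNS)


def write_summary_table(rows: Sequence[SummaryRow], path: str | Path) -> None:
    summary_to_frame(rows).to_csv(path, index=False)


def read_summary_table(path: str | Path) -> list[SummaryRow]:
    df = pd.read_csv(path)
    rows = []
    for rec in df.to_dict("records"):
        def val(key):
            v = rec.get(key)
            return None if v is None or (isinstance(v, float) and math.isnan(v)) else v
        cell = None
        if val("a") is not None:
            cell = UnitCell(rec["a"], rec["b"], rec["c"],
                            rec["alpha"], rec["beta"], rec["gamma"])
        sg = val("space_group")
        rows.append(SummaryRow(
            dataset_id=str(rec["dataset_id"]),
            space_group_number=None if sg is None else int(sg),
            unit_cell=cell,
            isa=val("isa"),
            r_meas=val("r_meas"),
            cc_half=val("cc_half"),
            completeness=val("completeness"),
            resolution_estimate=val("resolution"),
        ))
    return rows
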