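"""Real-time screening and merging of an acquisition directory.

A polling monitor watches a directory into which acquisition software
drops one sub-directory (or one reflection file) per dataset.  A dataset
is *complete* when its file set and sizes have not changed for a
quiescence interval, or when a sentinel file appears; each dataset is
processed exactly once.

Two modes mirror batch-pipeline stages:

* screening — per-dataset quality indicators only, no merging;
* merging — requires known cell and Laue group; each dataset passing the
  real-time filter (by default CC1/2 > 90% and ISa > 5) joins the valid
  set, the whole valid set is re-scaled and re-merged from scratch, and
  the merged completeness / CC1/2 / resolution are appended to an
  append-only history.  A stop condition fires when the merged
  completeness at the preset resolution reaches its target (default 95%).

State is persisted as a JSON sidecar so a crashed run resumes to the same
final statistics as an uninterrupted one.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .formats import DatasetRecord, SummaryRow, UnitCell, read_xds_ascii
from .merge_stats import (StatisticUndefined, bin_shells, cc_half,
                          completeness, dataset_summary, estimate_resolution,
                          group_equivalents)
from .scaling import FilterThresholds, fit_scales, merge
from .symmetry import LaueGroup, laue_operators

logger = logging.getLogger("edbatch")

__all__ = ["RealtimeConfig", "LiveState", "RealtimeMonitor",
           "detect_complete_datasets", "process_screening", "process_merging"]

SENTINEL_NAMES = ("COMPLETE", "collection_done.txt")


@dataclass
class RealtimeConfig:
    watch_dir: str
    mode: str = "screening"            # "screening" | "merging"
    poll_interval: float = 2.0         # s
    quiescence: float = 10.0           # s without file growth => complete
    cell: UnitCell | None = None       # required in merging mode
    laue_name: str | None = None       # required in merging mode
    thresholds: FilterThresholds = field(
        default_factory=FilterThresholds.realtime)
    stop_completeness: float = 95.0    # percent
    stop_resolution: float = 1.3       # Å, preset cutoff for the target
    low_res_limit: float = 20.0        # Å, inner bound of the stop window
    n_shells: int = 10
    seed: int = 17

    def __post_init__(self) -> None:
        if self.mode not in ("screening", "merging"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "merging" and (self.cell is None
                                       or self.laue_name is None):
            raise ValueError("merging mode requires known cell and Laue group")

    @property
    def laue(self) -> LaueGroup:
        return laue_operators(self.laue_name)


@dataclass
class LiveState:
    """Append-only record of a monitoring session."""

    seen: dict = field(default_factory=dict)       # path -> fingerprint info
    reported: list = field(default_factory=list)   # completed, in order
    valid: list = field(default_factory=list)      # paths passing the filter
    invalid: list = field(default_factory=list)    # [path, reason]
    rows: list = field(default_factory=list)       # serialized SummaryRows
    history: list = field(default_factory=list)    # per merge iteration
    stop_flagged: bool = False
    iteration: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "LiveState":
        return cls(**json.loads(text))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "LiveState":
        return cls.from_json(Path(path).read_text())


def _fingerprint(entry: Path) -> tuple:
    if entry.is_dir():
        files = sorted(p for p in entry.rglob("*") if p.is_file())
        return tuple((str(p.relative_to(entry)), p.stat().st_size)
                     for p in files)
    return (("", entry.stat().st_size),)


def _has_sentinel(entry: Path) -> bool:
    return entry.is_dir() and any((entry / s).exists() for s in SENTINEL_NAMES)


def detect_complete_datasets(watch_dir: str | Path, state: LiveState,
                             quiescence: float,
                             now: float | None = None) -> list[str]:
    """Newly completed dataset entries under ``watch_dir``, each reported
    exactly once.

    An entry is a sub-directory or a ``*.HKL`` file.  Completion =
    fingerprint (file names + sizes) unchanged for ``quiescence`` seconds,
    or a sentinel file present.
    """
    if now is None:
        now = time.monotonic()
    watch = Path(watch_dir)
    try:
        entries = sorted([p for p in watch.iterdir()
                          if p.is_dir() or p.suffix.upper() == ".HKL"])
    except OSError as exc:
        logger.warning("watch dir unreadable (%s); will retry", exc)
        return []
    new = []
    for entry in entries:
        key = str(entry)
        if key in state.reported:
            continue
        try:
            fp = list(map(list, _fingerprint(entry)))
        except OSError as exc:
            logger.warning("cannot stat %s (%s); will retry", entry, exc)
            continue
        info = state.seen.get(key)
        if _has_sentinel(entry):
            state.reported.append(key)
            new.append(key)
            continue
        if info is None or info["fp"] != fp:
            state.seen[key] = {"fp": fp, "stable_since": now}
            continue
        if now - info["stable_since"] >= quiescence:
            state.reported.append(key)
            new.append(key)
    return new


def _load_dataset(path: str) -> DatasetRecord:
    p = Path(path)
    if p.is_dir():
        hkls = sorted(p.glob("*.HKL")) + sorted(p.glob("*.hkl"))
        if not hkls:
            raise FileNotFoundError(f"{p}: no reflection file in dataset dir")
        return read_xds_ascii(hkls[0])
    return read_xds_ascii(p)


def _row_to_dict(row: SummaryRow) -> dict:
    return {
        "dataset_id": row.dataset_id,
        "space_group": row.space_group_number,
        "isa": row.isa, "r_meas": row.r_meas, "cc_half": row.cc_half,
        "completeness": row.completeness,
        "resolution": row.resolution_estimate,
    }


def process_screening(path: str, state: LiveState,
                      config: RealtimeConfig) -> SummaryRow:
    """Per-dataset indicators only; a failed dataset yields a row with
    missing fields and the batch continues."""
    try:
        rec = _load_dataset(path)
        laue = config.laue if config.laue_name else None
        row = dataset_summary(rec, laue=laue, n_shells=config.n_shells,
                              seed=config.seed)
    except Exception as exc:
        logger.warning("screening failed for %s: %s", path, exc)
        row = SummaryRow(dataset_id=Path(path).stem)
    state.rows.append(_row_to_dict(row))
    return row


def process_merging(path: str, state: LiveState,
                    config: RealtimeConfig) -> LiveState:
    """Admit the dataset if it passes the real-time filter, then re-scale
    and re-merge the whole valid set and append merged statistics to the
    history; evaluates the stop condition."""
    row = process_screening(path, state, config)
    t = config.thresholds
    reasons = []
    if row.cc_half is None or row.cc_half <= t.cc_half_min:
        reasons.append(f"CC1/2 not > {t.cc_half_min:g}")
    if row.isa is None or row.isa <= t.isa_min:
        reasons.append(f"ISa not > {t.isa_min:g}")
    if reasons:
        state.invalid.append([path, "; ".join(reasons)])
        return state
    state.valid.append(path)

    records = [_load_dataset(p) for p in state.valid]
    # force the known cell onto every record (merging mode contract)
    for rec in records:
        rec.header.unit_cell = config.cell
    laue = config.laue
    if len(records) >= 2:
        try:
            solution = fit_scales(records, laue)
        except ValueError as exc:
            logger.warning("scaling skipped: %s", exc)
            solution = None
    else:
        solution = None
    merged, shells = merge(records, solution, laue,
                           n_shells=config.n_shells, seed=config.seed)
    groups = group_equivalents(merged.reflections, laue)
    try:
        comp = completeness(groups, config.cell, laue,
                            config.low_res_limit, config.stop_resolution)
    except StatisticUndefined:
        comp = None
    pooled_groups = group_equivalents(
        pd.concat([r.reflections for r in records], ignore_index=True), laue)
    try:
        cc = cc_half(pooled_groups, seed=config.seed)[0]
    except StatisticUndefined:
        cc = None
    try:
        reso = estimate_resolution(shells)
    except StatisticUndefined:
        reso = None
    state.iteration += 1
    state.history.append({
        "iteration": state.iteration, "n_valid": len(state.valid),
        "completeness": comp, "cc_half": cc, "resolution": reso,
    })
    if comp is not None and comp >= config.stop_completeness:
        state.stop_flagged = True
        logger.info("stop condition met: completeness %.2f%% >= %.2f%% "
                    "at %.2f Å", comp, config.stop_completeness,
                    config.stop_resolution)
    return state


class RealtimeMonitor:
    """Polling monitor; the clock is injectable for deterministic tests."""

    def __init__(self, config: RealtimeConfig,
                 state: LiveState | None = None,
                 state_path: str | Path | None = None,
                 clock=time.monotonic) -> None:
        self.config = config
        self.clock = clock
        self.state_path = Path(state_path) if state_path else None
        if state is not None:
            self.state = state
        elif self.state_path and self.state_path.exists():
            self.state = LiveState.load(self.state_path)
            logger.info("resumed state: %d dataset(s) already processed",
                        len(self.state.reported))
        else:
            self.state = LiveState()

    def step(self, now: float | None = None) -> list[str]:
        """One poll: detect completed datasets and process them."""
        if now is None:
            now = self.clock()
        done = detect_complete_datasets(self.config.watch_dir, self.state,
                                        self.config.quiescence, now=now)
        for path in done:
            if self.config.mode == "merging":
                process_merging(path, self.state, self.config)
            else:
                process_screening(path, self.state, self.config)
        if done and self.state_path:
            self.state.save(self.state_path)
        return done

    def run(self, max_polls: int | None = None,
            stop_on_target: bool = True) -> LiveState:
        polls = 0
        while True:
            self.step()
            polls += 1
            if stop_on_target and self.state.stop_flagged:
                break
            if max_polls is not None and polls >= max_polls:
                break
            time.sleep(self.config.poll_interval)
        if self.state_path:
            self.state.save(self.state_path)
        return self.state
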