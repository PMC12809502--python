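"""Static HTML/CSV reporting.

The report directory mirrors the web-page report of the batch pipeline:
an ``index.html`` with the overall statistics table and three standard
panels (CC1/2, Rmeas/Rint and completeness against resolution), plus the
live-history plots for real-time runs.  Every number shown in the HTML is
rendered from the same DataFrame that is written to CSV, so the report
never contains report-only computation.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .merge_stats import ShellStats, shells_to_frame

__all__ = ["render_report"]

_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>edbatch report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; }}
td, th {{ border: 1px solid #999; padding: 2px 8px; text-align: right; }}
img {{ max-width: 640px; display: block; margin: 1em 0; }}
</style></head><body>
<h1>Data-reduction report</h1>
{summary_section}
{shell_section}
{history_section}
</body></html>
"""


def _plot_shells(df: pd.DataFrame, out_dir: Path) -> list[str]:
    per_shell = df[~df["overall"]].copy()
    if per_shell.empty:
        return []
    x = 1.0 / per_shell["d_min"] ** 2   # 1/d² axis, high resolution right
    made = []
    panels = [
        ("cc_half_vs_resolution.png", "CC1/2 vs resolution",
         [("cc_half", "CC1/2 (%)")]),
        ("r_factors_vs_resolution.png", "Rmeas and Rint vs resolution",
         [("r_meas", "Rmeas"), ("r_int", "Rint")]),
        ("completeness_vs_resolution.png", "Completeness vs resolution",
         [("completeness", "Completeness (%)")]),
    ]
    for fname, title, series in panels:
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for col, label in series:
            ax.plot(x, per_shell[col], "o-", label=label)
        ax.set_xlabel(r"1/d$^2$ (Å$^{-2}$)")
        ax.set_title(title)
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / fname, dpi=110)
        plt.close(fig)
        made.append(fname)
    return made


def _plot_history(df: pd.DataFrame, out_dir: Path) -> list[str]:
    made = []
    for col, fname, title in [
            ("completeness", "history_completeness.png",
             "Merged completeness per iteration"),
            ("cc_half", "history_cc_half.png", "Merged CC1/2 per iteration")]:
        if col not in df or df[col].dropna().empty:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.plot(df["iteration"], df[col], "o-")
        ax.set_xlabel("merge iteration")
        ax.set_title(title)
        fig.tight_layout()
        fig.savefig(out_dir / fname, dpi=110)
        plt.close(fig)
        made.append(fname)
    return made


def render_report(out_dir: str | Path,
                  shells: list[ShellStats] | None = None,
                  summary: pd.DataFrame | None = None,
                  history: pd.DataFrame | None = None) -> Path:
    """Write the report tree (HTML + CSV + PNG); returns the index path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if summary is not None and not summary.empty:
        summary.to_csv(out_dir / "summary.csv", index=False)
        summary_section = ("<h2>Per-dataset indicators</h2>"
                           + summary.to_html(index=False, na_rep=""))
    else:
        summary_section = "<h2>Per-dataset indicators</h2><p>no data</p>"

    if shells:
        df = shells_to_frame(shells)
        df.to_csv(out_dir / "shells.csv", index=False)
        plots = _plot_shells(df, out_dir)
        overall = df[df["overall"]]
        shell_section = (
            "<h2>Merging statistics</h2>"
            + overall.to_html(index=False, na_rep="")
            + "<h2>Statistics against resolution</h2>"
            + df[~df["overall"]].to_html(index=False, na_rep="")
            + "".join(f'<img src="{p}" alt="{p}">' for p in plots))
    else:
        shell_section = "<h2>Merging statistics</h2><p>no data</p>"

    if history is not None and not history.empty:
        history.to_csv(out_dir / "history.csv", index=False)
        plots = _plot_history(history, out_dir)
        history_section = ("<h2>Live merging history</h2>"
                           + history.to_html(index=False, na_rep="")
                           + "".join(f'<img src="{p}" alt="{p}">'
                                     for p in plots))
    else:
        history_section = ""

    index = out_dir / "index.html"
    index.write_text(_PAGE.format(summary_section=summary_section,
                                  shell_section=shell_section,
                                  history_section=history_section),
                     encoding="utf-8")
    return index
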