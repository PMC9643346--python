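"""Cohort aggregation and reporting.

Collects per-specimen morphometry records into the cohort table (Average and
sample-SD rows, mirroring the published ten-bone reference table), verifies
the packaged reference fixture, and writes CSV/figure reports.  Full
precision is kept internally; the printed table's mixed per-column rounding
(lengths and diameters to 3 decimals, SD of length to 5) is applied only at
presentation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .morphometry import MorphometryRecord
from .planning import HeatMap

__all__ = ["CohortTable", "ReportError", "aggregate_table",
           "load_table1_fixture", "report", "records_to_frame"]

_TABLE_COLUMNS = ["rc_length", "diam_base", "diam_45", "diam_90", "rc_volume"]
_OPTIONAL_COLUMNS = ["nerve_space_volume", "shell_min_thickness"]
_FIXTURE_SHA256 = "dc7bbf4d9ba156261bf66a05e053a5f37d80b5469cd65344b90253d1b367d8c8"

#: printed decimals per column: values row / SD row
_PRESENT_DECIMALS = {"rc_length": (3, 5), "diam_base": (3, 3), "diam_45": (3, 3),
                     "diam_90": (3, 3), "rc_volume": (3, 3)}


class ReportError(ValueError):
    """Raised for invalid cohort-report inputs."""


@dataclass
class CohortTable:
    records: list[MorphometryRecord]
    average_row: dict[str, float]
    sd_row: dict[str, float]
    n: int

    def to_dataframe(self, rounded: bool = False) -> pd.DataFrame:
        """Per-specimen rows plus Average and SD rows (presentation rounding
        applied only when ``rounded``)."""
        df = records_to_frame(self.records)
        avg = {"specimen_id": "Average", **self.average_row}
        sd = {"specimen_id": "SD", **self.sd_row}
        out = pd.concat([df, pd.DataFrame([avg, sd])], ignore_index=True)
        if rounded:
            for col, (dec, dec_sd) in _PRESENT_DECIMALS.items():
                if col not in out.columns:
                    continue
                vals = out[col].astype(float)
                body = vals.iloc[:-1].round(dec)
                tail = pd.Series([round(vals.iloc[-1], dec_sd)], index=[len(out) - 1])
                out[col] = pd.concat([body, tail])
        return out


def records_to_frame(records: list[MorphometryRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows)
    drop = [c for c in df.columns
            if c not in ["specimen_id", *_TABLE_COLUMNS, *_OPTIONAL_COLUMNS, "dehiscent"]
            or df[c].isna().all()]
    return df.drop(columns=drop)


def aggregate_table(records: list[MorphometryRecord]) -> CohortTable:
    """Column means and sample SDs (n-1) over the cohort.

    Optional columns are aggregated only over the records where they are
    present.
    """
    if len(records) < 2:
        raise ReportError(f"need at least 2 records for an SD row, got {len(records)}")
    avg, sd = {}, {}
    for col in _TABLE_COLUMNS + _OPTIONAL_COLUMNS:
        vals = np.array([getattr(r, col) for r in records
                         if getattr(r, col) is not None], dtype=float)
        if len(vals) == 0:
            continue
        avg[col] = float(vals.mean())
        sd[col] = float(vals.std(ddof=1)) if len(vals) >= 2 else float("nan")
    return CohortTable(records=list(records), average_row=avg, sd_row=sd,
                       n=len(records))


def load_table1_fixture() -> list[MorphometryRecord]:
    """The packaged ten-bone reference table as morphometry records."""
    ref = resources.files("rcmorph").joinpath("data/table1.csv")
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise ReportError(
            f"reference table fixture is corrupted (sha256 {digest[:12]}...)")
    df = pd.read_csv(ref)
    return [MorphometryRecord(specimen_id=str(row.specimen_id),
                              rc_length=float(row.rc_length),
                              diam_base=float(row.diam_base),
                              diam_45=float(row.diam_45),
                              diam_90=float(row.diam_90),
                              rc_volume=float(row.rc_volume))
            for row in df.itertuples()]


def _heatmap_figure(heatmap: HeatMap, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.2))
    shown = np.ma.masked_invalid(heatmap.freq)
    im = ax.imshow(shown, cmap="hot", vmin=0.0, vmax=1.0)
    ax.set_xticks(range(4), ["1", "2", "3", "4"])
    ax.set_yticks(range(4), ["A", "B", "C", "D"])
    ax.set_xlabel("anterior -> posterior")
    ax.set_ylabel("superior -> inferior")
    for i in range(4):
        for j in range(4):
            if np.isnan(heatmap.freq[i, j]):
                txt = "n/a*"
            else:
                txt = f"{100 * heatmap.freq[i, j]:.0f}%"
                if heatmap.unsafe[i, j]:
                    txt += "!"
            ax.text(j, i, txt, ha="center", va="center", color="tab:blue")
    ax.set_title(f"Canal-hit frequency (n={heatmap.n_specimens}); "
                 f"'!' artery risk, '*' not evaluable")
    fig.colorbar(im, ax=ax, label="hit frequency")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def report(cohort_table: CohortTable, heatmap: HeatMap | None,
           out_dir: str | Path, run_meta: dict | None = None) -> dict[str, Path]:
    """Write the cohort CSV table, heat-map CSV/figure and a structured run log.

    Returns the mapping of artifact names to written paths.  Outputs are
    deterministic: identical inputs produce byte-identical CSVs.
    """
    from . import __version__

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ReportError(f"cannot create report directory {out_dir}: {exc}") from exc

    written: dict[str, Path] = {}
    table_path = out_dir / "cohort_table.csv"
    df = cohort_table.to_dataframe(rounded=False)
    last = len(df) - 1  # SD row
    for col, (dec, dec_sd) in _PRESENT_DECIMALS.items():
        if col not in df.columns:
            continue
        df[col] = [f"{v:.{dec_sd if i == last else dec}f}"
                   for i, v in enumerate(df[col].astype(float))]
    df.to_csv(table_path, index=False)
    written["cohort_table"] = table_path

    if heatmap is not None:
        hm_path = out_dir / "heatmap.csv"
        heatmap.to_dataframe().to_csv(hm_path)
        written["heatmap"] = hm_path
        fig_path = out_dir / "heatmap.png"
        _heatmap_figure(heatmap, fig_path)
        written["heatmap_figure"] = fig_path

    log = {
        "software": {"name": "rcmorph", "version": __version__},
        "n_specimens": cohort_table.n,
        "average_row": cohort_table.average_row,
        "sd_row": cohort_table.sd_row,
    }
    if heatmap is not None:
        log["heatmap"] = {
            "threshold": heatmap.threshold,
            "selected": sorted(heatmap.selected),
            "n_specimens": heatmap.n_specimens,
        }
    if run_meta:
        log["run"] = run_meta
    log_path = out_dir / "run_log.json"
    log_path.write_text(json.dumps(log, indent=2, sort_keys=True))
    written["run_log"] = log_path
    return written
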