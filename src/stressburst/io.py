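"""CSV/TIFF input and output.

All tables are comma-separated UTF-8 with a header row and "." decimals.
Traces travel in long format (one row per cell per frame); localization
tables use track_id/frame/x_px/y_px/intensity columns.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from stressburst.containers import CellTrace

__all__ = ["traces_to_frame", "frame_to_traces", "write_traces_csv",
           "read_traces_csv", "write_stack_tiff", "read_stack_tiff"]


def traces_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        n = tr.n_frames
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "frame": np.arange(n),
                    "time_min": tr.times,
                    "length_um": tr.lengths,
                    "total_intensity": tr.total_intensity
                    if tr.total_intensity is not None else np.nan,
                    "reporter_intensity": tr.reporter_intensity
                    if tr.reporter_intensity is not None else np.nan,
                    "area_px2": tr.area if tr.area is not None else np.nan,
                    "fate": tr.fate,
                    "truncation_time": tr.truncation_time
                    if tr.truncation_time is not None else np.nan,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[CellTrace]:
    traces = []
    for cell_id, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        has_col = grp.columns.__contains__
        tr = CellTrace(
            cell_id=int(cell_id),
            times=grp["time_min"].to_numpy(float),
            lengths=grp["length_um"].to_numpy(float),
        )
        for col, attr in (("total_intensity", "total_intensity"),
                          ("reporter_intensity", "reporter_intensity"),
                          ("area_px2", "area")):
            if has_col(col) and grp[col].notna().any():
                setattr(tr, attr, grp[col].to_numpy(float))
        if has_col("fate"):
            tr.fate = str(grp["fate"].iloc[0])
        if has_col("truncation_time"):
            tt = grp["truncation_time"].iloc[0]
            tr.truncation_time = None if pd.isna(tt) else float(tt)
        traces.append(tr)
    return traces


def write_traces_csv(traces: list[CellTrace], path: str | Path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[CellTrace]:
    return frame_to_traces(pd.read_csv(path))


def write_stack_tiff(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack))


def read_stack_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
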