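"""Delimited-text readers and writers for every pipeline artifact.

All tables are comma-separated UTF-8 with a header row and decimal points.
Writers are atomic: content goes to a temporary file in the target
directory which is renamed into place, so a failed run never leaves a
partial output behind.  Mesh files (PLY/STL/OFF) are handled in
:mod:`atriometry.mesh`.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .axes import LandmarkSet
from .stats import PairedMeasurements, summarize
from .volumetry import ContourStack, Slice, VolumeSeries

__all__ = [
    "atomic_write_text",
    "write_contour_stack",
    "read_contour_stack",
    "write_volume_series",
    "read_volume_series",
    "write_landmarks",
    "read_landmarks",
    "write_paired",
    "read_paired",
    "read_ratings_table",
    "write_cohort_summary",
]

_LANDMARK_NAMES = (
    "dorsal_la", "mitral_center_ed", "mitral_center_es", "lv_apex", "rv_lateral",
)


def atomic_write_text(path, text: str) -> None:
    """Write text to ``path`` via a temporary file and atomic rename."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_df(df: pd.DataFrame, path) -> None:
    atomic_write_text(path, df.to_csv(index=False))


# -- contour stacks ---------------------------------------------------------


def write_contour_stack(stack: ContourStack, path) -> None:
    df = pd.DataFrame({
        "slice_index": np.arange(len(stack)),
        "area_mm2": [s.area for s in stack.slices],
        "thickness_mm": [s.thickness for s in stack.slices],
        "gap_mm": [s.gap for s in stack.slices],
        "phase_label": [stack.phase_label] * len(stack),
    })
    _atomic_write_df(df, path)


def read_contour_stack(path) -> ContourStack:
    df = pd.read_csv(path)
    required = {"slice_index", "area_mm2", "thickness_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"contour table {path} is missing columns {sorted(missing)}")
    df = df.sort_values("slice_index")
    gaps = df["gap_mm"] if "gap_mm" in df else pd.Series(0.0, index=df.index)
    slices = tuple(
        Slice(area=float(a), thickness=float(t), gap=float(g))
        for a, t, g in zip(df["area_mm2"], df["thickness_mm"], gaps)
    )
    phase = str(df["phase_label"].iloc[0]) if "phase_label" in df and len(df) else ""
    return ContourStack(slices=slices, phase_label=phase)


# -- volume series ----------------------------------------------------------


def write_volume_series(series: VolumeSeries, path) -> None:
    df = pd.DataFrame({
        "frame": np.arange(len(series.volumes)),
        "volume_mL": series.volumes,
        "phase_label": [series.phase_label] * len(series.volumes),
    })
    _atomic_write_df(df, path)


def read_volume_series(path) -> VolumeSeries:
    df = pd.read_csv(path)
    if not {"frame", "volume_mL"} <= set(df.columns):
        raise ValueError(f"volume series {path} needs columns frame, volume_mL")
    df = df.sort_values("frame")
    phase = str(df["phase_label"].iloc[0]) if "phase_label" in df and len(df) else ""
    return VolumeSeries(volumes=tuple(df["volume_mL"].astype(float)),
                        phase_label=phase)


# -- landmarks ---------------------------------------------------------------


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    rows = [
        {"name": n, **dict(zip(("x_mm", "y_mm", "z_mm"), getattr(landmarks, n)))}
        for n in _LANDMARK_NAMES
    ]
    _atomic_write_df(pd.DataFrame(rows), path)


def read_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path)
    if not {"name", "x_mm", "y_mm", "z_mm"} <= set(df.columns):
        raise ValueError(f"landmark table {path} needs columns name, x_mm, y_mm, z_mm")
    points = {}
    for _, row in df.iterrows():
        points[str(row["name"])] = np.array(
            [row["x_mm"], row["y_mm"], row["z_mm"]], float
        )
    missing = set(_LANDMARK_NAMES) - set(points)
    if missing:
        raise ValueError(f"landmark table {path} is missing points {sorted(missing)}")
    return LandmarkSet(**{n: points[n] for n in _LANDMARK_NAMES})


# -- paired measurements / ratings ------------------------------------------


def write_paired(data: PairedMeasurements, path) -> None:
    """Long layout: subject_id, method_or_rater, value."""
    n = len(data)
    df = pd.DataFrame({
        "subject_id": list(range(1, n + 1)) * 2,
        "method_or_rater": [data.label_x] * n + [data.label_y] * n,
        "value": np.concatenate([data.x, data.y]),
    })
    _atomic_write_df(df, path)


def read_ratings_table(path) -> pd.DataFrame:
    """Ratings as a wide subjects x raters table.

    Accepts the long layout (subject_id, method_or_rater, value) or a wide
    layout where each non-subject column is one rater.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"subject_id", "method_or_rater", "value"} <= cols:
        wide = df.pivot(index="subject_id", columns="method_or_rater",
                        values="value")
        # keep raters in first-appearance order, not alphabetical
        wide = wide[list(dict.fromkeys(df["method_or_rater"]))]
        if wide.isna().any().any():
            raise ValueError(f"ratings table {path} is incomplete")
        return wide
    rater_cols = [c for c in df.columns if c != "subject_id"]
    if len(rater_cols) < 2:
        raise ValueError(f"ratings table {path} needs at least two rater columns")
    wide = df.set_index("subject_id")[rater_cols] if "subject_id" in cols \
        else df[rater_cols]
    if wide.isna().any().any():
        raise ValueError(f"ratings table {path} is incomplete")
    return wide


def read_paired(path, label_x: str | None = None,
                label_y: str | None = None) -> PairedMeasurements:
    """Two-rater paired measurements from a long or wide table."""
    wide = read_ratings_table(path)
    cols = list(wide.columns)
    if label_x is None or label_y is None:
        if len(cols) != 2:
            raise ValueError(
                f"table has raters {cols}; specify which two to pair"
            )
        label_x, label_y = cols
    return PairedMeasurements(
        x=wide[label_x].to_numpy(float),
        y=wide[label_y].to_numpy(float),
        label_x=str(label_x),
        label_y=str(label_y),
    )


# -- cohort summary report ---------------------------------------------------


def write_cohort_summary(table: pd.DataFrame, path,
                         normality_alpha: float = 0.05) -> pd.DataFrame:
    """Per-variable summary (mean ± SD or median (IQR)) of a cohort table.

    Numeric columns are summarized with the normality-gated rule; the
    resulting table is written as CSV and returned.
    """
    rows = []
    for col in table.columns:
        if not pd.api.types.is_numeric_dtype(table[col]):
            continue
        if col == "subject_id":
            continue
        s = summarize(table[col].to_numpy(float), normality_alpha)
        if s["form"] == "mean_sd":
            desc = f"{s['mean']:.1f} ± {s['sd']:.1f}"
        else:
            lo, hi = s["iqr"]
            desc = f"{s['median']:.1f} ({lo:.1f}–{hi:.1f})"
        rows.append({
            "variable": col,
            "summary": desc,
            "form": s["form"],
            "normality_p": s["normality_p"],
        })
    out = pd.DataFrame(rows)
    _atomic_write_df(out, path)
    return out
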