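"""Tabular helpers: BiFC normalisation and descriptive length statistics."""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["bifc_normalize", "length_stats"]

log = logging.getLogger(__name__)


def bifc_normalize(rois: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ROI BiFC ratio and per-condition medians.

    Expects columns ``vyfp`` and ``mcherry`` (mean intensities per ROI)
    and optionally ``condition``.  The BiFC signal is normalised for
    transfection level by dividing vYFP by the co-transfected mCherry;
    ROIs with non-positive mCherry are excluded with a warning.  The
    per-condition summary statistic is the median.
    """
    required = {"vyfp", "mcherry"}
    missing = required - set(rois.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rois = rois.copy()
    bad = rois["mcherry"] <= 0
    if bad.any():
        log.warning("excluding %d ROI(s) with non-positive mCherry",
                    int(bad.sum()))
        rois = rois[~bad]
    rois["bifc"] = rois["vyfp"] / rois["mcherry"]
    group = rois["condition"] if "condition" in rois.columns else pd.Series(
        "all", index=rois.index
    )
    summary = (
        rois.groupby(group)["bifc"]
        .agg(median="median", n="count")
        .reset_index(names="condition")
    )
    return rois, summary


def length_stats(lengths: Sequence[float]) -> dict[str, float]:
    """Descriptive statistics of a filament-length sample.

    Returns mean, sample SD (ddof=1; 0 for n=1), median and n — the
    summary layer applied to externally measured length lists.
    """
    arr = np.asarray(lengths, dtype=float)
    if arr.size == 0:
        raise ValueError("empty length list")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return {
        "mean": float(arr.mean()),
        "sd": sd,
        "median": float(np.median(arr)),
        "n": int(arr.size),
    }
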