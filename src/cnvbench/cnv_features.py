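"""Per-sample descriptive statistics of CNV call sets.

For each (sample, tool) call set: number of CNVs, median and cumulative
length, median marker count per CNV, median within-CNV inter-marker
distance, and the deletions-to-duplications ratio (DDR).  Summaries over
samples report median and inter-quartile range per tool (optionally per
population); inter-tool dispersion within an algorithm class is quantified
by the median absolute deviation (MAD).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CNClass, CallSet, MarkerMap

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "sample_id",
    "tool_id",
    "n_cnvs",
    "n_deletions",
    "n_duplications",
    "median_length",
    "cum_length",
    "median_markers",
    "median_intermarker_dist",
    "ddr",
]

#: Consistency scaling that makes the MAD estimate the standard deviation
#: under normality.
MAD_NORMAL_SCALE = 1.4826


def intermarker_distance(length: int, n_markers: int) -> float:
    """Mean within-CNV marker gap: span / (markers - 1).

    Defined only for CNVs containing at least two markers.
    """
    if n_markers < 2:
        raise ValueError("inter-marker distance requires >= 2 markers")
    return length / (n_markers - 1)


def per_sample_features(
    callset: CallSet, marker_map: MarkerMap | None = None
) -> dict[str, object]:
    """Compute one feature-table row for a standardized call set.

    Marker counts come from the calls themselves, or are recomputed from
    ``marker_map`` when provided.  CNVs with fewer than two markers are
    excluded from the inter-marker-distance median; if no marker information
    is available at all the distance and marker fields are reported missing.
    The DDR is missing (NaN) when there are no duplications.
    """
    row: dict[str, object] = {
        "sample_id": callset.sample_id,
        "tool_id": callset.tool_id,
        "n_cnvs": len(callset),
        "n_deletions": sum(1 for s in callset if s.cn_class is CNClass.LOSS),
        "n_duplications": sum(1 for s in callset if s.cn_class is CNClass.GAIN),
        "median_length": np.nan,
        "cum_length": 0,
        "median_markers": np.nan,
        "median_intermarker_dist": np.nan,
        "ddr": np.nan,
    }
    if len(callset) == 0:
        return row

    lengths = np.array([s.length for s in callset], dtype=float)
    row["median_length"] = float(np.median(lengths))
    row["cum_length"] = int(lengths.sum())

    if marker_map is not None:
        marker_counts = [
            marker_map.count_in(s.chrom, s.start, s.end) for s in callset
        ]
    else:
        marker_counts = [s.n_markers for s in callset]
    known = [c for c in marker_counts if c is not None]
    if known:
        row["median_markers"] = float(np.median(known))
        dists = [
            intermarker_distance(s.length, c)
            for s, c in zip(callset.segments, marker_counts)
            if c is not None and c >= 2
        ]
        if dists:
            row["median_intermarker_dist"] = float(np.median(dists))
    else:
        logger.info(
            "no marker information for (%s, %s); marker features absent",
            callset.sample_id,
            callset.tool_id,
        )

    n_del, n_dup = row["n_deletions"], row["n_duplications"]
    if n_dup > 0:
        row["ddr"] = n_del / n_dup
    return row


def feature_table(
    callsets: Iterable[CallSet], marker_map: MarkerMap | None = None
) -> pd.DataFrame:
    """Feature rows for many call sets, one row per (sample, tool)."""
    rows = [per_sample_features(cs, marker_map) for cs in callsets]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def summarize_over_samples(
    rows: pd.DataFrame,
    group_by: str | Sequence[str] = "tool_id",
    features: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Median and inter-quartile range of each feature per group.

    Returns a long-format table with columns (group keys, feature, median,
    q25, q75).  Empty groups are omitted with a warning.  Quantiles use
    linear interpolation between order statistics throughout the package.
    """
    if isinstance(group_by, str):
        group_by = [group_by]
    if features is None:
        features = [
            c
            for c in rows.columns
            if c not in ("sample_id", "tool_id", "population")
            and pd.api.types.is_numeric_dtype(rows[c])
        ]
    out = []
    for keys, grp in rows.groupby(list(group_by), dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        for feat in features:
            vals = grp[feat].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                logger.warning("group %s: no values for %s; omitted", keys, feat)
                continue
            out.append(
                dict(zip(group_by, keys))
                | {
                    "feature": feat,
                    "median": float(np.median(vals)),
                    "q25": float(np.quantile(vals, 0.25)),
                    "q75": float(np.quantile(vals, 0.75)),
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(out)


def mad(values: Sequence[float], scaling: float = MAD_NORMAL_SCALE) -> float:
    """Median absolute deviation from the median, times ``scaling``."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueError("MAD of an empty sequence")
    return float(scaling * np.median(np.abs(arr - np.median(arr))))


def group_dispersion(
    values_per_tool: Mapping[str, float],
    tool_classes: Mapping[str, str],
    scaling: float = MAD_NORMAL_SCALE,
) -> dict[str, float]:
    """MAD of a per-tool statistic within each algorithm class.

    ``values_per_tool`` maps tool id to its statistic (e.g. median CNV count
    per sample); ``tool_classes`` maps tool id to its algorithm class
    (e.g. "hmm" / "segmentation").  Each class needs at least two tools.
    """
    by_class: dict[str, list[float]] = {}
    for tool, value in values_per_tool.items():
        by_class.setdefault(tool_classes[tool], []).append(float(value))
    out: dict[str, float] = {}
    for cls, vals in by_class.items():
        if len(vals) < 2:
            raise ValueError(f"algorithm class {cls!r} has fewer than 2 tools")
        out[cls] = mad(vals, scaling=scaling)
    return out
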