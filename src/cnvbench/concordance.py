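"""Inter-tool concordance, multi-tool consensus and external verification.

Concordance between two callers is deliberately asymmetric: the *predictor*
tool's CNVs are checked against the *verifier* tool's same-class calls by
per-base coverage, so a fragmenting caller can fully verify a coarse caller
without the reverse holding.  Consensus regions are defined by base-pair
stacking depth: every base called in the same CN class by at least k tools
belongs to the consensus.  External verification checks calls against a
reference variant set (e.g. a DGV-style BED) with the same coverage rule.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CallSet,
    CallSetKey,
    GenomicSegment,
    VARIANT_CLASSES,
)
from .family_validation import ValidationRecord, coverage_fraction

logger = logging.getLogger(__name__)

CONCORDANCE_COLUMNS = [
    "predictor_tool",
    "verifier_tool",
    "median_pct_concordant_seq_per_cnv",
    "pct_verified_cnvs",
    "pct_verified_cumulated_seq",
]


def _passes(coverage: float, threshold: float, strict: bool) -> bool:
    return coverage > threshold if strict else coverage >= threshold


def pairwise_concordance(
    calls: Mapping[CallSetKey, CallSet],
    threshold: float = 0.9,
    strict: bool = True,
    restrict_to: Mapping[CallSetKey, Sequence[ValidationRecord]] | None = None,
) -> pd.DataFrame:
    """Asymmetric predictor/verifier concordance for every ordered tool pair.

    Per ordered pair (P, V) and per shared sample, each of P's CNVs receives
    the fraction of its sequence covered by V's same-class calls.  Reported
    per pair, each summarized as the median over samples:

    * the per-sample median per-CNV concordant-sequence percentage,
    * the per-sample percentage of P's CNVs verified (coverage > threshold),
    * the per-sample percentage of P's cumulated CNV sequence covered by V.

    With ``restrict_to`` (per-CNV validation records keyed like ``calls``)
    only family-validated predictor CNVs enter the comparison.
    """
    tools = sorted({tool for _, tool in calls})
    samples = sorted({sample for sample, _ in calls})
    if len(tools) < 2:
        raise ValueError("pairwise concordance needs at least 2 tools")

    validated_keys: dict[CallSetKey, set[tuple[int, int, int, str]]] | None = None
    if restrict_to is not None:
        validated_keys = {
            key: {
                r.segment.sort_key() for r in records if r.validated
            }
            for key, records in restrict_to.items()
        }

    rows = []
    for pred in tools:
        for verif in tools:
            per_sample_median: list[float] = []
            per_sample_pct_verified: list[float] = []
            per_sample_pct_seq: list[float] = []
            shared = 0
            for sample in samples:
                p_cs = calls.get((sample, pred))
                v_cs = calls.get((sample, verif))
                if p_cs is None or v_cs is None:
                    continue
                shared += 1
                segments = list(p_cs.segments)
                if validated_keys is not None:
                    keep = validated_keys.get((sample, pred), set())
                    segments = [s for s in segments if s.sort_key() in keep]
                if not segments:
                    continue
                covs = np.array(
                    [coverage_fraction(s, v_cs, same_class=True) for s in segments]
                )
                lengths = np.array([s.length for s in segments], dtype=float)
                per_sample_median.append(100.0 * float(np.median(covs)))
                verified = np.array(
                    [_passes(c, threshold, strict) for c in covs], dtype=bool
                )
                per_sample_pct_verified.append(100.0 * float(verified.mean()))
                per_sample_pct_seq.append(
                    100.0 * float((covs * lengths).sum() / lengths.sum())
                )
            if shared == 0:
                raise ValueError(f"tools {pred!r} and {verif!r} share no samples")
            rows.append(
                {
                    "predictor_tool": pred,
                    "verifier_tool": verif,
                    "median_pct_concordant_seq_per_cnv": (
                        float(np.median(per_sample_median)) if per_sample_median else np.nan
                    ),
                    "pct_verified_cnvs": (
                        float(np.median(per_sample_pct_verified))
                        if per_sample_pct_verified
                        else np.nan
                    ),
                    "pct_verified_cumulated_seq": (
                        float(np.median(per_sample_pct_seq)) if per_sample_pct_seq else np.nan
                    ),
                }
            )
    return pd.DataFrame(rows, columns=CONCORDANCE_COLUMNS)


def depth_profile(
    segments: Iterable[tuple[int, int]]
) -> list[tuple[int, int, int]]:
    """Base-pair stacking depth of half-open intervals on one chromosome.

    Returns maximal runs (start, end, depth) with depth >= 1, via an event
    sweep over interval endpoints.
    """
    events: dict[int, int] = {}
    for s, e in segments:
        events[s] = events.get(s, 0) + 1
        events[e] = events.get(e, 0) - 1
    profile = []
    depth = 0
    prev: int | None = None
    for pos in sorted(events):
        if prev is not None and depth > 0 and pos > prev:
            profile.append((prev, pos, depth))
        depth += events[pos]
        prev = pos
    return profile


def consensus_calls(
    calls_by_tool: Mapping[str, CallSet], k: int = 3
) -> CallSet:
    """Consensus call set: bases called in one class by >= k distinct tools.

    Overlapping same-class calls *within* one tool count once (each tool's
    calls are unioned per class before stacking).  Emitted segments are the
    maximal runs of depth >= k, per chromosome and class; consecutive runs
    merge.  If k exceeds the number of tools the result is empty (warned).
    """
    tools = list(calls_by_tool)
    samples = {cs.sample_id for cs in calls_by_tool.values()}
    if len(samples) > 1:
        raise ValueError(f"consensus is per sample; got samples {sorted(samples)}")
    sample_id = next(iter(samples)) if samples else ""
    if k > len(tools):
        warnings.warn(
            f"k={k} exceeds the {len(tools)} available tools; consensus is empty",
            stacklevel=2,
        )
    segments: list[GenomicSegment] = []
    for cls in VARIANT_CLASSES:
        chroms = sorted(
            {s.chrom for cs in calls_by_tool.values() for s in cs if s.cn_class is cls}
        )
        for chrom in chroms:
            intervals: list[tuple[int, int]] = []
            for cs in calls_by_tool.values():
                starts, ends = cs.merged_index(chrom, cls)
                intervals.extend(zip(starts.tolist(), ends.tolist()))
            run_start: int | None = None
            run_end: int | None = None
            for s, e, depth in depth_profile(intervals):
                if depth >= k:
                    if run_end == s:
                        run_end = e
                    else:
                        if run_start is not None:
                            segments.append(
                                GenomicSegment(
                                    chrom=chrom,
                                    start=run_start,
                                    end=run_end,
                                    cn_class=cls,
                                    sample_id=sample_id,
                                    tool_id=f"consensus_k{k}",
                                )
                            )
                        run_start, run_end = s, e
            if run_start is not None:
                segments.append(
                    GenomicSegment(
                        chrom=chrom,
                        start=run_start,
                        end=run_end,
                        cn_class=cls,
                        sample_id=sample_id,
                        tool_id=f"consensus_k{k}",
                    )
                )
    return CallSet(sample_id, f"consensus_k{k}", segments)


def verify_against_reference(
    callset: CallSet,
    reference: Iterable[GenomicSegment],
    threshold: float = 0.9,
    class_aware: bool = True,
    strict: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Verify calls against an external reference variant set.

    Each call is verified when the reference union (same-class, or any class
    with ``class_aware=False`` for references lacking gain/loss annotation)
    covers more than ``threshold`` of it.  Returns the verified fraction and
    a per-CNV record table.
    """
    ref = CallSet("reference", "reference", reference)
    if len(ref) == 0:
        warnings.warn("empty reference: all calls unverified", stacklevel=2)
    rows = []
    for seg in callset:
        cov = coverage_fraction(seg, ref, same_class=class_aware)
        rows.append(
            {
                "chrom": seg.chrom,
                "start": seg.start,
                "end": seg.end,
                "cn_class": seg.cn_class.value,
                "coverage": cov,
                "verified": _passes(cov, threshold, strict),
            }
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "cn_class", "coverage", "verified"]
    )
    fraction = float(df["verified"].mean()) if len(df) else np.nan
    return fraction, df
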