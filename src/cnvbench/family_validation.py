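"""In-silico validation of offspring CNV calls against parental calls.

Because the overwhelming majority of germline CNVs are inherited, an
offspring CNV prediction can be checked against the parents: it is
*validated* when segments of the same CN class (gain or loss) called in at
least one parent jointly cover more than a threshold fraction (default 90%)
of the offspring CNV.  Each parent is evaluated separately -- the union is
taken within one parent's calls, never across the couple.

Two modes exist.  *Same-tool* validation requires the parental calls to come
from the tool that produced the offspring call and uses a strict ``>``
comparison at the threshold.  *Extended* validation accepts parental calls
from any tool and uses ``>=``, compensating for tool-specific false
negatives in the parents.  Both comparisons are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CNClass, CallSet, CallSetKey, GenomicSegment, Pedigree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ValidationRecord:
    """Outcome of validating one offspring CNV against the parents."""

    segment: GenomicSegment
    coverage_father: float
    coverage_mother: float
    validated: bool
    threshold: float
    mode: str  # "same_tool" | "extended"


def coverage_fraction(
    target: GenomicSegment,
    others: CallSet | Iterable[GenomicSegment],
    same_class: bool = True,
) -> float:
    """Fraction of ``target``'s bases covered by the union of ``others``.

    Only segments on the target's chromosome count; with ``same_class`` only
    segments of the target's CN class contribute.  Coverage is the per-base
    union -- fragmented covering segments are fine, continuity is not
    required.
    """
    if not isinstance(others, CallSet):
        others = CallSet("", "", others)
    covered = 0
    classes = [target.cn_class] if same_class else [CNClass.LOSS, CNClass.GAIN]
    for cls in classes:
        starts, ends = others.merged_index(target.chrom, cls)
        if starts.size == 0:
            continue
        lo = np.maximum(starts, target.start)
        hi = np.minimum(ends, target.end)
        covered += int(np.clip(hi - lo, 0, None).sum())
    if not same_class:
        # union across classes could double-count where a loss and a gain
        # call overlap; recompute on the pooled interval set instead
        from .core import merge_intervals

        pooled = merge_intervals(
            (s, e)
            for cls in (CNClass.LOSS, CNClass.GAIN)
            for s, e in zip(*others.merged_index(target.chrom, cls))
        )
        covered = sum(
            max(0, min(e, target.end) - max(s, target.start)) for s, e in pooled
        )
    return covered / target.length


def _passes(coverage: float, threshold: float, strict: bool) -> bool:
    return coverage > threshold if strict else coverage >= threshold


def validate_trio(
    offspring: CallSet,
    father: CallSet,
    mother: CallSet,
    threshold: float = 0.9,
    strict: bool = True,
) -> list[ValidationRecord]:
    """Same-tool trio validation of every offspring CNV.

    All three call sets must come from the same tool.  An offspring CNV is
    validated when either parent's same-class union covers more than
    ``threshold`` of it (strictly, by default).
    """
    tools = {offspring.tool_id, father.tool_id, mother.tool_id}
    if len(tools) != 1:
        raise ValueError(f"same-tool validation across tools {sorted(tools)}")
    records = []
    for seg in offspring:
        cov_f = coverage_fraction(seg, father, same_class=True)
        cov_m = coverage_fraction(seg, mother, same_class=True)
        records.append(
            ValidationRecord(
                segment=seg,
                coverage_father=cov_f,
                coverage_mother=cov_m,
                validated=_passes(max(cov_f, cov_m), threshold, strict),
                threshold=threshold,
                mode="same_tool",
            )
        )
    return records


def validate_extended(
    offspring: CallSet,
    parental_callsets: Sequence[CallSet],
    father_id: str,
    mother_id: str,
    threshold: float = 0.9,
    strict: bool = False,
) -> list[ValidationRecord]:
    """Extended validation: any tool's parental call may validate.

    ``parental_callsets`` holds call sets for the two parents over any subset
    of tools.  Per parent, the best coverage over tools is taken; the CNV is
    validated when that best coverage reaches the threshold (``>=`` by
    default) in at least one parent.
    """
    father_sets = [cs for cs in parental_callsets if cs.sample_id == father_id]
    mother_sets = [cs for cs in parental_callsets if cs.sample_id == mother_id]
    records = []
    for seg in offspring:
        cov_f = max(
            (coverage_fraction(seg, cs, same_class=True) for cs in father_sets),
            default=0.0,
        )
        cov_m = max(
            (coverage_fraction(seg, cs, same_class=True) for cs in mother_sets),
            default=0.0,
        )
        records.append(
            ValidationRecord(
                segment=seg,
                coverage_father=cov_f,
                coverage_mother=cov_m,
                validated=_passes(max(cov_f, cov_m), threshold, strict),
                threshold=threshold,
                mode="extended",
            )
        )
    return records


def summarize_validation(records: Sequence[ValidationRecord]) -> dict[str, float] | None:
    """Table-2-style per-sample summary of validation records.

    Percentages of validated CNVs overall and by class, the DDR restricted
    to validated CNVs (NaN without validated duplications), and the
    validated cumulative-sequence percentage (validated bp / total CNV bp).
    Returns None for an empty record list (no CNVs -> no summary row).
    """
    if not records:
        logger.info("no CNVs to summarize; summary row absent")
        return None
    n = len(records)
    n_val = sum(r.validated for r in records)
    dels = [r for r in records if r.segment.cn_class is CNClass.LOSS]
    dups = [r for r in records if r.segment.cn_class is CNClass.GAIN]
    n_val_del = sum(r.validated for r in dels)
    n_val_dup = sum(r.validated for r in dups)
    total_bp = sum(r.segment.length for r in records)
    val_bp = sum(r.segment.length for r in records if r.validated)
    return {
        "n_cnvs": n,
        "n_validated": n_val,
        "pct_validated": 100.0 * n_val / n,
        "pct_validated_deletions": 100.0 * n_val_del / len(dels) if dels else np.nan,
        "pct_validated_duplications": 100.0 * n_val_dup / len(dups) if dups else np.nan,
        "ddr_validated": n_val_del / n_val_dup if n_val_dup > 0 else np.nan,
        "pct_validated_sequence": 100.0 * val_bp / total_bp,
    }


def stratify_by_size(
    records: Sequence[ValidationRecord], bin_edges: Sequence[float]
) -> pd.DataFrame:
    """Validation rate per CNV-length bin.

    ``bin_edges`` must be strictly increasing; CNVs shorter than the first
    edge or at least the last edge fall into open-ended extreme bins.
    Empty bins report count 0 and an undefined (NaN) rate.
    """
    edges = list(bin_edges)
    if any(b >= a for a, b in zip(edges[1:], edges[:-1])):
        raise ValueError("bin edges must be strictly increasing")
    full_edges = [-np.inf, *edges, np.inf]
    rows = []
    lengths = np.array([r.segment.length for r in records], dtype=float)
    validated = np.array([r.validated for r in records], dtype=bool)
    for lo, hi in zip(full_edges[:-1], full_edges[1:]):
        in_bin = (lengths >= lo) & (lengths < hi)
        count = int(in_bin.sum())
        rows.append(
            {
                "bin_low": lo,
                "bin_high": hi,
                "n_cnvs": count,
                "n_validated": int(validated[in_bin].sum()),
                "pct_validated": 100.0 * validated[in_bin].mean() if count else np.nan,
            }
        )
    return pd.DataFrame(rows)


def validate_dataset(
    calls: Mapping[CallSetKey, CallSet],
    pedigree: Pedigree,
    mode: str = "same_tool",
    threshold: float = 0.9,
    strict: bool | None = None,
    tools: Sequence[str] | None = None,
) -> tuple[dict[CallSetKey, list[ValidationRecord]], pd.DataFrame]:
    """Run trio validation over a whole benchmark dataset.

    ``calls`` maps (sample_id, tool_id) to standardized call sets.  For each
    trio and each tool with an offspring call set, offspring CNVs are
    validated in the requested mode; missing parental call sets count as
    empty.  Returns the per-CNV records keyed like ``calls`` plus a
    per-(sample, tool) summary table with population labels.
    """
    if mode not in ("same_tool", "extended"):
        raise ValueError(f"mode must be 'same_tool' or 'extended', got {mode!r}")
    if strict is None:
        strict = mode == "same_tool"
    if tools is None:
        tools = sorted({tool for _, tool in calls})

    all_records: dict[CallSetKey, list[ValidationRecord]] = {}
    summary_rows = []
    for trio in pedigree:
        for tool in tools:
            offspring = calls.get((trio.offspring_id, tool))
            if offspring is None or len(offspring) == 0:
                continue
            if mode == "same_tool":
                father = calls.get((trio.father_id, tool)) or CallSet(trio.father_id, tool, [])
                mother = calls.get((trio.mother_id, tool)) or CallSet(trio.mother_id, tool, [])
                records = validate_trio(offspring, father, mother, threshold, strict)
            else:
                parental = [
                    cs
                    for (sample, _t), cs in calls.items()
                    if sample in (trio.father_id, trio.mother_id)
                ]
                records = validate_extended(
                    offspring, parental, trio.father_id, trio.mother_id, threshold, strict
                )
            all_records[(trio.offspring_id, tool)] = records
            summary = summarize_validation(records)
            if summary is not None:
                summary_rows.append(
                    {
                        "sample_id": trio.offspring_id,
                        "tool_id": tool,
                        "population": trio.population,
                        **summary,
                    }
                )
    return all_records, pd.DataFrame(summary_rows)
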