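"""Reading, standardizing and writing CNV call sets, pedigrees and marker maps.

Heterogeneous caller output is brought onto one segment model: tab-separated
files are parsed through a small dialect registry, marker-level output is
converted to segments, CN genotypes are collapsed to classes, and call sets
are standardized (autosomes only, normal-class calls dropped, overlapping or
book-ended same-class calls merged).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    CNClass,
    CallSet,
    GenomicSegment,
    MarkerMap,
    Pedigree,
    Trio,
    VARIANT_CLASSES,
    collapse_genotype_to_class,
    merge_intervals,
    parse_chrom,
)

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["sample_id", "tool_id", "chrom", "start", "end", "cn", "n_markers"]


class CallFileError(ValueError):
    """Malformed call file content, annotated with the offending line."""


def _parse_cn(value: object, line: int) -> tuple[CNClass, int | None]:
    """Interpret a cn field as either a class word or an integer genotype."""
    s = str(value).strip().lower()
    if s in CNClass._value2member_map_:
        return CNClass(s), None
    try:
        genotype = int(s)
    except ValueError:
        raise CallFileError(f"line {line}: unknown CN code {value!r}") from None
    try:
        return collapse_genotype_to_class(genotype), genotype
    except ValueError:
        raise CallFileError(f"line {line}: unknown CN code {value!r}") from None


def _read_segment_dialect(path: Path) -> list[CallSet]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise CallFileError(f"{path}: cannot parse as tab-separated: {exc}") from exc
    missing = [c for c in CALL_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise CallFileError(f"{path}: missing required columns {missing}")

    segments: list[GenomicSegment] = []
    n_dropped = 0
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        chrom = parse_chrom(getattr(row, "chrom"))
        if chrom is None:
            n_dropped += 1
            continue
        try:
            start, end = int(getattr(row, "start")), int(getattr(row, "end"))
        except (TypeError, ValueError):
            raise CallFileError(f"line {line}: non-integer coordinates") from None
        cn_class, genotype = _parse_cn(getattr(row, "cn"), line)
        n_markers = None
        if "n_markers" in df.columns:
            raw = getattr(row, "n_markers")
            if raw is not None and not pd.isna(raw) and str(raw) != "":
                n_markers = int(raw)
        try:
            segments.append(
                GenomicSegment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    cn_class=cn_class,
                    cn_genotype=genotype,
                    n_markers=n_markers,
                    sample_id=str(getattr(row, "sample_id")),
                    tool_id=str(getattr(row, "tool_id")),
                )
            )
        except ValueError as exc:
            raise CallFileError(f"line {line}: {exc}") from None
    if n_dropped:
        logger.info("%s: dropped %d non-autosomal rows", path, n_dropped)

    grouped: dict[tuple[str, str], list[GenomicSegment]] = {}
    for seg in segments:
        grouped.setdefault((seg.sample_id, seg.tool_id), []).append(seg)
    return [
        CallSet(sample_id, tool_id, segs)
        for (sample_id, tool_id), segs in sorted(grouped.items())
    ]


DIALECTS: dict[str, Callable[[Path], list[CallSet]]] = {
    "segment": _read_segment_dialect,
    # unknown tools fall back to the generic segment dialect
    "generic": _read_segment_dialect,
}


def read_call_file(path: str | Path, dialect: str = "segment") -> list[CallSet]:
    """Read a tab-separated call file into one CallSet per (sample, tool).

    The ``segment`` dialect expects columns
    ``sample_id tool_id chrom start end cn [n_markers]`` where ``cn`` is a
    class word (loss/normal/gain) or an integer CN genotype 0-6.
    Non-autosomal rows are dropped (and counted in the log).
    """
    try:
        reader = DIALECTS[dialect]
    except KeyError:
        raise ValueError(
            f"unknown dialect {dialect!r}; registered: {sorted(DIALECTS)}"
        ) from None
    return reader(Path(path))


def write_call_file(callsets: Iterable[CallSet], path: str | Path) -> None:
    """Write call sets to the canonical tab-separated segment layout."""
    rows = []
    for cs in callsets:
        for seg in cs.segments:
            rows.append(
                {
                    "sample_id": cs.sample_id,
                    "tool_id": cs.tool_id,
                    "chrom": seg.chrom,
                    "start": seg.start,
                    "end": seg.end,
                    "cn": seg.cn_genotype if seg.cn_genotype is not None else seg.cn_class.value,
                    "n_markers": "" if seg.n_markers is None else seg.n_markers,
                }
            )
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def write_bed(callsets: Iterable[CallSet], path: str | Path) -> None:
    """Export as BED6: name = CN class, score = marker count (0 if unknown)."""
    with open(path, "w") as fh:
        for cs in callsets:
            for seg in cs.segments:
                score = seg.n_markers if seg.n_markers is not None else 0
                fh.write(
                    f"chr{seg.chrom}\t{seg.start}\t{seg.end}\t{seg.cn_class.value}\t{score}\t.\n"
                )


def read_bed(path: str | Path, default_class: CNClass | None = None) -> list[GenomicSegment]:
    """Read a BED-like reference variant file.

    Column 4, when present and equal to loss/gain/normal, is taken as the CN
    class; otherwise ``default_class`` is required (DGV-style references often
    lack a usable class annotation).
    """
    segments: list[GenomicSegment] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise CallFileError(f"line {line_no}: expected >=3 BED columns")
            chrom = parse_chrom(fields[0])
            if chrom is None:
                continue
            cn_class = default_class
            if len(fields) >= 4 and fields[3].lower() in CNClass._value2member_map_:
                cn_class = CNClass(fields[3].lower())
            if cn_class is None:
                raise CallFileError(
                    f"line {line_no}: no CN class in column 4 and no default_class given"
                )
            segments.append(
                GenomicSegment(chrom=chrom, start=int(fields[1]), end=int(fields[2]), cn_class=cn_class)
            )
    return segments


def markers_to_segments(
    marker_states: Sequence[tuple[str, CNClass | str | int]],
    marker_map: MarkerMap,
) -> list[GenomicSegment]:
    """Convert marker-level caller output to segments.

    Maximal runs of consecutive markers (in map order, per chromosome) that
    share one non-normal CN state become one segment spanning the first
    marker's position to the last marker's position + 1, with ``n_markers``
    set to the run length.  A run never extends across a marker in a
    different state, nor across a chromosome boundary.
    """
    states: dict[str, CNClass] = {}
    for marker_id, state in marker_states:
        if isinstance(state, (int,)) and not isinstance(state, bool):
            cls = collapse_genotype_to_class(state)
        else:
            cls = CNClass(state)
        if marker_id not in marker_map:
            raise KeyError(f"unknown marker id {marker_id!r}")
        states[marker_id] = cls

    chroms = sorted({marker_map.location(m)[0] for m in states})
    segments: list[GenomicSegment] = []
    for chrom in chroms:
        run: list[int] = []
        run_class: CNClass | None = None

        def flush() -> None:
            if run and run_class in VARIANT_CLASSES:
                segments.append(
                    GenomicSegment(
                        chrom=chrom,
                        start=run[0],
                        end=run[-1] + 1,
                        cn_class=run_class,
                        n_markers=len(run),
                    )
                )

        # walk ALL map markers on this chromosome in genome order; any marker
        # with a different state -- including markers absent from the input,
        # treated as state-unknown -- breaks the run, so a segment span never
        # contains a marker that was not reported in that state
        positions = marker_map.positions(chrom)
        ids = marker_map.marker_ids(chrom)
        for pos, marker_id in zip(positions, ids):
            cls = states.get(marker_id)
            if cls is not None and cls is run_class:
                run.append(int(pos))
            else:
                flush()
                run = [int(pos)] if cls is not None else []
                run_class = cls
        flush()
    return segments


def standardize(callset: CallSet) -> CallSet:
    """Standardize a call set for cross-tool comparison.

    Drops normal-class segments, merges overlapping or book-ended same-class
    segments, sorts by position and keeps autosomal calls of any size
    (short sub-kb outliers included).  Idempotent.
    """
    merged_segments: list[GenomicSegment] = []
    for cls in VARIANT_CLASSES:
        per_chrom: dict[int, list[GenomicSegment]] = {}
        for seg in callset.segments:
            if seg.cn_class is cls:
                per_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in per_chrom.items():
            intervals = merge_intervals((s.start, s.end) for s in segs)
            for start, end in intervals:
                contributing = [s for s in segs if s.start < end and s.end > start]
                n_markers = (
                    sum(s.n_markers for s in contributing)
                    if all(s.n_markers is not None for s in contributing)
                    and len(contributing) > 0
                    else (contributing[0].n_markers if len(contributing) == 1 else None)
                )
                merged_segments.append(
                    GenomicSegment(
                        chrom=chrom,
                        start=start,
                        end=end,
                        cn_class=cls,
                        n_markers=n_markers,
                        sample_id=callset.sample_id,
                        tool_id=callset.tool_id,
                    )
                )
    return callset.with_segments(merged_segments)


def standardize_all(
    calls: Mapping[tuple[str, str], CallSet]
) -> dict[tuple[str, str], CallSet]:
    return {key: standardize(cs) for key, cs in calls.items()}


# -- pedigree and marker-map I/O -------------------------------------------

PED_COLUMNS = ["family", "individual", "father", "mother", "sex", "population"]


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a PED-style whitespace-separated pedigree.

    Columns: ``family individual father mother sex population``.  Rows whose
    father and mother are both non-missing ("0" marks missing) define trios.
    """
    trios: list[Trio] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise CallFileError(
                    f"line {line_no}: expected 6 whitespace-separated fields"
                )
            _family, individual, father, mother, _sex, population = fields[:6]
            if father != "0" and mother != "0":
                trios.append(
                    Trio(
                        offspring_id=individual,
                        father_id=father,
                        mother_id=mother,
                        population=population,
                    )
                )
    return Pedigree(trios)


def write_pedigree(pedigree: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, trio in enumerate(pedigree, start=1):
            fam = f"FAM{i:04d}"
            fh.write(f"{fam} {trio.father_id} 0 0 1 {trio.population}\n")
            fh.write(f"{fam} {trio.mother_id} 0 0 2 {trio.population}\n")
            fh.write(
                f"{fam} {trio.offspring_id} {trio.father_id} {trio.mother_id} 0 {trio.population}\n"
            )


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read a tab-separated marker map: ``marker_id chrom position``."""
    df = pd.read_csv(path, sep="\t", dtype={"marker_id": str})
    required = ["marker_id", "chrom", "position"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CallFileError(f"{path}: missing marker map columns {missing}")
    entries = []
    for row in df.itertuples(index=False):
        chrom = parse_chrom(row.chrom)
        if chrom is None:
            continue
        entries.append((str(row.marker_id), chrom, int(row.position)))
    return MarkerMap(entries)


def write_marker_map(marker_map: MarkerMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tchrom\tposition\n")
        for marker_id, chrom, position in marker_map.iter_entries():
            fh.write(f"{marker_id}\t{chrom}\t{position}\n")
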