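"""Report assembly, group comparisons and pipeline orchestration.

Builds the benchmark's standard tables (per-sample features, validation
rates, validated-CNV features, pseudo-validation rates, concordance
matrices), compares algorithm classes (HMM vs segmentation) with a paired
Wilcoxon signed-rank test and a label-permutation test on the inter-tool
MAD, and runs the whole pipeline from one configuration mapping.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .call_io import (
    read_call_file,
    read_marker_map,
    read_pedigree,
    standardize_all,
    write_bed,
    write_call_file,
    write_pedigree,
)
from .cnv_features import feature_table, mad, summarize_over_samples
from .concordance import consensus_calls, pairwise_concordance
from .core import CallSet, index_callsets
from .family_validation import validate_dataset
from .permutation_null import PermutationScheme, pseudo_validation_rate
from .synthetic_data import ToolProfile, default_profiles, simulate_dataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupComparison:
    """Result of a paired two-group comparison of one statistic."""

    statistic_name: str
    median_a: float
    median_b: float
    test_statistic: float
    p_value: float
    n_pairs: int
    undefined: bool = False


def paired_rank_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    statistic_name: str = "",
) -> GroupComparison:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are discarded (the classical treatment); if every
    difference is zero the test is undefined and reported as such with
    p = NaN.  Exact null distribution for small samples, normal
    approximation with continuity correction otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return GroupComparison(
            statistic_name=statistic_name,
            median_a=float(np.median(a)),
            median_b=float(np.median(b)),
            test_statistic=math.nan,
            p_value=math.nan,
            n_pairs=int(a.size),
            undefined=True,
        )
    res = stats.wilcoxon(a, b, zero_method="wilcox", correction=True, method="auto")
    return GroupComparison(
        statistic_name=statistic_name,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        test_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_pairs=int(a.size),
    )


def label_permutation_test(
    values_per_tool: Mapping[str, float],
    class_labels: Mapping[str, str],
    n_perm: int = 10_000,
    seed: int = 0,
    exact_if_feasible: bool = True,
    max_exact: int = 10_000,
) -> dict[str, float]:
    """Permutation test for the difference in inter-tool MAD between classes.

    The observed statistic is |MAD(class A tools) - MAD(class B tools)| of
    the per-tool values.  Class labels are permuted across tools keeping the
    group sizes fixed; p is the fraction of permuted statistics >= the
    observed one, with the +1 (observed-included) correction for the sampled
    variant.  When the number of distinct assignments is small (20 for six
    tools split 3/3) the test enumerates them exhaustively by default.
    """
    tools = sorted(values_per_tool)
    values = np.array([values_per_tool[t] for t in tools], dtype=float)
    labels = [class_labels[t] for t in tools]
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    n_a = labels.count(classes[0])
    if n_a < 2 or len(tools) - n_a < 2:
        raise ValueError("each class needs at least 2 tools for a MAD")

    def statistic(idx_a: Sequence[int]) -> float:
        mask = np.zeros(len(tools), dtype=bool)
        mask[list(idx_a)] = True
        return abs(mad(values[mask], scaling=1.0) - mad(values[~mask], scaling=1.0))

    observed = statistic([i for i, l in enumerate(labels) if l == classes[0]])

    n_assignments = math.comb(len(tools), n_a)
    if exact_if_feasible and n_assignments <= max_exact:
        perm_stats = np.array(
            [statistic(c) for c in itertools.combinations(range(len(tools)), n_a)]
        )
        p = float(np.mean(perm_stats >= observed - 1e-12))
        method = "exact"
        n_used = n_assignments
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            idx = rng.permutation(len(tools))[:n_a]
            if statistic(idx) >= observed - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
        method = "sampled"
        n_used = n_perm
    return {
        "observed": float(observed),
        "p_value": float(p),
        "method": method,
        "n_permutations": n_used,
    }


def compare_algorithm_classes(
    summary: pd.DataFrame,
    tool_classes: Mapping[str, str],
    value_column: str,
) -> GroupComparison:
    """Paired HMM-vs-segmentation comparison of a per-(sample, tool) value.

    Per sample, the value is summarized by its median across the tools of
    each class; the resulting per-sample pairs feed the signed-rank test.
    """
    df = summary.copy()
    df["alg_class"] = df["tool_id"].map(tool_classes)
    pivot = (
        df.groupby(["sample_id", "alg_class"])[value_column].median().unstack("alg_class")
    )
    classes = sorted(c for c in pivot.columns if pd.notna(c))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 algorithm classes, got {classes}")
    pivot = pivot.dropna()
    return paired_rank_test(
        pivot[classes[0]].to_numpy(),
        pivot[classes[1]].to_numpy(),
        statistic_name=f"{value_column} ({classes[0]} vs {classes[1]})",
    )


DEFAULT_CONFIG: dict = {
    "threshold": 0.9,
    "consensus_k": 3,
    "permutation": {"n_replicates": 10, "scopes": ["pooled", "within_population"]},
    "seed": 0,
    "simulate": {"n_trios": 30, "n_loci": 200},
}


def run_pipeline(config: Mapping, out_dir: str | Path) -> dict[str, Path]:
    """Run the full benchmark and write all report tables.

    ``config`` either names input files (``calls``, ``pedigree``, optional
    ``marker_map``) or carries a ``simulate`` section; thresholds, the
    consensus ``k``, the permutation scheme and the seed are all taken from
    the config with sensible defaults.  Outputs (TSV tables plus a JSON
    manifest) are a pure function of config and seed.
    """
    cfg = {**DEFAULT_CONFIG, **dict(config)}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    threshold = float(cfg.get("threshold", 0.9))

    marker_map = None
    if cfg.get("calls"):
        if not cfg.get("pedigree"):
            raise ValueError("config names call files but no pedigree")
        callsets = []
        calls_cfg = cfg["calls"]
        for path in [calls_cfg] if isinstance(calls_cfg, (str, Path)) else calls_cfg:
            callsets.extend(read_call_file(path, dialect=cfg.get("dialect", "segment")))
        calls = index_callsets(callsets)
        pedigree = read_pedigree(cfg["pedigree"])
        if cfg.get("marker_map"):
            marker_map = read_marker_map(cfg["marker_map"])
        tool_classes = dict(cfg.get("tool_classes", {}))
    elif "simulate" in cfg:
        sim = dict(cfg["simulate"])
        profiles = sim.pop("profiles", None)
        if profiles is not None:
            profiles = [ToolProfile(**p) for p in profiles]
        else:
            profiles = default_profiles()
        calls, pedigree, truth, _panel = simulate_dataset(
            profiles=profiles, seed=seed, **sim
        )
        truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
        write_pedigree(pedigree, out / "trios.ped")
        tool_classes = {p.tool_id: p.algorithm_class for p in profiles}
    else:
        raise ValueError("config must name input call files or a 'simulate' section")

    calls = standardize_all(calls)
    write_call_file(calls.values(), out / "calls_standardized.tsv")

    features = feature_table(calls.values(), marker_map)
    features.to_csv(out / "table1_features.tsv", sep="\t", index=False)
    summarize_over_samples(features).to_csv(
        out / "table1_summary.tsv", sep="\t", index=False
    )

    records, val_summary = validate_dataset(
        calls, pedigree, mode="same_tool", threshold=threshold
    )
    val_summary.to_csv(out / "table2_validation.tsv", sep="\t", index=False)
    _records_ext, ext_summary = validate_dataset(
        calls, pedigree, mode="extended", threshold=threshold
    )
    ext_summary.to_csv(out / "table2_validation_extended.tsv", sep="\t", index=False)

    validated_sets = {
        key: cs.with_segments(
            r.segment for r in records.get(key, []) if r.validated
        )
        for key, cs in calls.items()
        if key in records
    }
    validated_features = feature_table(
        [cs for cs in validated_sets.values() if len(cs)], marker_map
    )
    validated_features.to_csv(out / "table3_validated_features.tsv", sep="\t", index=False)

    perm_cfg = dict(cfg.get("permutation", {}))
    scopes = perm_cfg.pop("scopes", ["pooled"])
    perm_tables = []
    for scope in scopes:
        scheme = PermutationScheme(
            n_replicates=int(perm_cfg.get("n_replicates", 10)),
            scope=scope,
            seed=seed,
        )
        try:
            perm_tables.append(
                pseudo_validation_rate(calls, pedigree, scheme, threshold=threshold)
            )
        except ValueError as exc:
            logger.warning("pseudo-validation scope %s skipped: %s", scope, exc)
    if perm_tables:
        pd.concat(perm_tables, ignore_index=True).to_csv(
            out / "table4_pseudovalidation.tsv", sep="\t", index=False
        )

    tools = sorted({tool for _, tool in calls})
    if len(tools) >= 2:
        conc_all = pairwise_concordance(calls, threshold=threshold)
        conc_val = pairwise_concordance(calls, threshold=threshold, restrict_to=records)
        conc_val[["predictor_tool", "verifier_tool", "pct_verified_cnvs"]].to_csv(
            out / "s6_concordance_counts.tsv", sep="\t", index=False
        )
        conc_val.to_csv(out / "s7_concordance_sequence.tsv", sep="\t", index=False)
        conc_all.to_csv(out / "concordance_all_calls.tsv", sep="\t", index=False)

    k = int(cfg.get("consensus_k", 3))
    samples = sorted({sample for sample, _ in calls})
    consensus_sets = []
    for sample in samples:
        by_tool = {tool: calls[(sample, tool)] for tool in tools if (sample, tool) in calls}
        if len(by_tool) >= 2:
            consensus_sets.append(consensus_calls(by_tool, k=k))
    if consensus_sets:
        write_bed(consensus_sets, out / f"consensus_k{k}.bed")

    comparisons = []
    if tool_classes and len(set(tool_classes.values())) == 2:
        for column, table in (
            ("n_cnvs", features),
            ("median_length", features),
            ("ddr", features),
            ("pct_validated", val_summary),
        ):
            try:
                comparisons.append(
                    compare_algorithm_classes(table, tool_classes, column).__dict__
                )
            except (ValueError, KeyError) as exc:
                logger.warning("group comparison on %s skipped: %s", column, exc)
        if comparisons:
            pd.DataFrame(comparisons).to_csv(
                out / "group_comparisons.tsv", sep="\t", index=False
            )

    manifest = {
        "seed": seed,
        "threshold": threshold,
        "consensus_k": k,
        "n_trios": len(pedigree),
        "tools": tools,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {p.name: p for p in out.iterdir() if p.is_file()}
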