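"""Chance ("pseudo") validation rate via parent-offspring permutation.

Part of the apparent family-based validation rate is expected by chance:
common CNVs are carried by unrelated individuals too.  Randomly reassigning
parent pairs to offspring and re-running the validation yields an empirical
null for this chance component.  Reassignment is a derangement by default
(no offspring keeps its true parents, which would leak genuine validations
into the null) and parent pairs travel as units to preserve within-couple
CNV correlation; both are configurable.  The permutation can be drawn from
the pooled set of trios or within each population separately.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CallSet, CallSetKey, Pedigree, Trio
from .family_validation import validate_dataset


@dataclass(frozen=True)
class PermutationScheme:
    """How parents are reassigned to offspring."""

    n_replicates: int = 10
    scope: str = "pooled"  # "pooled" | "within_population"
    keep_pairs_intact: bool = True
    exclude_self: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.scope not in ("pooled", "within_population"):
            raise ValueError(f"unknown scope {self.scope!r}")


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of range(n) without fixed points."""
    if n < 2:
        raise ValueError("a derangement needs at least 2 elements")
    while True:  # rejection sampling; acceptance prob -> 1/e
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def _assignment(n: int, exclude_self: bool, rng: np.random.Generator) -> np.ndarray:
    if exclude_self:
        return _derangement(n, rng)
    return rng.permutation(n)


def permute_parents(
    pedigree: Pedigree, scheme: PermutationScheme, rng: np.random.Generator | None = None
) -> Pedigree:
    """Reassign parents to offspring according to the scheme.

    Each offspring receives the parent pair (or, with
    ``keep_pairs_intact=False``, an independently drawn father and mother)
    of another trio; with ``within_population`` scope donors always come
    from the offspring's own population.
    """
    if rng is None:
        rng = np.random.default_rng(scheme.seed)
    trios = list(pedigree)
    if scheme.scope == "within_population":
        groups = [
            [i for i, t in enumerate(trios) if t.population == pop]
            for pop in pedigree.populations
        ]
    else:
        groups = [list(range(len(trios)))]

    new_trios: list[Trio | None] = [None] * len(trios)
    for idx in groups:
        if len(idx) < 2:
            raise ValueError(
                "permutation scope contains a single trio; cannot reassign parents"
            )
        fa = _assignment(len(idx), scheme.exclude_self, rng)
        mo = fa if scheme.keep_pairs_intact else _assignment(len(idx), scheme.exclude_self, rng)
        for j, i in enumerate(idx):
            donor_f = trios[idx[fa[j]]]
            donor_m = trios[idx[mo[j]]]
            new_trios[i] = replace(
                trios[i], father_id=donor_f.father_id, mother_id=donor_m.mother_id
            )
    return Pedigree(t for t in new_trios if t is not None)


def pseudo_validation_rate(
    calls: Mapping[CallSetKey, CallSet],
    pedigree: Pedigree,
    scheme: PermutationScheme | None = None,
    threshold: float = 0.9,
    mode: str = "same_tool",
    tools: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Validation rate under randomly reassigned parents.

    For each replicate the pedigree is permuted and the full validation is
    re-run; the per-sample validated percentage is summarized by its median
    over samples, and the replicate medians are reported per tool as median
    and inter-quartile range.  The replicate index offsets the random
    stream, so results are reproducible for a fixed seed.
    """
    if scheme is None:
        scheme = PermutationScheme()
    if tools is None:
        tools = sorted({tool for _, tool in calls})
    per_replicate: dict[str, list[float]] = {t: [] for t in tools}
    pooled_val: dict[str, int] = {t: 0 for t in tools}
    pooled_n: dict[str, int] = {t: 0 for t in tools}
    for rep in range(scheme.n_replicates):
        rng = np.random.default_rng((scheme.seed, rep))
        permuted = permute_parents(pedigree, scheme, rng=rng)
        records, summary = validate_dataset(
            calls, permuted, mode=mode, threshold=threshold, tools=tools
        )
        for tool in tools:
            sub = summary[summary["tool_id"] == tool] if len(summary) else summary
            if len(sub):
                per_replicate[tool].append(float(sub["pct_validated"].median()))
                pooled_val[tool] += int(sub["n_validated"].sum())
                pooled_n[tool] += int(sub["n_cnvs"].sum())
            else:
                per_replicate[tool].append(np.nan)

    rows = []
    for tool in tools:
        vals = np.asarray(per_replicate[tool], dtype=float)
        ok = vals[~np.isnan(vals)]
        rows.append(
            {
                "tool_id": tool,
                "scope": scheme.scope,
                "n_replicates": scheme.n_replicates,
                "median_pct_validated": float(np.median(ok)) if ok.size else np.nan,
                "q25": float(np.quantile(ok, 0.25)) if ok.size else np.nan,
                "q75": float(np.quantile(ok, 0.75)) if ok.size else np.nan,
                "pooled_pct_validated": (
                    100.0 * pooled_val[tool] / pooled_n[tool] if pooled_n[tool] else np.nan
                ),
                "pooled_n_cnvs": pooled_n[tool],
            }
        )
    return pd.DataFrame(rows)
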