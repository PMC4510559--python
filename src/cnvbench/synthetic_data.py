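"""Synthetic trio/caller simulator for end-to-end testing of the benchmark.

The generator produces (i) a panel of CNV loci on the 22 autosomes with
population-specific allele frequencies and an excess of deletions over
duplications, (ii) trio genotypes with Mendelian transmission plus a small
de novo component (germline CNVs are overwhelmingly inherited), and (iii)
noisy per-tool call sets governed by ``ToolProfile`` error models.  Two
default profiles emulate the qualitative contrast between caller families:
HMM-like tools call fewer, longer, cleaner segments; segmentation-like
tools call more, fragment large events, and carry a higher false-positive
rate.  The profiles are calibrated to direction only -- no claim of
quantitative fidelity to any real caller is made.

Everything is driven by seedable numpy generators, so a fixed seed
reproduces the full dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CNClass,
    CallSet,
    CallSetKey,
    GenomicSegment,
    MarkerMap,
    Pedigree,
    Trio,
)

#: hg19 autosome lengths in base pairs (chromosomes 1-22).
HG19_AUTOSOME_LENGTHS: dict[int, int] = {
    1: 249_250_621, 2: 243_199_373, 3: 198_022_430, 4: 191_154_276,
    5: 180_915_260, 6: 171_115_067, 7: 159_138_663, 8: 146_364_022,
    9: 141_213_431, 10: 135_534_747, 11: 135_006_516, 12: 133_851_895,
    13: 115_169_878, 14: 107_349_540, 15: 102_531_392, 16: 90_354_753,
    17: 81_195_210, 18: 78_077_248, 19: 59_128_983, 20: 63_025_520,
    21: 48_129_895, 22: 51_304_566,
}

#: Median inter-marker spacing of a dense genotyping array, in bp; used to
#: assign plausible marker counts when no marker map is supplied.
DEFAULT_MARKER_SPACING = 684

DEFAULT_POPULATIONS = ("CEU", "YRI")


def scaled_genome(scale: float = 1.0) -> dict[int, int]:
    """hg19-like autosome lengths multiplied by ``scale`` (desk-scale tests
    use small scales to keep coordinates and runtimes low)."""
    return {c: max(1_000, int(round(l * scale))) for c, l in HG19_AUTOSOME_LENGTHS.items()}


@dataclass(frozen=True)
class CnvLocus:
    chrom: int
    start: int
    end: int
    cn_class: CNClass
    freq_by_population: Mapping[str, float]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CnvLocusPanel:
    """Non-overlapping CNV loci with per-population allele frequencies."""

    loci: tuple[CnvLocus, ...]
    genome: Mapping[int, int]

    def __len__(self) -> int:
        return len(self.loci)

    def deletion_fraction(self) -> float:
        if not self.loci:
            return float("nan")
        return sum(l.cn_class is CNClass.LOSS for l in self.loci) / len(self.loci)


@dataclass(frozen=True)
class ToolProfile:
    """Error model of one simulated caller.

    sensitivity
        Per-CNV detection probability.
    fp_rate_per_mb
        Poisson rate of false-positive calls per megabase of genome.
    breakpoint_jitter_sd
        SD (bp) of independent Gaussian noise on each breakpoint.
    fragmentation_prob
        Probability that a detected CNV is split into two sub-segments
        separated by ``fragment_gap`` bp (segmentation-style behaviour).
    class_confusion_prob
        Probability of reporting a loss as a gain or vice versa.
    marker_spacing
        Typical within-CNV marker spacing used to synthesize marker counts
        when no marker map is given.
    """

    tool_id: str
    algorithm_class: str = "hmm"  # "hmm" | "segmentation"
    sensitivity: float = 1.0
    fp_rate_per_mb: float = 0.0
    breakpoint_jitter_sd: float = 0.0
    fragmentation_prob: float = 0.0
    fragment_gap: int = 2_000
    class_confusion_prob: float = 0.0
    emits_genotypes: bool = False
    marker_spacing: int = DEFAULT_MARKER_SPACING

    def __post_init__(self) -> None:
        for name in ("sensitivity", "fragmentation_prob", "class_confusion_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.breakpoint_jitter_sd < 0 or self.fp_rate_per_mb < 0:
            raise ValueError("rates must be non-negative")
        if self.algorithm_class not in ("hmm", "segmentation"):
            raise ValueError(f"unknown algorithm class {self.algorithm_class!r}")


def perfect_profile(tool_id: str = "perfect", algorithm_class: str = "hmm") -> ToolProfile:
    """A noiseless caller: calls exactly the truth."""
    return ToolProfile(tool_id=tool_id, algorithm_class=algorithm_class)


def default_profiles() -> list[ToolProfile]:
    """The two stock profiles contrasting the caller families.

    The HMM-like profile detects slightly more reliably, adds few false
    positives and never fragments; the segmentation-like profile adds
    several-fold more false positives, fragments a third of large calls and
    jitters breakpoints harder -- yielding more calls per sample of lower
    family validity, the qualitative contrast seen between real caller
    families.
    """
    return [
        ToolProfile(
            tool_id="hmm_like",
            algorithm_class="hmm",
            sensitivity=0.92,
            fp_rate_per_mb=0.012,
            breakpoint_jitter_sd=300.0,
            fragmentation_prob=0.0,
            class_confusion_prob=0.01,
            marker_spacing=500,
        ),
        ToolProfile(
            tool_id="segmentation_like",
            algorithm_class="segmentation",
            sensitivity=0.85,
            fp_rate_per_mb=0.045,
            breakpoint_jitter_sd=800.0,
            fragmentation_prob=0.30,
            fragment_gap=2_000,
            class_confusion_prob=0.02,
            marker_spacing=900,
        ),
    ]


@dataclass(frozen=True)
class TrueCnv:
    """One true CNV in one sample, with its inheritance annotation."""

    sample_id: str
    chrom: int
    start: int
    end: int
    cn_class: CNClass
    origin: str  # "inherited" | "de_novo" | "parental"
    transmitting_parent: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start

    def segment(self, tool_id: str = "truth") -> GenomicSegment:
        return GenomicSegment(
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            cn_class=self.cn_class,
            sample_id=self.sample_id,
            tool_id=tool_id,
        )


class TruthSet:
    """True CNV content of every simulated sample."""

    def __init__(self, cnvs: Iterable[TrueCnv], genome: Mapping[int, int]) -> None:
        self.cnvs: tuple[TrueCnv, ...] = tuple(cnvs)
        self.genome = dict(genome)
        self._by_sample: dict[str, list[TrueCnv]] = {}
        for cnv in self.cnvs:
            self._by_sample.setdefault(cnv.sample_id, []).append(cnv)

    def __len__(self) -> int:
        return len(self.cnvs)

    def samples(self) -> list[str]:
        return sorted(self._by_sample)

    def for_sample(self, sample_id: str) -> list[TrueCnv]:
        return list(self._by_sample.get(sample_id, []))

    def callset(self, sample_id: str, tool_id: str = "truth") -> CallSet:
        return CallSet(
            sample_id, tool_id, (c.segment(tool_id) for c in self.for_sample(sample_id))
        )

    def de_novo_fraction(self, offspring_ids: Sequence[str]) -> float:
        """Fraction of offspring CNVs flagged de novo."""
        offspring = set(offspring_ids)
        events = [c for c in self.cnvs if c.sample_id in offspring]
        if not events:
            return float("nan")
        return sum(c.origin == "de_novo" for c in events) / len(events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [c.sample_id for c in self.cnvs],
                "chrom": [c.chrom for c in self.cnvs],
                "start": [c.start for c in self.cnvs],
                "end": [c.end for c in self.cnvs],
                "cn_class": [c.cn_class.value for c in self.cnvs],
                "origin": [c.origin for c in self.cnvs],
                "transmitting_parent": [c.transmitting_parent for c in self.cnvs],
            }
        )


def _place_disjoint(
    n: int,
    genome: Mapping[int, int],
    lengths: np.ndarray,
    rng: np.random.Generator,
    occupied: dict[int, list[tuple[int, int]]] | None = None,
    min_gap: int = 5_000,
    max_tries: int = 200,
) -> list[tuple[int, int, int]]:
    """Place n intervals of given lengths on the genome, pairwise disjoint
    (with a guard gap) and disjoint from ``occupied``."""
    chroms = sorted(genome)
    weights = np.array([genome[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    if occupied is None:
        occupied = {}
    placed: list[tuple[int, int, int]] = []
    for i in range(n):
        length = int(lengths[i])
        for attempt in range(max_tries):
            chrom = int(rng.choice(chroms, p=weights))
            limit = genome[chrom] - length
            if limit <= 1:
                continue
            start = int(rng.integers(0, limit))
            end = start + length
            clash = any(
                start - min_gap < e and end + min_gap > s
                for s, e in occupied.get(chrom, [])
            )
            if not clash:
                occupied.setdefault(chrom, []).append((start, end))
                placed.append((chrom, start, end))
                break
        else:
            raise RuntimeError(
                f"could not place interval of {length} bp after {max_tries} tries; "
                "genome too small or too crowded"
            )
    return placed


def simulate_panel(
    n_loci: int,
    populations: Sequence[str] = DEFAULT_POPULATIONS,
    mean_freq: float = 0.15,
    freq_divergence: float = 0.0,
    ddr_target: float = 4.0,
    median_length_bp: float = 10_000.0,
    length_sigma: float = 0.8,
    genome: Mapping[int, int] | None = None,
    seed: int | np.random.Generator = 0,
) -> CnvLocusPanel:
    """Simulate a panel of CNV loci.

    Loci are placed disjointly on the 22 autosomes (chromosome chosen
    proportional to length), lengths are log-normal with the given median,
    and each locus is a deletion with probability ddr_target/(1+ddr_target)
    so the expected deletion/duplication ratio matches ``ddr_target``.
    Population allele frequencies are drawn per population around
    ``mean_freq``; ``freq_divergence`` sets the SD of the log-frequency
    scatter between populations (0 means identical frequencies).
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if genome is None:
        genome = HG19_AUTOSOME_LENGTHS
    lengths = np.maximum(
        200, rng.lognormal(np.log(median_length_bp), length_sigma, size=n_loci)
    ).astype(int)
    placed = _place_disjoint(n_loci, genome, lengths, rng)
    p_del = ddr_target / (1.0 + ddr_target)
    classes = np.where(rng.random(n_loci) < p_del, CNClass.LOSS, CNClass.GAIN)
    loci = []
    for (chrom, start, end), cls in zip(placed, classes):
        freqs = {}
        for pop in populations:
            if freq_divergence > 0:
                f = float(
                    np.clip(mean_freq * rng.lognormal(0.0, freq_divergence), 0.0, 1.0)
                )
            else:
                f = mean_freq
            freqs[pop] = f
        loci.append(
            CnvLocus(chrom=chrom, start=start, end=end, cn_class=CNClass(cls), freq_by_population=freqs)
        )
    return CnvLocusPanel(loci=tuple(loci), genome=dict(genome))


def simulate_trios(
    panel: CnvLocusPanel,
    n_trios: int | Mapping[str, int] = 30,
    de_novo_rate: float = 0.01,
    private: bool = False,
    median_length_bp: float = 10_000.0,
    length_sigma: float = 0.8,
    ddr_target: float = 4.0,
    seed: int | np.random.Generator = 0,
) -> tuple[TruthSet, Pedigree]:
    """Simulate trio genotypes with Mendelian transmission.

    Each parent carries 0/1/2 variant chromosomes per locus (each
    chromosome carries the variant with the locus's population frequency);
    the offspring inherits each parental copy with probability 1/2.  With
    ``private=True`` frequencies are ignored and every locus is instead
    carried (one copy) by exactly one parent of one trio -- loci are then
    unique to one family, the limit of vanishing population frequency.

    De novo offspring events are appended at a rate such that the expected
    de novo fraction of offspring CNVs equals ``de_novo_rate``; they are
    placed disjoint from all panel loci.
    """
    if not 0.0 <= de_novo_rate < 1.0:
        raise ValueError("de_novo_rate must be in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if isinstance(n_trios, Mapping):
        spec = dict(n_trios)
    else:
        pops = sorted({p for l in panel.loci for p in l.freq_by_population}) or ["POP"]
        base = n_trios // len(pops)
        spec = {pop: base for pop in pops}
        for pop in pops[: n_trios - base * len(pops)]:
            spec[pop] += 1

    trios: list[Trio] = []
    i = 0
    for pop, count in spec.items():
        for _ in range(count):
            i += 1
            trios.append(
                Trio(
                    offspring_id=f"{pop}_child_{i:03d}",
                    father_id=f"{pop}_father_{i:03d}",
                    mother_id=f"{pop}_mother_{i:03d}",
                    population=pop,
                )
            )
    pedigree = Pedigree(trios)

    n_loci = len(panel)
    cnvs: list[TrueCnv] = []

    # carrier chromosomes per parent per locus
    parent_copies: dict[str, np.ndarray] = {}
    if private:
        owner_trio = rng.integers(0, len(trios), size=n_loci)
        owner_parent = rng.integers(0, 2, size=n_loci)  # 0 father, 1 mother
    for t_idx, trio in enumerate(trios):
        freqs = np.array(
            [l.freq_by_population.get(trio.population, 0.0) for l in panel.loci]
        )
        if private:
            fa = np.zeros(n_loci, dtype=np.int64)
            mo = np.zeros(n_loci, dtype=np.int64)
            mine = owner_trio == t_idx
            fa[mine & (owner_parent == 0)] = 1
            mo[mine & (owner_parent == 1)] = 1
        else:
            fa = rng.binomial(2, freqs)
            mo = rng.binomial(2, freqs)
        parent_copies[trio.father_id] = fa
        parent_copies[trio.mother_id] = mo

        # one chromosome inherited per parent: the transmitted chromosome
        # carries the variant with probability (carrier copies)/2, so a
        # homozygous carrier parent transmits with certainty
        child = (rng.random(n_loci) < fa / 2).astype(np.int64) + (
            rng.random(n_loci) < mo / 2
        ).astype(np.int64)

        for l_idx, locus in enumerate(panel.loci):
            for sample_id, copies in ((trio.father_id, fa[l_idx]), (trio.mother_id, mo[l_idx])):
                if copies > 0:
                    cnvs.append(
                        TrueCnv(
                            sample_id=sample_id,
                            chrom=locus.chrom,
                            start=locus.start,
                            end=locus.end,
                            cn_class=locus.cn_class,
                            origin="parental",
                        )
                    )
            if child[l_idx] > 0:
                from_f = fa[l_idx] > 0
                from_m = mo[l_idx] > 0
                transmitting = (
                    "both" if from_f and from_m
                    else trio.father_id if from_f
                    else trio.mother_id
                )
                cnvs.append(
                    TrueCnv(
                        sample_id=trio.offspring_id,
                        chrom=locus.chrom,
                        start=locus.start,
                        end=locus.end,
                        cn_class=locus.cn_class,
                        origin="inherited",
                        transmitting_parent=transmitting,
                    )
                )

    # de novo events, disjoint from the panel so they can never be validated
    if de_novo_rate > 0:
        occupied: dict[int, list[tuple[int, int]]] = {}
        for locus in panel.loci:
            occupied.setdefault(locus.chrom, []).append((locus.start, locus.end))
        p_del = ddr_target / (1.0 + ddr_target)
        for trio in trios:
            k_inherited = sum(
                1 for c in cnvs
                if c.sample_id == trio.offspring_id and c.origin == "inherited"
            )
            lam = k_inherited * de_novo_rate / (1.0 - de_novo_rate)
            n_dn = int(rng.poisson(lam))
            if n_dn == 0:
                continue
            dn_lengths = np.maximum(
                200, rng.lognormal(np.log(median_length_bp), length_sigma, size=n_dn)
            ).astype(int)
            for chrom, start, end in _place_disjoint(
                n_dn, panel.genome, dn_lengths, rng, occupied=occupied
            ):
                cls = CNClass.LOSS if rng.random() < p_del else CNClass.GAIN
                cnvs.append(
                    TrueCnv(
                        sample_id=trio.offspring_id,
                        chrom=chrom,
                        start=start,
                        end=end,
                        cn_class=cls,
                        origin="de_novo",
                    )
                )
    return TruthSet(cnvs, panel.genome), pedigree


def simulate_calls(
    truth: TruthSet,
    profile: ToolProfile,
    marker_map: MarkerMap | None = None,
    seed: int | np.random.Generator = 0,
) -> dict[CallSetKey, CallSet]:
    """Generate noisy call sets for every sample in the truth set.

    Each true CNV is detected with probability ``sensitivity``; detected
    calls get Gaussian breakpoint jitter (clamped so start < end and to
    chromosome bounds), may be fragmented into two sub-segments, and may
    have their class flipped.  False positives arrive as a Poisson process
    along each chromosome at ``fp_rate_per_mb`` with log-normal lengths and
    deletion-biased classes.  Marker counts come from ``marker_map`` when
    given, otherwise from the profile's nominal marker spacing.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[CallSetKey, CallSet] = {}

    def n_markers_for(chrom: int, start: int, end: int) -> int:
        if marker_map is not None:
            return max(1, marker_map.count_in(chrom, start, end))
        return max(1, int(round((end - start) / profile.marker_spacing)))

    def jitter(start: int, end: int, chrom_len: int) -> tuple[int, int]:
        if profile.breakpoint_jitter_sd <= 0:
            return start, end
        s = start + int(round(rng.normal(0, profile.breakpoint_jitter_sd)))
        e = end + int(round(rng.normal(0, profile.breakpoint_jitter_sd)))
        s = max(0, min(s, chrom_len - 2))
        e = max(s + 1, min(e, chrom_len))
        return s, e

    for sample_id in truth.samples():
        segments: list[GenomicSegment] = []
        for cnv in truth.for_sample(sample_id):
            if rng.random() >= profile.sensitivity:
                continue
            chrom_len = truth.genome[cnv.chrom]
            start, end = jitter(cnv.start, cnv.end, chrom_len)
            cls = cnv.cn_class
            if profile.class_confusion_prob > 0 and rng.random() < profile.class_confusion_prob:
                cls = CNClass.GAIN if cls is CNClass.LOSS else CNClass.LOSS
            pieces: list[tuple[int, int]]
            gap = profile.fragment_gap
            if (
                profile.fragmentation_prob > 0
                and end - start > 3 * gap
                and rng.random() < profile.fragmentation_prob
            ):
                mid = (start + end) // 2
                pieces = [(start, mid - gap // 2), (mid + gap // 2, end)]
            else:
                pieces = [(start, end)]
            for s, e in pieces:
                segments.append(
                    GenomicSegment(
                        chrom=cnv.chrom,
                        start=s,
                        end=e,
                        cn_class=cls,
                        cn_genotype=(
                            (1 if cls is CNClass.LOSS else 3)
                            if profile.emits_genotypes
                            else None
                        ),
                        n_markers=n_markers_for(cnv.chrom, s, e),
                        sample_id=sample_id,
                        tool_id=profile.tool_id,
                    )
                )
        # false positives: Poisson along each chromosome
        if profile.fp_rate_per_mb > 0:
            p_del = 0.8
            for chrom, chrom_len in truth.genome.items():
                lam = profile.fp_rate_per_mb * chrom_len / 1e6
                for _ in range(int(rng.poisson(lam))):
                    length = max(
                        200, int(rng.lognormal(np.log(8_000.0), 0.8))
                    )
                    if chrom_len <= length + 1:
                        continue
                    start = int(rng.integers(0, chrom_len - length))
                    cls = CNClass.LOSS if rng.random() < p_del else CNClass.GAIN
                    segments.append(
                        GenomicSegment(
                            chrom=chrom,
                            start=start,
                            end=start + length,
                            cn_class=cls,
                            n_markers=n_markers_for(chrom, start, start + length),
                            sample_id=sample_id,
                            tool_id=profile.tool_id,
                        )
                    )
        out[(sample_id, profile.tool_id)] = CallSet(sample_id, profile.tool_id, segments)
    return out


def simulate_dataset(
    n_trios: int = 60,
    n_loci: int = 400,
    profiles: Sequence[ToolProfile] | None = None,
    mean_freq: float = 0.15,
    freq_divergence: float = 0.0,
    ddr_target: float = 4.0,
    de_novo_rate: float = 0.01,
    private: bool = False,
    marker_map: MarkerMap | None = None,
    seed: int = 0,
) -> tuple[dict[CallSetKey, CallSet], Pedigree, TruthSet, CnvLocusPanel]:
    """One-stop simulation: panel + trios + per-tool call sets.

    Sub-stages consume independent child seeds spawned from ``seed``, so the
    whole dataset is reproducible from the single integer.
    """
    if profiles is None:
        profiles = default_profiles()
    root = np.random.SeedSequence(seed)
    panel_seed, trio_seed, *call_seeds = root.spawn(2 + len(profiles))
    panel = simulate_panel(
        n_loci,
        mean_freq=mean_freq,
        freq_divergence=freq_divergence,
        ddr_target=ddr_target,
        seed=np.random.default_rng(panel_seed),
    )
    truth, pedigree = simulate_trios(
        panel,
        n_trios=n_trios,
        de_novo_rate=de_novo_rate,
        private=private,
        ddr_target=ddr_target,
        seed=np.random.default_rng(trio_seed),
    )
    calls: dict[CallSetKey, CallSet] = {}
    for profile, cs_seed in zip(profiles, call_seeds):
        calls.update(
            simulate_calls(truth, profile, marker_map=marker_map, seed=np.random.default_rng(cs_seed))
        )
    return calls, pedigree, truth, panel


def simulate_marker_map(
    genome: Mapping[int, int],
    spacing: int = DEFAULT_MARKER_SPACING,
    jitter: float = 0.3,
    seed: int | np.random.Generator = 0,
) -> MarkerMap:
    """A marker map with roughly uniform spacing (desk-scale genomes only:
    a full hg19 map at array density would hold millions of markers)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    entries = []
    i = 0
    for chrom in sorted(genome):
        pos = int(rng.integers(1, spacing + 1))
        while pos < genome[chrom]:
            i += 1
            entries.append((f"m{i:07d}", chrom, pos))
            step = max(1, int(rng.normal(spacing, jitter * spacing)))
            pos += step
    return MarkerMap(entries)
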