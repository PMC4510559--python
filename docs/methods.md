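# Methods

## Segment model and coordinate conventions

Every CNV call is a half-open interval [start, end) on an autosome (1–22)
with 0-based integer coordinates, BED-compatible on disk.  A call carries a
CN *class* (loss/gain; the categorical direction of the variation) and
optionally a CN *genotype* (the integer copy count 0–6 reported by HMM-style
callers), which collapses deterministically onto a class (0,1 → loss, 2 →
normal, 3–6 → gain).  Standardization drops normal-class calls, restricts to
autosomes, and merges overlapping or book-ended same-class calls from one
(sample, tool) pair — the validation rule is phrased in terms of a per-base
union, which presumes a clean union is computable.  Calls are never merged
across classes, and short (< 1 kb) calls are retained.  Standardization is
idempotent and can only reduce the summed segment length.

Marker-level caller output (lists of markers with CN states) is converted to
segments as maximal runs of map-consecutive markers sharing one non-normal
state; a segment spans the first to the last marker position + 1, since
markers are points and no breakpoint between markers is observable.  A map
marker absent from the input (state unknown) breaks a run, so re-expanding
the output segments against the marker map reproduces the input states
exactly — this round trip is enforced by a property test.  An optional
max-gap merge across adjacent same-state runs is deliberately *not* applied
by default.

## Trio validation

For offspring segment *s* and one parent's call set *P*,
cov(s, P) = |s ∩ ⋃{p ∈ P same class}| / |s|.  The parents are evaluated
separately; pooling both parents' calls into one union would let two
half-covering parents validate a CNV neither carries.  Same-tool validation
uses strict `cov > t` (default t = 0.9); extended validation (parental calls
from any tool) uses `cov ≥ t`.  The two comparison conventions coexist in
the framework deliberately and are configurable; with continuous simulated
coverage values the difference is immaterial, but boundary cases in unit
tests pin down each mode's convention.  Validation granularity is CN class,
not genotype: requiring genotype identity would conflate caller disagreement
about dosage with disagreement about presence.

Coverage arithmetic is implemented by sorted-array interval operations
(merge, clip, sum) and is checked *exactly* — not approximately — against a
per-base brute-force counter on thousands of random small instances; the
oracle is an independent code path kept only in the test suite.

## Pseudo-validation (permutation null)

Common CNVs are carried by unrelated individuals, so part of the apparent
validation rate is chance.  The null reassigns parent *pairs* to offspring
by a uniform random derangement (no offspring keeps its own parents —
self-assignment would leak true validations into the null) and re-runs the
validation; 10 replicates are summarized by the median over replicates of
the per-sample median validated percentage, with IQR.  Scope is either
pooled across populations or within each population.  Two modelling choices
were genuinely open and are exposed as toggles with conservative defaults:
parent pairs travel as units (preserving within-couple CNV correlation),
and self-assignment is excluded.  Replicate *r* seeds its generator from
(seed, r), so results are reproducible and replicates independent.

Under perfect calling with locus frequency *f* per chromosome, a random
parent pair carries a given locus with probability q = 1 − (1 − f)⁴; the
pooled pseudo-validation rate converges to q.  This closed form calibrates
the null in the acceptance tests.  Because the parents' carrier states are
fixed across replicates, the Monte-Carlo error of the pooled rate is
governed by the number of distinct locus × parent-pair draws, not by the
replicate count; tolerances use that effective sample size.

## Concordance, consensus, external verification

Concordance is directional: predictor CNVs are scored by verifier coverage,
so a fragmenting caller can verify a coarse caller fully without the
converse.  Three measures are reported per ordered pair, each summarized
per sample and then as the cross-sample median: the median per-CNV
concordant-sequence percentage (per-CNV → per-sample median → cross-sample
median, in that order), the percentage of predictor CNVs verified at the
threshold, and the percentage of cumulated predictor sequence covered.
Optionally only family-validated predictor CNVs enter the comparison.

Consensus regions are defined by base-pair stacking depth: each tool's
same-class calls are unioned first (so within-tool overlaps count once),
then bases covered by ≥ k tools are emitted as maximal runs.  This is the
region-level reading of "called by at least k tools"; call-level reciprocal
overlap chains would make the consensus depend on fragmentation.  The
consensus is nested in k by construction and is verified against a per-base
depth oracle.

External verification against a reference variant set (e.g. a DGV-style
BED) reuses the coverage rule; it is class-aware by default with a
class-blind flag for references lacking gain/loss annotation.

## Signal formula layer

θ = 2/π·arctan(R_A/R_B) maps the two-channel intensity ratio to [0, 1]
(computed via arctan2 so a zero denominator yields the limit θ = 1; both
channels zero is an error).  BAF interpolates θ piecewise-linearly through
the genotype-cluster medians: 0 below θ^AA, 0 → 0.5 on [θ^AA, θ^AB],
0.5 → 1 on [θ^AB, θ^BB], 1 above.  The strict inequalities of the textbook
piecewise form leave the boundaries undefined; they are assigned by
continuity (the linear branches attain 0, 0.5, 1 there), making BAF total,
continuous and monotone.  Note an orientation wrinkle: θ as written
*increases with the A allele*, while BAF interpolation needs θ to increase
from the AA to the BB cluster; the conventional transform uses R_B/R_A.
Both orientations are supported via a flag rather than silently correcting
either convention.  LRR = log₂R^obs − log₂R^exp requires strictly positive
intensities.

## Feature statistics

Within-CNV inter-marker distance is span/(n_markers − 1) — the mean gap —
with CNVs of fewer than two markers excluded from the median; no standard
formula exists, and the per-CNV mean-gap-then-per-sample-median reading is
used (the pooled-gaps alternative is a documented variant).  DDR with zero
duplications is reported missing, not infinite.  Quantiles use linear
interpolation between order statistics package-wide.  The MAD defaults to
the 1.4826 normal-consistency scaling and is configurable; the
label-permutation test statistic |MAD_A − MAD_B| is scale-invariant under
permutation, so the choice does not affect p-values.

## Group comparisons

The HMM-vs-segmentation comparison pairs samples: per sample, the statistic
is the median over the tools of each class, and the paired vectors feed a
two-sided Wilcoxon signed-rank test (scipy; exact null for small n, normal
approximation with continuity correction otherwise; all-zero differences →
undefined, reported as such).  The test suite checks the p-values against
full 2ⁿ sign enumeration for n ≤ 10.  The inter-tool dispersion comparison
permutes class labels across tools; with six tools split 3/3 only 20
distinct assignments exist, so the test enumerates them exhaustively by
default and falls back to sampling (with the +1 correction) for larger
problems — a 10,000-draw sampler over a 20-element space is supported for
fidelity but statistically redundant.  Raw p-values are reported;
multiple-testing correction is off by default and available as a flag.

## Simulator

The generator emulates the structure of a two-population trio study:

* **Panel** — loci placed disjointly (5 kb guard) on hg19-length autosomes,
  chromosome chosen proportional to length; lengths log-normal with median
  10 kb and σ(log) = 0.8, matching the skewed kb-scale size spectrum of
  array-based CNV calls; class deletion with probability DDR/(1 + DDR),
  default DDR target 4 (within the 2.8–5.5 per-tool range of real call
  sets); per-population frequencies around a mean of 0.15 with optional
  log-normal divergence.
* **Trios** — default 60 trios split evenly between populations (the scale
  of the classic HapMap CEU/YRI trio panels), 400 loci giving on the order
  of 100–200 true CNVs per genome.  Parents carry 0/1/2 variant chromosomes
  per locus (each chromosome Bernoulli(f)); the offspring inherits one
  chromosome per parent, so transmission probability is copies/2 and a
  homozygous parent always transmits.  De novo events (default rate 1%,
  reflecting the ~99% inherited share of germline CNVs) are appended per
  offspring with a Poisson count calibrated so the expected de novo
  *fraction* of offspring CNVs equals the configured rate, and are placed
  disjoint from all panel loci so they can never be parent-validated —
  which makes the non-validated fraction under perfect calling an exact
  readout of the de novo fraction.
* **Callers** — a detected call (probability = sensitivity) gets Gaussian
  breakpoint jitter (clamped to keep start < end within the chromosome),
  may be split into two fragments around a fixed gap, and may flip class;
  false positives follow a Poisson process per chromosome with
  deletion-biased classes.  The stock `hmm_like` profile (sensitivity 0.92,
  0.012 FP/Mb, 300 bp jitter, no fragmentation) and `segmentation_like`
  profile (0.85, 0.045 FP/Mb, 800 bp jitter, fragmentation probability 0.3)
  reproduce the *direction* of the real-world contrast — more calls, lower
  family validity for segmentation-style callers — and claim nothing
  quantitative about any specific tool.

What the simulator does **not** model: genuine breakpoint uncertainty from
marker spacing (jitter is Gaussian, not marker-quantized), multi-allelic
and non-Mendelian inheritance, correlated errors between tools run on the
same intensity files, batch effects, and population differences in marker
coverage.  Passing the end-to-end tests therefore demonstrates the
correctness of the benchmarking arithmetic and its statistical calibration
under a clean generative model — not caller performance on real arrays,
where family validation remains a proxy for specificity and laboratory
validation of individual CNVs is still warranted.

## Numerical and degenerate-case choices

* Coverage ties at the threshold follow the mode's comparison (`>` vs `≥`),
  exercised by exact-boundary tests.
* Empty call sets yield no summary row (logged) rather than zeros; empty
  size bins report count 0 and an undefined rate.
* Derangements are sampled by rejection (uniform over derangements;
  acceptance probability → 1/e); a scope with one trio is an error.
* All generators are numpy `Generator`s seeded explicitly; dataset
  sub-stages consume seeds spawned from one root `SeedSequence`.
* Test problem sizes (e.g. 30 trios × 200 loci for the end-to-end checks,
  1,000 random instances for the interval oracle) were chosen to make the
  statistical tolerances — 3 standard errors of the relevant estimator —
  decisive at desk scale.
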