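# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic data does and does not
emulate, and the numerical conventions.

## Binding calls (`promtarget.peaks`)

Model: for one sequence ID with probes ordered by genomic start (ties by
probe id), the per-probe analysis value is the mean log2 enrichment across
ChIP replicates. Every window of `w = 5` consecutive probes (step 1; a
sequence ID with n probes has n − w + 1 windows) is tested with a
one-sample t-test against mean 0, df = w − 1, upper tail. Defaults:
`w = 5`, per-window `alpha = 0.0017`. The family-wise level over n windows
is `1 − (1 − alpha)^n` under independence; `adjusted_alpha(0.0017, 30)`
≈ 0.0497 documents the conventional "~30 windows ⇒ ~0.05" calibration.
Note that a 35-probe sequence ID literally has 31 windows; the function
takes the window count as an argument, so both conventions are available.
Because overlapping windows are positively correlated, the realised
family-wise rate is below the independence bound — measured at ≈ 0.04 on
10,000 null sequence IDs (see `scripts/acceptance.py`).

A sequence ID is bound iff ≥ 1 window is significant. Its effect size is
the **maximum window mean** over all windows (log2 scale), so the 0.25
threshold downstream corresponds to a 1.2-fold enrichment of the best
window; the alternative (mean of significant windows) was rejected because
the threshold is stated as a fold enrichment, which is a single window's
scale. Degenerate zero-variance windows are significant iff their mean is
positive (t → +∞) and are flagged. Sequence IDs with fewer than w probes
are reported `untestable`, not errors.

Gene assignment: a sequence ID spanning `[start, end)` is assigned every
gene whose coding interval intersects `[start − 10 kb, end + 10 kb)`
(half-open arithmetic throughout); an empty assignment marks it
intergenic.

## Expression calls (`promtarget.expression`)

Pooled-variance Student's t (not Welch) per probe set: with equal small
group sizes (default 4 vs 4) the pooled form is the classical choice and
the two coincide at exactly equal n. p-values are two-sided from t with
n₁ + n₂ − 2 df; no multiple-testing correction is applied across probe
sets — error control happens downstream by requiring independent binding
evidence.

Consistency filter: a gene is ambiguous iff it has ≥ 2 *significant*
probe sets with both effect signs. Restricting the sign comparison to
significant probe sets avoids discarding genes over noise-level sign flips
in non-significant probe sets. Single-probe-set genes are vacuously
consistent. Gene-level effect size = mean of the significant probe-set
effects (the analysis reports a single per-gene effect without stating an
aggregation rule; the mean is the least committal choice, and the min-p
alternative differs only in pathological cases).

Degenerate inputs: zero pooled variance with zero difference gives
t = 0, p = 1; with a nonzero difference, p = 0 with a `degenerate` flag.

## Integration (`promtarget.integrate`)

Symbols are matched case-sensitively after whitespace trimming; empty
symbols never match. A gene bound via several sequence IDs takes the
maximum binding effect (parallel to the max-window rule). Filters are
strict inequalities (`> 0.25`, `> 0.5`); both thresholds are arguments, so
the stricter 2-fold variant is `expr_threshold = 1.0`. Reported
percentages are `100·count/denominator` rounded **half-up** to one
decimal, with the raw value carried alongside. The enrichment operation
is the upper hypergeometric tail P(X ≥ k) with population |universe|,
successes |category| and draws |targets| — the right-tailed Fisher test
for a 2×2 table.

## Motif analysis (`promtarget.motifs`)

Matching is exact IUPAC consensus — no mismatches and no position-weight
scores, because the analysis counts consensus occurrences. An `N` in the
sequence matches only a consensus `N`. Both strands are scanned by default
(CACCC-box biology is strand-agnostic); reverse-strand hits are reported
by the forward-strand offset of their 5'-most base, and palindromic
consensi are scanned once. TSS-relative coordinates skip zero
(…, −2, −1, +1, +2, …), the classical promoter convention.

Frequency ranking is by the number of sequence IDs containing the motif
(ties: total hits, then name); both presence and total-occurrence counts
are emitted because published summaries are ambiguous between them.

Co-occurrence distances: all (reference, partner) occurrence pairs within
a sequence ID compete; the signed distance `partner − reference` with the
smallest |d| is the per-sequence representative, an exact upstream/
downstream tie resolving to the upstream (negative) value. Distances are
computed on raw sequence offsets; they differ from TSS-relative position
differences only for pairs straddling the TSS (by the one skipped
coordinate). Histograms use half-open 50-bp bins over ±1000 bp with
out-of-range records tallied separately.

The promoter-box annotator scans the forward strand for CACCC, CCAAT
(accepting ATTGG, the reverse-orientation CCAAT box) and TATAA. The
bundled Tal1-style fixture reproduces the mapped erythroid promoter
architecture (CACCC at −788/−710/−185, CCAAT at −133/−57, TATA at −28) on
a background scrubbed of any other core-box occurrence, so annotation is
exact; the mutated-box fragments (`TAL1_MUT_E1/E2/E3`) are scanner
negative controls.

## Synthetic data (`promtarget.simulate`)

What it emulates: the array geometry (5–35 probes of 49–74 bp per
sequence ID at ≥ 100 bp start-to-start spacing within a 4.5 kb promoter
span; a configurable intergenic fraction, default 3%), two independent
ChIP replicates, four WT and four KO expression replicates with 1–3 probe
sets per gene, and uniform-ACGT promoter sequences with motifs planted at
exact TSS-relative positions.

Study conditions (defaults): binding shift `chip_effect = 0.5` and
expression effect `|expr_effect| = 1.0` at `noise sd 0.25` on the log2
scale for both platforms; `bound_fraction = 0.25` and `de_fraction = 0.5`,
the rates observed on the platforms being emulated (≈ 25% of promoters
bound, ≈ half of probe sets differential). Spiked enrichment covers a
contiguous run of 8–12 probes (~0.8–1.2 kb at ~100 bp spacing), the width
of a typical displayed promoter-array binding peak; a run of ≥ 5 is
required so at least one window covers it fully. Each sequence ID lives in
its own 50 kb genomic slab, which guarantees no foreign gene within 10 kb
and makes gene assignment unambiguous. All genes are generated on the
forward strand (the strand column exists for real-data compatibility;
promoter sequences are generated independently per sequence ID, so strand
would add no information here).

"Inter-probe distance" is implemented as start-to-start spacing: ~36
probes per 4.5 kb span imply ~128 bp spacing, which is only consistent
with the stated 100–3700 bp range under the start-to-start reading. The
per-sequence-ID spacing draw is capped so the probes fit the span;
infeasible geometry (probe count × minimum spacing exceeding the span)
raises with an explanatory message.

What it does **not** emulate: probe GC/affinity effects, dye bias,
spatial artifacts, cross-hybridization, MAS5-style probe-level
summarisation, correlated noise between replicates, or realistic genomic
sequence composition. Passing tests therefore demonstrate the correctness
and calibration of the *statistics* under the assumed Gaussian model, not
robustness to array artifacts.

Determinism: every generator draws from `default_rng([seed, stream])`
with a fixed stream id per generator, so outputs are reproducible and
independent of invocation order.

## Pipeline (`promtarget.pipeline`, CLI `promtarget`)

Stages run in order simulate → expression → peaks → integrate → motifs,
all thresholds living in `RunConfig` (YAML) defaults. The motif stage
restricts scanning to bound promoters when binding calls are available,
mirroring the co-occurrence analysis of bound-and-regulated promoters.
Every count in the run report equals the row count of the corresponding
output TSV, and identical config + seed reproduces outputs byte for byte.

## Problem sizes

The test suite and acceptance script run at desk scale by design: 10,000
null sequence IDs for the family-wise calibration, 1,000 sequence IDs /
~970 genes for the end-to-end recovery experiment, 2,000 genes for the
type-I-error check, 500 promoters for the distance-concentration
experiment, and 1,000 random sequence IDs / 4,000 scanner comparisons for
the oracle checks. Full-platform scale (21,536 sequence IDs) is a
configuration choice, not a code change.

## Known limitations

* Consensus-only motif model; no PWM/HMM scoring or conservation.
* No FDR control across sequence IDs or probe sets (by design of the
  recipe being implemented; the integration step is the error control).
* Gene-symbol joins ignore synonyms; annotation quality is the caller's
  responsibility.
* The generator's Gaussian, artifact-free noise makes the recovery
  figures an upper bound on what real arrays would give.
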