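# Methods

## Scope and data model

`rtsig` analyzes reverse-transcription (RT) signatures in (t)RNA-seq data at
single-base resolution. Its inputs are reference sequences (FASTA; RNA `U`
normalized to DNA `T`; identifiers kept verbatim to the first whitespace so
pipe-delimited tRNA ids survive), mapped alignments (SAM/BAM; unmapped,
secondary and supplementary records skipped) and a modification annotation
table (TSV: `ref_seg`, 1-based `pos`, short code such as `m1A`). Alignment
itself is out of scope: reads arrive mapped, e.g. by Bowtie 2 with a
mismatch-tolerant policy appropriate for heavily modified tRNA (about one
mismatch per 22 nt); soft-clipped tailing remnants should be trimmed
upstream.

Coordinates are 1-based and closed everywhere outside the I/O layer. Read
orientation comes from pairing flags (first-in-pair → forward, counted in
the capital-letter profile columns; second-in-pair → reverse, small
letters; unpaired → forward). It is deliberately *not* taken from strand
flags: the capital/small split mirrors forward vs. reverse reads of a
paired-end run over single-stranded tRNA references.

## The profile file

One row per reference position with coverage ≥ `min_cov` (default 20, the
boundary inclusive — a data-quality filter, not a statistical one), 21
tab-separated columns: `ref_seg, mod, pos, ref_base, cov, pre_base,
mism_rate, A, G, T, C, N, a, g, t, c, n, single_jump_rate_direct,
single_jump_rate_delayed, double_jump_rate, arrest_rate`. Rates are
serialized with 5 decimals; reading a profile back is lossless at that
precision. `pre_base` is the 3′ neighbour (`pos + 1`) — the template base
the enzyme reads immediately *before* reaching the position — empty at the
3′ terminus.

Definitions, for position N on one reference:

* **coverage** `cov(N)`: aligned bases only, summed over the ten
  orientation-split counters. A read whose deletion spans N contributes to
  the *span* of N but not to its coverage.
* **mismatch rate** `(cov − matches)/cov` with matches =
  `#ref_base(forward) + #ref_base(reverse)`. `N` calls never match but stay
  in the denominator. This convention is forced by exact agreement with the
  built-in ten-row worked-example profile, which contains rows with
  `N > 0`; all ten printed rates reproduce to 5 decimals.
* **arrest rate** `clamp((cov(N+1) − cov(N))/cov(N+1), 0, 1)` when
  `cov(N+1) > 0`, else 0; 0 at the 3′-terminal position. The RT proceeds
  3′→5′, so coverage can only drop (in expectation) toward 5′; the clamp
  absorbs mapping noise that would otherwise produce negative rates.
* **jump rates**: denominator = reads spanning N (deletion-bearing reads
  included — they have no aligned base at N and would otherwise vanish
  from the denominator). Numerators: deletion at N only (direct), at N−1
  only (delayed, attributed to N), at both (double). At N = 1 delayed and
  double are structurally 0.

The profiler is a single-pass accumulator; a property-based test checks it
against an independent brute-force implementation that re-walks every read
for every position, on randomized read sets including insertions,
soft-clips and multi-segment deletions.

## The simulator

`simulate_library` emulates cDNA synthesis molecule by molecule. The walk
starts at the 3′ end; at each position one event is drawn from the site's
`ModEventParams` (the per-modification entry at annotated sites, one shared
small `background` elsewhere):

* **arrest** — synthesis terminates *before* incorporation opposite the
  site, so the abortive fragment covers positions strictly 3′ of it. This
  choice (the paper trail of real protocols is ambiguous on whether an
  arrested cDNA retains a base opposite the modification) makes the
  coverage-drop arrest estimator asymptotically unbiased.
* **direct jump** — 1-nt deletion at N, continue at N−1.
* **delayed jump** — normal incorporation at N, deletion at N−1, continue
  at N−2. The event is attributed to N in the ground truth, matching the
  profiler's delayed-jump attribution.
* **double jump** — 2-nt deletion spanning N−1..N, continue at N−2.
* **read-through** — incorporate a base drawn from the site's
  incorporation distribution.

At position 1 a delayed jump degrades to read-through and a double jump to
a direct jump (no 5′ neighbour exists); the ground truth records the
degraded class, preserving the conservation invariant that event counts at
a site sum to the number of molecules that drew an event there.

Misincorporation is parameterized as a total mass `p_mismatch` split over
the three non-reference bases plus `N` (`n_fraction`). Optionally
`prebase_bias` routes that share of the substitution mass to the prebase
base when it differs from the reference base — in the worked-example rows
the dominant misincorporated base visibly tracks the prebase (C after C,
T after T, G after G), a slippage-like pattern the bias reproduces.
`mismatch_dist(ref_base, prebase)` materializes the vector; its reference
entry is the correct-incorporation mass and it sums to 1.

Reads longer than `read_length` are truncated keeping the 5′-most aligned
bases (the signature-rich end); a `paired_fraction` of molecules is also
emitted as a reverse-orientation mate over the 3′-proximal window,
mirroring 2 × 75 bp paired-end geometry. Each reference has its own RNG
substream derived from `(seed, CRC32(ref_seg))`, so adding a reference
never perturbs another's reads.

### Presets

`builtin_presets()` ships five EpiScript conditions (Mg 3 mM reference;
MnCl₂ at 0.5, 1, 3, 5 mM). The m1A anchors are measured averages: arrest
0.82 → 0.24 and misincorporation mass 0.54 → 0.80 between the reference
and Mn 3 mM. Remaining numbers are stylized but ordered by the qualitative
record: the modified-site effect peaks at 3 mM and falls off slightly at
5 mM; background errors rise continuously with MnCl₂ and stay in the
low-percent range; m22G responds less strongly than m1A; jump mass is
small and delayed-dominant (see below). All preset values live in
`src/rtsig/data/presets.yaml` with inline rationale.

### Estimator coupling — why preset jumps are delayed-dominant

The three features are not estimated on independent denominators, and the
estimators conflate event classes in known ways:

* the arrest estimator measures `p_arrest + p_jump_direct + p_jump_double`
  — direct and double jumps also remove the aligned base at N, so the
  coverage drop attributes them to arrest;
* the jump estimators measure `p_jump / (1 − p_arrest)` — arrested
  molecules never span the site, shrinking the denominator;
* the mismatch estimator is unbiased for `p_mismatch` regardless of the
  other probabilities (its denominator is exactly the incorporations).

The presets therefore keep direct + double jump mass small (≤ 0.008) and
put the manganese-driven jump increase into the delayed class, which
leaves the arrest feature interpretable; mechanistically this reads as
incorporation at the modified site followed by slippage over its 5′
neighbour. Validation runs that quote a single generating probability
(parameter recovery at 10,000 molecules, three binomial standard errors)
probe one feature at a time with the other event classes switched off, so
each recovered rate is an unbiased binomial estimate of its generating
value.

## Signature statistics

Selections are by modification status against the annotation: a specific
code, `modified` (any annotated site), `unmodified`, or everything.
Summaries report median and mean with bootstrap percentile 95% CIs (10,000
resamples by default, seeded and reproducible). Condition comparisons
match positions on `(ref_seg, pos)` — a position must pass the coverage
filter in both conditions — and test the per-position deltas
(treated − reference) with a two-sided Wilcoxon signed-rank test;
unmatched pools use a two-sided Mann–Whitney U. α = 0.05, no
multiple-testing correction (flags are per panel, as in the visualizations
this mirrors; all-zero deltas report p = 1, fewer than two matched
positions report p undefined and non-significant). The aggregate "jump
rate" of condition-level statements is `jump_total`, the per-position sum
of the three deletion classes. `prevalence` reports the percentage of
selected positions whose feature exceeds a threshold (default 0:
"positions bearing a jump at all"). `mismatch_composition` pools
non-reference base counts (forward + reverse merged, `N` included) over a
selection, optionally stratified by prebase, normalized to 1 per stratum.

## Validation and problem sizes

The test suite and `scripts/acceptance.py` compute everything they assert:

* the ten built-in worked-example rows reproduce their printed mismatch
  rates (5 decimals) and coverages (counter sums) exactly;
* profiler vs. brute-force oracle equivalence over ≥ 200 randomized read
  sets of up to 50 reads;
* parameter recovery at n = 10,000 molecules within 3 binomial standard
  errors for arrest 0.82/0.24, mismatch mass 0.54/0.80 and jump 0.04/0.49;
* under the full Mg/Mn presets (3 references × 10,000 molecules), the
  matched m1A arrest delta lands near −0.58 and the mismatch delta near
  +0.26;
* null calibration: 100 repeated comparisons with identical generating
  parameters (12 matched modified sites, 400 molecules per reference) flag
  significance within the 99% binomial band around the nominal 5% — the
  exact signed-rank test is discrete at n = 12, so the realized rate runs
  conservative (a few percent);
* the coverage filter keeps exactly the positions with cov ≥ 20.

Problem sizes were chosen so the whole suite runs in about a minute and the
acceptance script in about one minute on one CPU, while keeping Monte
Carlo error well inside the stated tolerances.

## What the synthetic data does and does not show

The simulator reproduces the *structure* of RT-signature data —
modification-dependent arrest/mismatch/jump generation, paired-end
orientation splits, coverage decay toward 5′, prebase-dependent
misincorporation — with known ground truth, which is what the profiling
and statistics layers need for validation. It does not model sequencing
base-call errors beyond the substitution channel, quality scores, PCR
duplication, ligation or tailing biases, multi-mapping between near-identical
tRNA isoacceptors, or position-specific background variation (background
parameters are shared across unmodified sites). Passing tests therefore
demonstrate correctness of the estimators and statistics on data of this
structure, not robustness to every artifact of real libraries.

## Known limitations

* The arrest/jump coupling above means that on real data with abundant
  direct/double deletions, "arrest rate" reads as "synthesis-loss rate at
  the site" (arrest plus site-skipping); the profile columns keep the
  classes separate so users can decompose it.
* The jump denominator (spanning reads) is one of two defensible choices;
  aligned-base coverage is the other. Published profile tables cannot
  disambiguate which convention legacy pipelines used.
* Negative coverage drops are clamped to 0; noisy positions can silently
  hide small real effects below the mapping-noise floor.
* The fixture references are random sequences without tRNA secondary
  structure or full modification complements.
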