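# rtsig — reverse-transcription signature profiling of tRNA modifications

Many modified ribonucleosides — m1A, m22G, m1G, m3C among them — carry
methyl groups on the Watson–Crick face of the base. When a reverse
transcriptase (RT) copies such a template into cDNA, the blocked base
pairing leaves a characteristic trace in deep-sequencing data: the enzyme
misincorporates non-complementary dNTPs (**mismatch**), aborts primer
extension (**arrest**), or skips one or two template nucleotides, visible
as deletions (**jump**). The per-position pattern of these three event
rates is the **RT signature**, and it is the raw material of
sequencing-based RNA-modification detection. Reaction conditions reshape
it: replacing Mg²⁺ with Mn²⁺ in the RT buffer makes polymerases read
through blockades — arrest collapses while mismatch and jump rates rise.

`rtsig` is a Python library (plus a thin `rtsig` CLI) for this analysis:

* **profiling** — turn SAM/BAM alignments of (t)RNA-seq reads into a
  per-position *profile file*: coverage, base counts split by read
  orientation (capital letters for forward reads, small for reverse),
  prebase, mismatch rate, arrest rate and the three jump-class rates,
  discarding positions with coverage < 20;
* **annotation** — mark modified sites from a Modomics/tRNAdb-style TSV;
* **signature analysis** — per-modification distributions (median/mean
  with bootstrap 95% CIs), matched condition comparisons (Wilcoxon
  signed-rank), prevalence fractions and mismatch composition by prebase;
* **simulation** — a seeded reverse-transcription simulator with
  modification-dependent arrest, misincorporation and nucleotide-skipping
  probabilities, including built-in presets for an Mg 3 mM reference and
  MnCl₂ buffers at 0.5/1/3/5 mM, emitting SAM plus a ground-truth table.

## The statistics, briefly

For a reference position N with aligned-base coverage `cov(N)` (a read
deleting N does not count):

* mismatch rate = `(cov(N) − matches(N)) / cov(N)`, where matches are
  aligned bases equal to the reference base; `N` base calls count as
  mismatches and stay in the denominator;
* arrest rate = `clamp((cov(N+1) − cov(N)) / cov(N+1), 0, 1)` — the
  relative coverage drop from the 3′ neighbour, since the RT walks the
  template 3′→5′ and an abortive cDNA ends just 3′ of the blocking site;
* jump rates = over reads *spanning* N, the fraction with a deletion at N
  only (single jump direct), at N−1 only (single jump delayed, attributed
  to N), or at both (double jump).

## Worked example

`examples/03_compare_conditions.py` simulates six templates bearing an m1A
site under the Mg reference and Mn 3 mM presets, profiles both libraries
and compares the matched m1A positions:

```
m1A arrest    : reference mean 0.823 -> treated mean 0.249, mean delta -0.574, p=0.0312 *
m1A mismatch  : reference mean 0.534 -> treated mean 0.802, mean delta +0.268, p=0.0312 *
m1A jump_total: reference mean 0.110 -> treated mean 0.134, mean delta +0.024, p=0.0312 *
```

Arrest collapses from ~82% to ~24% while mismatch rises from ~54% to ~80% —
the manganese read-through effect the presets encode; asterisks flag
p < 0.05 in the two-sided Wilcoxon signed-rank test over matched positions.
The other examples show library simulation with ground-truth tallies
(`01`), the 21-column profile file itself (`02`), and mismatch composition
stratified by prebase on the package's built-in ten-row worked-example
profile (`04`), where the dominant misincorporated base visibly tracks the
base the enzyme read just before the site.

The same pipeline is available from the shell:

```
rtsig simulate --refs refs.fasta --ann ann.tsv --preset EpiScript_Mn_3mM \
    --seed 1 --out treated.sam --truth treated.truth.tsv
rtsig profile  --refs refs.fasta --ann ann.tsv --alignments treated.sam \
    --out treated.profile.tsv
rtsig compare  --reference reference.profile.tsv --treated treated.profile.tsv \
    --ann ann.tsv --mod m1A --feature arrest --out deltas.tsv
```

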