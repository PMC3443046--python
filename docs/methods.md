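# Methods

This note records the models, parameter choices and numerical conventions
behind `longamp`, and what the synthetic experiments do and do not show.

## Read simulation

### Error model

Reads are generated by walking a template (one haplotype of an amplicon) and
emitting, per template base:

* with probability `p_del` (default **0.02**): skip the base (deletion, `D`);
* otherwise emit it, miscalled to a uniformly chosen different base with
  probability `p_mis` (default **0.01**; `X` vs `M`);
* after each emission, append uniformly random inserted bases in a geometric
  run with continuation probability `p_ins` (default **0.12**, `I`), so the
  expected number of insertions per emitted base is `p_ins/(1-p_ins)` and the
  fraction of read bases that are insertions is exactly `p_ins`.

Event rates are position-independent by construction; the per-cycle event
rate regressed on cycle over >10⁶ simulated bases has |slope| < 10⁻⁵ per
base (asserted in the tests).  Every read carries its exact event walk
(`TrueAlignment`), which downstream stages use as an oracle.  Unanchored
deletions at either end of the walk are trimmed and the reference span
adjusted, since an alignment cannot express them.

The insertion run-length law (geometric) and the uniform base composition of
inserted/miscalled bases are modeling choices; no run-length distribution is
claimed by the data the model emulates.  Reported base qualities are flat
**Q20**, which is the recalibrator's starting prior, so the reported-quality
covariate is degenerate on simulated data (it is kept in the hierarchy so
real FASTQ input works unchanged).

### Read lengths

Lengths follow a log-normal solved from two constraints: mean **700** bases
and **5%** of reads longer than **2,500** bases.  Substituting
`mu = ln(mean) - sigma²/2` into the tail constraint gives
`sigma²/2 - z·sigma + ln(2500/mean) = 0` with `z = Φ⁻¹(0.95)`; the smaller
positive root is used (`sigma ≈ 1.245`, `mu ≈ 5.776`).  The pair
(mean < threshold, 0 < tail < 0.5) outside the discriminant's range is
rejected as infeasible; a zero tail is infeasible for any log-normal.
Lengths are floored at 50 bases and truncated to the source fragment.

### Coverage model

Fragment starts are uniform over an interval extended by the read length
past both amplicon ends, with the fragment truncated to the amplicon — the
natural model of sheared amplicon molecules, which tiles coverage uniformly.
Interior-only starts would instead peak mid-amplicon and halve coverage near
the ends where sites sit.  Reads are drawn until the accumulated reference
span reaches `depth × amplicon_len` (default depth **70**), which pins the
realized mean fold coverage at `depth` exactly regardless of edge truncation
and of the insertion-driven inflation of read length relative to reference
span.  Read starts remain random, so per-site depth still fluctuates.

On short (2 kb) amplicons the observed mean read length is truncation-limited
(~400 bases at the defaults); the configured length law is recovered on
contigs much longer than the mean read length.

### Truth panel

Each panel plants `n_true_sites` (default **38**) heterozygous true-de-novo
SNPs — the alternate allele on exactly one haplotype — and `n_artifact_sites`
(default **60**) artifact sites recorded in the truth VCF but absent from
both haplotypes, i.e. 98 sites total.  (An alternative design of 48/72 = 120
candidate sites is reachable through the same two parameters.)  Sites keep
≥10 bases of separation and a 200-base margin from amplicon ends.  Alleles
are drawn uniformly from the three non-reference bases.

## Alignment

The aligner is a three-state affine-gap dynamic program (match/mismatch
state plus one insertion and one deletion state), *glocal*: the read aligns
end-to-end, the reference interval is free at both ends and is reported as a
start offset, never as CIGAR ops.  Scoring defaults are
`match +1, mismatch 5, gap open 2, gap extend 1`; the constructor enforces
`gap_open < mismatch`, the regime that makes 12%-insertion reads alignable
and that produces reference bias.  Conventions:

* a gap run of length L costs `gap_open + L·gap_extend`; direct transitions
  between adjacent insertion and deletion runs are allowed, each run paying
  its own open penalty;
* ties are broken deterministically: match state preferred over insertion
  over deletion, and the smallest reference end among equal final scores;
* indel ops are reported as traced, not left-normalized, because the
  placement of gaps is itself the object of study (reference bias);
* scores are integers; the reported score always equals recomputation from
  (CIGAR, read, reference).

Demultiplexing (`assign_amplicon`) aligns both orientations against every
panel amplicon.  Two exact-by-default accelerations are used: candidate
(amplicon, orientation) pairs are pre-ranked by glocal edit distance (edlib,
infix mode) and only candidates within a margin of the best distance receive
the affine DP; and the DP is restricted to a reference window of half-width
`max(32, ceil(3·read_len·(p_ins+p_del)))` around the edlib hit.  Both can be
switched off for a provably exhaustive search; equality of the two paths is
asserted on seeded instances in the tests.  For mutually dissimilar amplicon
panels (the intended use) the accelerated path returns the same best record.

## Error profiling

Each aligned read base is classified MATCH/MISMATCH/INSERTION by comparison
to the reference; deletions are attached to the preceding read position.
Cycles (read positions) are counted in sequencing orientation, so
reverse-strand alignments are re-indexed from the read's 3' reference end.
Rates use **aligned read bases (M + I ops)** as the common denominator, so
the three mode rates sum coherently; with that denominator the generator's
insertion parameter is recovered exactly and the deletion parameter maps to
`p_del(1-p_ins)/(1-p_del)` ≈ 1.8% at the defaults.  Alignment itself
converts a small fraction of adjacent single-base insertion+deletion pairs
into apparent mismatches (a mismatch costs less than two opened gaps), so
profiled rates on aligner output differ slightly from the walk's event
fractions — measured: insertion ~12.0%, deletion ~1.8–1.9%, mismatch
~0.9–1.0%.  Bases at known variant sites are included by default (het
alleles then count as mismatches); an exclusion switch drops them.

The per-cycle table is truncated at cycle 1000 by default (configurable);
observation counts are non-increasing in cycle by construction.

GC bias: the reference is cut into non-overlapping 100-base windows
(configurable), window coverage is aligned reference-consuming bases (M and
D) divided by window size, windows are binned by GC fraction in 5% bins, and
each bin reports mean coverage relative to the global mean over all windows;
the window-weighted mean of relative coverage is 1 by construction.  Bins
with fewer than 5 windows are flagged low-confidence.

## Base-quality recalibration

Counts of (observations, mismatches) are accumulated for every M-op base
outside known variant sites — insertions and deletions carry no mismatch
signal and are excluded — at four hierarchy levels: read group; (read group,
reported quality); (…, cycle); (…, dinucleotide), where the dinucleotide is
(previous base, current base) in sequencing orientation with an `N` sentinel
at cycle 1.  Child counts sum to parent counts at every level.

Empirical quality uses additive smoothing, `Q = -10 log10((m+1)/(n+2))`,
capped at 60: it is finite for error-free bins (n=0,m=0 gives the
uninformative ~3.01) and monotone non-increasing in m.  Recalibrated quality
composes the read-group quality with deltas of each level against its parent
(`quality` against read group; `cycle` and `dinucleotide` against their
quality bin), applying a delta only where the bin has ≥ `min_obs` (default
**100**) observations, then clamps to [2, 60] and rounds.  The smoothing
introduces a small downward bias in sparse bins (`(m+1)/(n+2)` vs `m/n`),
which is why a doubled late-cycle error rate is recovered as a delta of
~2.9 rather than the asymptotic `10·log10 2 ≈ 3.01` at a few tens of errors
per bin.

A caution for interpreting recalibrated values: when two covariates are
strongly aliased (e.g. identical reads, where cycle determines dinucleotide),
their deltas double-count the same fluctuation and per-value calibration
degrades; with reads at random offsets the covariates decorrelate and
`|Q - (-10 log10 r)| ≤ 1` holds for well-populated quality values.

## Genotyping

Pileup entries are (base, quality, strand) from M ops; reads whose alignment
deletes the position are counted separately; inserted bases never enter the
column.  A site is suppressed (no-call) when the deletion fraction
`n_del / (n_del + n_entries)` exceeds `max_deletion_fraction` — default
**0.5**, following the stated intent ("up to 50% deletions") rather than the
`0.8` flag value it is sometimes encoded as; both are exposed.  Bases below
`min_base_quality` (default **Q10**) and bases matching neither ref nor alt
are dropped; zero retained bases is a LOW_DEPTH no-call.

Likelihoods: `P(b|allele) = 1-e` or `e/3` with `e = min(10^(-Q/10), 3/4)`
(the cap makes a Q0 base uninformative rather than impossible); diploid
`P(b|a₁a₂) = ½P(b|a₁) + ½P(b|a₂)`; log-likelihoods sum over retained bases.
Priors `(1-3θ/2, θ, θ/2)` with `θ = 10⁻³`; QUAL is the PHRED-scaled
posterior against hom-ref (capped at 9999), PL is the 0-normalized
PHRED-scaled likelihood triple, and a site is polymorphic when
`QUAL ≥ call_confidence` (default **30**).  Discovery mode tests the most
frequent quality-filtered non-reference base at every position.

## Validation and reference bias

Genotype-and-validate force-calls each truth-VCF site with the VCF's own
alternate allele and maps (truth status × polymorphic) to TP/FN/FP/TN; sites
with zero usable coverage or suppressed by the deletion filter are NO_DATA
and excluded from metric denominators (the emulated study had none).
Metrics are sensitivity `tp/(tp+fn)`, specificity `tn/(tn+fp)`, PPV
`tp/(tp+fp)`, NPV `tn/(tn+fn)`, reported at full precision and rounded to
whole percent.

The reference-bias report counts ref/alt pileup bases at known het sites
after Q10 filtering and scans each spanning read for the alternate allele
inside insertions whose anchor lies within `k = 5` bases of the site
(VISIBLE / HIDDEN / ABSENT; exact alt-base matches only).  The recovered
allele fraction `(n_alt + n_hidden)/(n_ref + n_alt + n_hidden)` is
non-decreasing relative to the visible fraction by construction.  Note the
scan has a chance-hit baseline: at a 12% insertion rate a ref-haplotype read
has an appreciable probability of carrying the alt base inside a nearby
random insertion, so HIDDEN counts are slightly inflated on truth and
aligner output alike, and the recovered median can land marginally above
0.5.  Only directional statements (aligned median ≤ truth median; recovery
non-decreasing) are asserted.

## End-to-end experiments and problem sizes

The validation experiment plants 38 true het + 60 artifact sites on four
2 kb amplicons, simulates to 70x, aligns, recalibrates, force-calls all 98
sites and reports the confusion matrix; under seeds examined it classifies
all or all-but-one site correctly (sensitivity ≥ 97%, specificity ≥ 95%).
The discovery experiment calls every position de novo and partitions missed
planted sites into `low_coverage` (quality-filtered depth < 10),
`reference_bias` (≥ 2 HIDDEN reads at the site), and `other`.

Test and acceptance runs use desk-scale problem sizes chosen to keep
statistical error well inside the asserted tolerances: ~1.5–3×10⁵ aligned
bases for rate recovery (binomial s.e. ≲ 0.1 points), ≥10⁶ walked bases for
the positional-slope bound, 10⁴ reads for length-law recovery, and one 70x
panel for the end-to-end experiment.  A single seed drives each experiment;
panel construction and read simulation draw from seed-derived substreams so
stages are independently reproducible, and the pipeline manifest records
output hashes for byte-identity checks.

## What the synthetic data does not show

The generator emulates the error *profile*, not the instrument: no
polymerase kinetics, no circular-consensus subread structure, no chimeras or
PCR duplicates, no quality-value noise, no context-dependent error hotspots
(an optional artifact-site error mode is deliberately absent from the DNA by
default).  Passing tests therefore demonstrate the correctness and internal
consistency of the pipeline and the qualitative phenomena (flat error
profile, reference bias, recalibration behavior) — not platform performance
on real libraries, where PCR efficiency, context effects and subread
filtering add failure modes the simulation excludes.  Real-data discovery
shortfalls (e.g. low-coverage dropouts from poor amplification) are
represented only through their mechanism, not their observed frequencies.
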