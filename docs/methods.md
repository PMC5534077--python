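# Methods

This note records the models, conventions and tunable parameters behind
`mhcdoc`, the choices made where the procedure is genuinely open, and
what the simulation-based tests do and do not demonstrate.

## The genotyping model

An *amplicon* is the set of reads from one PCR of one sample, identified
by its unique forward/reverse 6 bp tag pair.  After preprocessing, an
amplicon is a table of distinct trimmed insert sequences ("variants")
with read depths.  The analysis assumes true alleles amplify at markedly
higher depth than artefacts, so correct genotyping reduces to locating
the boundary in the ranked depth list.

Two stages sharpen and then locate that boundary:

**Error correction** deletes variants that are recognisably derived from
a deeper "parent" variant — 1–2 substitutions away, or one single-base
indel inside a homopolymer run of length ≥ `run_min` (default 3) — and
adds their reads to the parent.  The decisive evidence is cross-amplicon
occurrence, evaluated on a snapshot of the uncorrected, length-filtered
table so the per-amplicon processing order cannot erase it:

* *454 rule*: a candidate (depth < 50% of the parent, strictly) is an
  artefact iff it occurs in exactly one amplicon of the run.  454-style
  substitution errors hit random positions, so recurrence across
  amplicons indicates a real allele.
* *MiSeq rule*: substitution errors recur at the same sites across
  amplicons, so recurrence proves nothing.  A 1–2 nt variant is a true
  allele only if its depth exceeds 50% of the parent's (strictly) in
  *every* amplicon where the two co-occur, or if it occurs in at least
  one amplicon without the parent.
* *Homopolymer rule* (both platforms): artefact iff shallower than the
  parent and never observed without it.

When several parents qualify, the deepest is taken.  Candidates are
processed shallowest-first within an amplicon so artefact-of-artefact
cascades fold inward.  A variant private to one sample is never deleted
for privacy alone.  Reads are moved, never destroyed: per-amplicon
totals are invariant under correction.

**DOC calling** ranks the corrected depths d_1 ≥ d_2 ≥ … (ties broken
lexicographically; top `n_max` = 12 observed variants, no zero padding)
and computes the rate of change ROC_i = d_i/d_{i+1} for each break,
normalised to percentages DOC_i = 100·ROC_i/ΣROC.  The DOC maximum
locates the allele/artefact inflection and its rank is A_i.  A secondary
`cumulative_roc` mode (ratios of successive cumulative depths, DOC as
normalised successive differences) is available behind a flag for
fidelity experiments; no equivalence between the modes is asserted, and
the cumulative mode has a structural early-rank bias on flat plateaus.

## The good/poor call

The original analysis had three people inspect cumulative-depth curves
and discard amplicons without a clear inflection.  The package replaces
that judgement with an explicit rule set (`call_genotype`):

* **good via inflection**: max DOC ≥ τ (default 50%) with a unique
  argmax, *and* the variants below the break sit at artefact-like
  relative depth — below `min_allele_fraction` (default 5%) of the
  amplicon.  The second condition is essential: with only 2–3 breaks a
  near-flat profile puts ~50% on some break by construction, and
  without it a pure allele plateau would be "confidently" cut in half.
  Empirically true alleles occupy ≥ ~3–7% relative depth and artefacts
  ≤ ~1–3%, so 5% separates the bands.
* **good via clean plateau**: the variant list is exhausted below
  `n_max`, every adjacent ratio is ≤ `plateau_ratio` (default 2), the
  shallowest variant holds ≥ `min_allele_fraction` of the amplicon, and
  total depth ≥ `min_plateau_depth` (default 50 reads).  This is the
  artefact-free limit: when correction and the singleton filter have
  removed the entire tail, the absence of anything below the plateau is
  itself the boundary, and all observed variants are alleles.  The
  depth floor keeps genuinely shallow flat profiles (e.g. four variants
  of depth 5) poor.
* everything else — tied maxima, weak inflections, fewer than three
  variants (with ≤ 2 variants the lone DOC value is 100 by
  construction and carries no evidence) — is **poor** and excluded.

τ, the plateau parameters and `n_max` are exposed in configuration; the
defaults were fixed from the structure of the statistic (flat-profile
baselines, the empirical allele/artefact relative-depth bands) before
the validation suites were run, and are deliberately conservative:
borderline amplicons fall out as poor rather than being miscalled.

## The simulator

`simdata` emulates the statistical structure the analysis assumes, not
sequencer physics (no flowgrams, no cluster chemistry, no per-base
quality recalibration).

* **Allele pool**: one random ancestor per length class (239–242 bp
  classical, 236 bp non-classical); each allele is the ancestor with
  `divergence` (default 8) random substitutions, rejected until all
  same-length classical pairs differ by ≥ `min_pairwise_substitutions`
  (default 3).  The floor guarantees the 1–2 nt correction rules cannot
  collapse two simulated true alleles; real alleles 1–2 nt apart would
  be at risk exactly as the MiSeq "always > 50%" clause anticipates,
  and that regime is not calibrated here.
* **Genotypes**: either unrelated individuals with allele counts uniform
  in a range (default 3–9), or families in which each parent carries two
  haplotypes (sets of classical alleles) and each chick inherits one
  haplotype from each parent uniformly — giving Mendelian closure by
  construction.
* **Depth**: negative-binomial per amplicon.  Means are the two
  platforms' characteristic regimes (63 and 2818 reads/amplicon); the
  dispersion parameters (19 and 27) were back-computed from typical
  standard errors of those means over runs of ~70-90 amplicons.
* **Amplification efficiency**: per-allele lognormal weights
  (σ = `efficiency_sd`, default 0.35) shared by classical and
  co-amplified non-classical alleles.  With ~4 non-classical loci this
  puts roughly 40–50% of reads in non-classical variants (removed by
  the length filter) and spreads true classical alleles over ~3–20% of
  the amplicon, matching the observed bands.
* **Artefacts**, per read, with defaults per platform (454 / MiSeq):
  substitution artefacts 0.03 / 0.05 — 1–2 substitutions off a parent
  drawn by weight; on MiSeq they are drawn from a run-global set of 10
  repeatable (position, base) sites so identical artefact variants
  accumulate depth and recur across amplicons, while 454 substitutions
  hit random positions; homopolymer ±1 indels in runs ≥ 3 at 0.08 /
  0.005 (the 454-characteristic error); chimeras 0.01 (5′ of one allele
  joined to the 3′ of another at a uniform breakpoint); cross-sample
  contamination 0.01 / 0.005 (a read copied from a pool allele outside
  the genotype); unique singleton errors 0.06 / 0.05.  These rates are
  not reported by any source; they were chosen once so that the
  realized *relative* depths of surviving artefact variants fall in the
  observed artefact band and sit below the allele band, and so that
  roughly half of raw variant diversity is singleton noise.
* **Emission**: each read becomes
  `fwd_tag + fwd_primer + insert + revcomp(rev_primer) + revcomp(rev_tag)`
  (degenerate primer positions concretised per read).  454-style runs
  write one FASTA with random per-read orientation; MiSeq-style runs
  write paired 250 bp R1/R2 FASTQ — constructs are ≤ 294 bp, so mates
  always overlap by ≥ 206 bp.  Qualities are constant Q37 with a 2%
  fraction of Q20 pairs to exercise the Q30 filter (454 reads carry no
  qualities).  Everything is deterministic given the run seed;
  identical configurations emit byte-identical files.

What the simulator does *not* model: PCR-cycle-dependent artefact
amplification (an early-cycle error can reach allele-like depth in real
data; simulated artefact depths are thin-tailed), quality-score
heterogeneity along reads, tag jumps, and true alleles closer than the
pairwise floor.  Passing tests therefore show the pipeline implements
its rules correctly and that those rules suffice under the assumed
error structure — not that the rules would rescue pathological real
runs.

## Preprocessing conventions

* Pair merging is ungapped: the best suffix/prefix overlap ≥ 100 bp by
  mismatch fraction (≤ 0.25), disagreements resolved to the
  higher-quality base, agreements keeping the higher quality.
  Indel-containing overlaps are rejected rather than aligned.
* The Q30 rule is mean read quality ≥ 30; a mean of exactly 30 passes
  ("below Q30" is removed).
* Tag matching is exact; primer matching honours IUPAC degeneracy with
  a configurable mismatch budget, default 0.  A read must present
  complete tags and primers in either orientation to be assigned.
* Singletons are depth-1 variants *within an amplicon* (dataset-wide
  removal would delete legitimate rare alleles).
* The 239–242 bp retention window applies to the tabulated trimmed
  insert; the simulator generates alleles on the same convention, so
  the filter is self-consistent.

## Statistics

`fisher_exact_2x2` uses the standard two-sided convention (sum of
margin-fixed tables with point probability ≤ observed), delegating to
scipy; the test suite verifies it against exhaustive integer
hypergeometric enumeration for every table with N ≤ 40.  Degenerate
margins return p = 1 with a warning.  `mann_whitney` computes U from
midranks, with tie-corrected variance, 0.5 continuity correction and a
normal two-sided p; it is checked against scipy's asymptotic method and
against full permutation enumeration for group sizes 3–8 (with heavy
ties at n ≈ 3 any normal approximation is crude, so the permutation
comparison uses continuous samples).  A genotype "match" in all
concordance metrics is set equality of called allele sequences, not
equality of A_i alone.

## Known limitations

* At the shallow depth regime (~63 reads/amplicon) the automated call is
  stricter than human curve inspection: many amplicons a person would
  accept fall below τ once the DOC is normalised over all breaks, so
  the shallow platform's absolute success rate is conservative.  The
  diversity-dependent *contrast* between regimes — equal behaviour
  where both succeed, failure concentrated at 6+ alleles on the shallow
  platform — is reproduced; the shallow platform's absolute success
  percentage is not a calibrated quantity.
* The DOC method inherently excludes true alleles with very poor
  amplification efficiency; at high depth the default bands make this
  rare, but it is visible in scaled-down runs.
* Correction order sensitivity is bounded but not zero; reversing the
  amplicon processing order changes results on < 1% of simulated
  amplicons (tested), because cross-amplicon evidence comes from the
  uncorrected snapshot.
* Chimeras are only removed insofar as the singleton filter and the
  1–2 nt rules catch them; there is no dedicated chimera detector.
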