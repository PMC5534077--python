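# mhcdoc

Amplicon genotyping of highly duplicated MHC class I genes, with a
platform-aware error-correction stage, degree-of-change (DOC) allele
calling, and tooling to compare 454-style and MiSeq-style sequencing runs
of the same individuals.

## The problem

The classical MHC class I loci of passerine birds (the house sparrow is
the motivating system) are so duplicated that a single PCR co-amplifies
3–9 similar alleles per individual, plus 236 bp non-classical loci,
plus a cloud of PCR and sequencing artefacts.  Genotyping an amplicon
means deciding, from relative read depths and sequence similarity, which
variants are real gene copies and which are 1–2 nt substitution errors,
homopolymer indels, chimeras or cross-sample contamination.  The package
implements the full analysis chain used for this problem:

1. **Preprocessing** — merge 250 bp read pairs on ≥100 bp overlaps, drop
   reads with mean Phred < 30, demultiplex by dual 6 bp tags, trim tags
   and primers (IUPAC degeneracy honoured), tally exact sequences per
   amplicon, remove singletons, and keep only 239–242 bp variants
   (classical loci; the co-amplified 236 bp non-classical variants are
   removed).
2. **Error correction** — among each amplicon's top-50 variants, a
   variant 1–2 substitutions from a deeper "parent" at under 50% of its
   depth is a candidate artefact.  For 454-style data it is deleted when
   it occurs in only one amplicon of the run; for MiSeq-style data
   (whose substitution errors recur at the same sites across amplicons)
   it is kept only if it exceeds 50% of the parent *in every amplicon
   where the two co-occur*, or appears somewhere without the parent.
   Homopolymer-indel variants fold into their parents the same way.
   Deleted variants' reads are added to the parent, so depth is conserved.
3. **DOC genotyping** — rank the corrected depths, compute the rate of
   change ROC_i = d_i/d_{i+1} between successive ranked variants (top 12),
   and express each as a percentage of the total, DOC_i = 100·ROC_i/ΣROC.
   A dominant DOC value locates the inflection between true alleles and
   residual artefacts; its rank is the inferred allele count A_i.
   Amplicons without a clear, consistent inflection are "poor" and
   excluded.
4. **Validation and comparison** — success rates by allele count,
   Fisher's exact test on good/poor counts, Mann–Whitney U on read
   depths, genotype concordance within replicate pairs and across
   platforms, and pedigree consistency (every chick allele must appear
   in a parent).
5. **Naming** — called alleles are matched against a local reference
   FASTA: full-length identity keeps the published name, identity over
   the overlap with different length appends "a", anything else is novel
   (`Pado-UA*NNN`-style numbering).

Raw reads from dual-platform MHC studies are rarely redistributable, so
the package ships a first-class simulator (`mhcdoc.simdata`) that
generates tagged amplicon runs with known ground truth: a shared allele pool, Mendelian
families, lognormal per-allele amplification efficiency, platform depth
regimes (~63 vs ~2818 reads/amplicon) and platform-specific artefact
spectra, with every read labelled by its true source.

## Worked example

```bash
python examples/01_simulate_run.py     # emit a 6-sample MiSeq-like run
python examples/02_preprocess_reads.py # FASTQ -> variant x depth table
python examples/03_correct_and_genotype.py
```

The last step prints, for this run:

```
127 artefact variants folded into parents

S01: good  A_i=6  max DOC=95.0%  top depths [458, 352, 312, 271, 257, 251, 2, 2]
S02: good  A_i=6  max DOC=81.5%  top depths [324, 304, 218, 207, 172, 138, 3, 2]
S03: good  A_i=5  max DOC=90.7%  top depths [448, 425, 288, 249, 215, 3, 2, 2]
...
```

Each line is one amplicon: after correction the true alleles (hundreds
of reads each) are separated from residual artefacts (2–4 reads) by a
sharp depth cliff; the DOC maximum sits on that cliff and A_i counts the
alleles above it — here recovering every simulated genotype exactly.
`examples/04_platform_comparison.py` runs the same individuals under
both depth regimes and shows the characteristic platform pattern: the
shallow 454-like run fails on high-diversity amplicons while the two
platforms agree wherever both succeed.  A thin CLI mirrors the stages
(`mhcdoc simulate|preprocess|correct|genotype|compare|run`).

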