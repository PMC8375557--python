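# Methods

## The marker-discovery model

The pipeline looks for two complementary signatures of genetic sex in
reduced-representation (2b-RAD) data from a phenotypically sexed panel:

* **Sex-limited tags.** A restriction tag that lies on the W (or Y)
  chromosome is sequenced only in the heterogametic sex. With a
  presence threshold of ≥ 3 reads per locus per individual, the strict
  criterion — present in *every* individual of one sex and in *none*
  of the other — is the detector; each tag also carries a two-sided
  Fisher exact p-value from its presence 2×2 table so that relaxed
  criteria remain rankable. At 10 females vs 10 males the perfect split
  attains the distribution's minimum, p = 2/184756 ≈ 1.08 × 10⁻⁵ (two
  tables of the C(20,10) equally-extreme arrangements).
* **Gametolog SNPs.** Where Z and W copies of a shared locus have
  diverged, the heterogametic sex is constitutively heterozygous and
  the homogametic sex homozygous. Each biallelic tag SNP is tested with
  a two-sided Fisher exact test on the (het vs hom) × (female vs male)
  table; an allele-count model is available as an alternative.
  Candidates are taken by rank (top-N), reflecting screening practice;
  Bonferroni and Benjamini–Hochberg columns are reported alongside the
  raw p so a corrected-threshold selection is possible.

The heterogamety call is directional: ZW requires female-specific tags
to strictly outnumber male-specific tags *and* female-heterogametic
patterns to be at least as frequent as male-heterogametic ones among
the top SNPs; XY is the mirror; anything else is undetermined.

The Fisher test is computed by exact rational (Fraction) enumeration of
the hypergeometric support, summing probabilities ≤ the observed
table's. This removes floating-point ambiguity from the ≤ comparison,
which matters because candidate selection is a ranking: ties must break
identically on every platform. `scipy.stats.fisher_exact` is used in
the test suite as an independent cross-check, never as the
implementation.

### Pattern classification

A site is `female_heterogametic` when every non-absent female call is
heterozygous and every non-absent male is homozygous for one shared
allele; `male_heterogametic` is the mirror; `fixed_difference` when the
sexes are homozygous for different alleles; anything else (including
mixed within-sex configurations) is `uninformative`. Absent calls are
dropped per marker, not imputed. Applied to the shipped top-10 SNP
table this yields 7 female-heterogametic, 2 male-heterogametic and 1
fixed-difference pattern — note the source study's text describes all
ten as female-heterozygous, but its printed genotypes for rows 6–8 are
not; the classifier follows the printed genotypes and we document the
discrepancy rather than resolve it.

## Tag geometry

BsaXI is modelled purely by its degenerate recognition motif
`ACNNNNNCTCC` and fixed core offsets: 9 nt retained 5′ of the motif and
7 nt 3′ of it (27-nt core), plus 3 terminal nt on each side in the raw
33-nt read. The 9 + 11 + 7 structure is an inference from the 13
published candidate tags — all carry the motif at offset 9 — not a
printed specification; the physical cut-site offsets are not modelled
beyond the 3-nt read pads. Custom enzymes can be described by a
`RecognitionSpec`. Coordinates are 0-based half-open (BED) throughout;
tag identity is strand-independent via canonicalization
(min of sequence and reverse complement). Overlapping motif matches are
all reported; matching is set-wise on IUPAC codes with subject-side `N`
never matching.

## Read QC

Filters run in a fixed order — wrong length → N fraction strictly
above 8% → mean Phred below 20 → no motif on either strand — and each
read lands in exactly one bucket (pass or a single fail reason), which
the QC report asserts as an accounting identity. "Poor quality" has no
published definition in this protocol; mean Phred ≥ 20 is our
documented default and a parameter. Reads whose motif matches on the
minus strand are rescued by reverse complementation rather than
discarded, maximizing data use. A motif placed such that the 27-nt core
window does not fit fails separately as `wrong_structure`.

## Catalog and genotyping

Cores are clustered by a deterministic greedy rule: unique sequences
sorted by descending total abundance (lexicographic tie-break) join the
first existing locus whose consensus is within 2 substitutions — in
either orientation, because a single substitution can flip which strand
of a tag is lexicographically minimal — else found a new locus. The
result is permutation-invariant to input order and conserves read
depth. Genotyping is a threshold caller, not a likelihood model: absent
below 3 reads (the published minimum-depth rule), heterozygous when the
second allele has ≥ 2 reads *and* > 10% of locus depth, else
homozygous. At 2b-RAD depths (~30–37×) this is deterministic and, on
simulations, exact: 100% genotype accuracy without sequencing error and
≥ 99% (empirically 100% at the default scale) at 1% per-base error.
Loci with more than two genotype-supported alleles are flagged
multi-allelic and excluded from SNP calling; error-only alleles (never
supported by a genotype call) do not define SNPs. SNP positions are
0-based internally and 1-based in emitted tables, following the
published table convention.

## K-mer survey

Canonical 17-mer counting (the `-C`-style behaviour) over reads;
k-mers containing N are dropped. The estimator is deliberately simple
rather than a GenomeScope-style mixture fit:

* error cutoff = first local minimum of the spectrum (0 when the
  spectrum does not descend from multiplicity 1);
* homozygous peak = argmax of multiplicity × count above the cutoff
  after a window-3 moving average, refined to the raw argmax within the
  smoothing window so single-bin spikes resolve exactly;
* genome size = Σ_{m>cutoff} m·count(m) / peak depth;
* heterozygosity: distinct k-mers below ¾ of the homozygous depth form
  the heterozygous peak (het k-mers occur on one haplotype at half
  depth); with h = (het peak / 2) / (het peak / 2 + homozygous bulk)
  the fraction of heterozygous k-mer loci, the per-base rate is
  1 − (1 − h)^(1/k).

This assumes a unimodal coverage peak, low repeat content, and
genome-wide (not RAD) reads. On 30× error-free reads of a 100 kb
simulated genome it recovers size within a few percent, and recovers a
planted 1.0% heterozygosity within the [0.5%, 2.0%] band. It is not
expected to reproduce survey estimates for real, repeat-rich genomes.

## The synthetic-data generator

The generator emulates the study design: 10 females + 10 males (both
counts configurable), a single autosome/Z stand-in contig (100 kb
default) with 200 planted tag loci, a separate sex-limited contig with
3 tags, 10 gametolog SNPs and 50 autosomal SNPs hosted in distinct
tags, per-tag-copy Poisson coverage (default 37×, matching the
published mean depth; the end-to-end analyses use 30×), iid
substitution errors (default 0.1%, typical of Illumina after QC; the
stress analyses use 1%), reads of 3 + 27 + 3 = 33 nt emitted from a
random strand with constant Q40 qualities. SNPs are planted only at
degenerate motif positions so both alleles remain valid restriction
tags. Backgrounds are scrubbed of accidental motif occurrences on both
strands, so the planted coordinates are exactly the digestible sites —
a property the digestion tests exploit. One sex-limited contig (rather
than scattered regions) keeps truth bookkeeping simple.

Deliberately not modelled: realistic base-quality profiles (a
low-quality/no-motif read injector exercises the QC path instead), PCR
duplicates, indels (2b-RAD tags are too short for meaningful indel
handling), paired-end structure (reads are emitted pre-merged), linked
repeat structure, and allele-specific amplification bias. Passing tests
therefore demonstrate correctness of the inference machinery under the
stated noise model, not robustness to every artefact of real libraries.
The per-locus depth distribution of real 2b-RAD libraries is unknown;
Poisson is an assumption.

Genome-survey reads are generated by a separate uniform-coverage
shotgun model (default 100-nt reads) over one or two haplotypes,
because RAD reads cannot support a genome-size estimate; diploid
haplotypes are derived by iid mutation at a chosen heterozygosity.

## Problem sizes and determinism

Default analysis scale is desk-scale by design: a 100 kb genome with
~200 tag loci and 20 individuals (~240 k reads) screens end-to-end in
seconds; the null-model check runs 50 reduced-scale replicates (12 kb,
25 loci, 10× coverage) since the false-positive behaviour of the strict
presence criterion depends on the panel size, not the locus count; the
concordance analog uses the published validation panel size (38 F +
57 M) at reduced genome scale. All randomness flows from a single seed
through `numpy.random.SeedSequence` spawning, so every artefact —
FASTA, FASTQ, truth tables, results — is bit-reproducible per seed.

## Known limitations

* The alignment-rate and absolute locus/SNP counts of the real study
  depend on its raw data (a public SRA accession) and reference
  practice (mapping against per-sex reference individuals); this
  pipeline genotypes catalog-wise and does not reproduce those numbers.
* The association test behind the published SNP ranking is unstated in
  the protocol; two-sided Fisher exact is our choice, exact at n = 20.
* The depth-threshold genotyper has no error model; at depths ≪ 20× a
  likelihood caller would be preferable.
* Scaffold statistics are computed on given or simulated scaffolds;
  assembly itself is out of scope, as are homology annotation, primer
  thermodynamics and wet-lab validation steps.
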