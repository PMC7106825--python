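# Methods

## The measurement

The package measures the footprint of 5-methylcytosine deamination in
population variant catalogues. The unit of observation is the CpG
dinucleotide, keyed by the plus-strand C coordinate: the dinucleotide is
palindromic, so a C>T call at the C and a G>A call at the following G are
two descriptions of one mutable unit and are collapsed onto one site
before any counting. All per-stratum statistics are ratios over these
units:

* **mutation rate** — mutated units / all units, with Wilson-score 95%
  intervals (a normal-approximation mode exists behind `ci_method`);
* **Af-weighted rate** — sum of allele frequencies of mutated units / all
  units, a frequency-weighted analogue bounded above by the plain rate;
* **mean methylation** — mean per-unit bisulfite beta.

Allele frequencies come from the `AF` INFO field or `AC/AN`; a site seen
in several catalogues keeps the maximum frequency (a per-source mode keeps
per-catalogue maxima). The "Af = 0" bin of the six-bin frequency partition
({0}, (0,0.06), [0.06,0.12), [0.12,0.18), [0.18,0.24), [0.24,1]) is the
unmutated complement, since any reported variant has AC >= 1.

## CpG-island calling and classification

Islands satisfy the Gardiner-Garden criteria: GC >= 0.5, length > 200 bp,
observed/expected CpG ratio obs·L/(#C·#G) > 0.6. The caller slides a
200-bp window by 1 bp, merges overlapping/adjacent qualifying windows, and
keeps a merged segment only if the segment itself passes all three
criteria (`recheck=False` keeps raw unions for comparison). Segmentation
by window-merging over-extends borders by up to ~window/2 on either side
of a sharp composition change; this localization uncertainty is inherent
to the criteria and is why downstream truth-recovery tests compare band
aggregates rather than exact border positions. Ingested island BEDs are
sorted and overlap-merged but exempt from the composition invariants.

Classification is per island: a gene whose strand-aware TSS ± 100 bp
(closed interval) intersects the island contributes a TSS-coding or
TSS-noncoding label; otherwise a transcript-body intersection contributes
an intragenic label. A TSS hit outranks a body hit *from the same gene*
(an island at a gene's own promoter is not also intragenic); distinct
labels from different genes make the island miscellaneous (MISC); no gene
at all makes it intergenic. RefSeq-style transcript records sharing a gene
name are collapsed to their union span first, so isoforms sharing a
promoter do not inflate MISC. MISC islands are reported separately and
excluded from the five-class tables.

Signed distances to the nearest island border follow the convention
`d = pos - start` (negative) left of the island and `d = pos - end`
(non-negative) right of it; equidistant ties go to the lower-coordinate
island; sites inside islands carry an in-island marker instead of a
distance. Under chromosome mirroring this convention transforms as
`d' = -d - 2` (the dinucleotide anchor shifts by two under reverse
complement), which is the form the invariant test asserts. Shores are the
up-to-2-kb flanks, clipped at chromosome ends and neighbouring islands.

## Profiles and smoothing

The distance profile is the per-unit rate (or mean beta) at each exact
signed distance within ±5 kb, pooled per CpG (not per island); distances
with no sites are missing, not zero. Smoothing averages per-position
values over non-overlapping blocks counted outward from the border — 20
positions for TSS-coding, intragenic-coding and intergenic classes, 100
for the sparser noncoding classes — labelling each block by its midpoint;
a trailing partial block averages what is available. No additional
normalization constant is applied to the profile: "normalized incidence"
is the raw per-site rate at each distance. The paired shore comparison
between two classes runs a paired t over matched block means within
±2 kb, dropping incomplete pairs, with a zero-variance guard (identical
profiles give t = 0, p = 1).

## Coding consequences

Every CDS base that is the C or G of a plus-strand CpG is *primed*: its
deamination substitution (C>T or G>A) is projected into transcript
orientation, the codon mutated across exon junctions, and both codons
translated under the standard genetic code. Stop-preserving changes are
silent; stop-gains nonsense; stop-losses are pooled with missense but
flagged. Sites covered by several transcripts keep each transcript's
consequence in the long table and resolve to the most severe (nonsense >
missense > silent) in headline tables. The analysis restricts to
hyper-methylated sites (per-site beta >= 0.67, switchable to parent-island
mean), where deamination is actually active, and crosses them with an
exome-scale catalogue: a primed site is observed only on an exact
position-and-allele match. Observed fractions per consequence and
allele-count spectra (singleton, AC=2, 3–5, >5) quantify negative
selection.

## Signature decomposition

Rare variants (Af <= 0.01, reference allele taken as ancestral — rare
variants are recent, so the reference is almost surely ancestral) are
tallied into the 96 pyrimidine-collapsed trinucleotide channels. The
normalized spectrum is fit by nonnegativity-constrained least squares
against a signature matrix; weights are renormalized to sum to one;
signatures below the 1% threshold are pruned and the fit repeated to a
fixed point (at most K rounds; the pruned residual can only be at least
the full-fit residual, and both are reported). Unconstrained regression is
available behind a flag for comparison but can return meaningless negative
exposures. The packaged `synthetic_signatures()` matrix is a deterministic
synthetic stand-in in the COSMIC v2 layout (30 columns; a
deamination-like "Signature 1" peaked on N[C>T]G, a flat "Signature 5",
and reproducible sparse random columns); any 96×K TSV with columns summing
to one is accepted.

## The synthetic generator

`synthetic.generate(config, out_dir)` emits a complete bundle (FASTA,
genePred, island BED, bedGraph methylation, two VCFs, truth tables) that
is byte-identical for identical `(config, seed)`. What it emulates, and
the defaults:

* **Sequence** — 2 chromosomes × 500 kb. Background: i.i.d. nucleotides at
  GC 0.38 with 65% of arising CpGs broken, so background windows
  essentially never satisfy all three island criteria simultaneously while
  non-island CpGs remain plentiful (~1 per 90 bp). Islands: i.i.d. at GC
  0.70 (obs/exp ≈ 1), lengths 400–1400 bp by class, planted in ~31-kb
  slots so ±5-kb profiles never overlap a neighbour.
* **Annotation** — gene models realize every island class on both strands:
  TSS genes (three exons, random CDS offsets, hence junction-spanning
  codons), island-spanning intragenic genes, a MISC construction (coding
  TSS in the island plus a noncoding gene body across it), and plain
  coding genes for non-island CDS CpGs.
* **Mutation probabilities** — per-site Bernoulli draws: island classes
  0.036 (TSS-coding), 0.041 (TSS-noncoding), 0.062 (intergenic), 0.060
  (intragenic-noncoding), 0.050 (MISC); intragenic-coding islands split
  into short hyper-methylated (0.25) and long hypo-methylated (0.06)
  subgroups whose site-weighted mean is ~0.11; shores 0.03–0.10 ordered by
  class; background 0.276; non-CpG C:G>T:A control 0.02. These defaults
  mirror the per-class ordering and magnitudes the pipeline is meant to
  resolve; they are demo parameters, not claims about any genome.
* **Allele frequencies** — a two-component mix (70% Beta(0.5, 25) mass
  near zero, 30% uniform tail) rounded onto AC/AN with AN = 8654, so all
  six frequency bins are populated and AF = AC/AN holds exactly. Each
  mutated site is written as its C>T record, its G>A record, or (10%)
  both, exercising the palindromic join and deduplication.
* **Methylation** — class-specific island betas (0.02–0.15; hyper/hypo
  intragenic-coding 0.85/0.10), a linear shore ramp from 0.30 at the
  border to the 0.80 background over 2 kb (the simplest shape consistent
  with a monotone rise-and-plateau; no functional form is prescribed by
  the phenomenon), Gaussian noise (sd 0.05), clipped to [0, 1].
* **Exome catalogue** — consequence-primed hyper-methylated CDS sites are
  observed with probability 0.8/0.7/0.5 (silent/missense/nonsense) and
  drawn allele counts from shifted geometrics with singleton mass
  0.28/0.42/0.55, emulating negative selection; AN = 121412.

What the generator does **not** emulate: linkage and coalescent structure
(sites are independent Bernoulli draws), sequencing error, coverage
heterogeneity, repeat structure, isoform diversity, CpG depletion history,
or realistic chromosome-scale composition. Passing tests therefore
demonstrate that the estimators recover known per-site generative
parameters through the full file-format round trip — not that real-genome
estimates are unbiased under ascertainment or demographic effects.

## Numerical and design choices

* Coordinates are 0-based half-open everywhere; VCF converts on ingestion.
* Soft-masked lowercase sequence is uppercased and used; N never matches.
* Y-chromosome sites are enumerated but excluded from allele-frequency
  analyses (`exclude_chroms_af`); X is included.
* Events with populated non-PASS FILTER are dropped; an absent/'.' FILTER
  is accepted (consortium files differ in FILTER discipline).
* Missing allele frequencies drop an event from rarity filtering and from
  Af-weighted numerators, always with a counter.
* Hyper/hypo thresholds: island Group A is strictly > 0.67, Group B
  strictly < 0.33; the coding-analysis hyper filter is >= 0.67. Grouping
  requires >= 5 covered CpGs per island (coverage >= 1 read).
* Dunn's post-hoc uses pooled-rank z with tie correction and Bonferroni;
  all p-values two-tailed at alpha 0.05; no correction is applied across
  the battery's separate chi-squared comparisons.
* Problem sizes: the demo bundle is 2 × 500 kb with ~15k CpG units and
  ~14k variant records; island calling, the full pipeline and the
  acceptance script each complete in seconds on one CPU, and the whole
  test suite in well under a minute. Signature-recovery checks use 10^6
  multinomial events over 3 seeds.

## Known limitations

* The caller implements the sliding-window Gardiner-Garden criteria, not
  the UCSC hidden-Markov-style island track; border placement differs by
  up to ~100–150 bp around sharp composition changes.
* Only SNVs are handled; indels, phasing and ancestral-state inference
  from outgroups are out of scope.
* The consequence annotator covers CDS point changes only (no splice,
  UTR or frameshift classes), standard genetic code, no selenocysteine.
* The shipped signature matrix is synthetic; quantitative weights against
  real catalogues require supplying a curated reference matrix.
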