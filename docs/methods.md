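# Methods

## Model and procedure

`editcall` treats A-to-I editing detection as an outlier test against a
dataset's own error process. For a site with quality-filtered reference
count n_ref and alternate count n_alt, and a dataset-wide background of
N_ref reference-matching and N_sub mismatching bases of the same
substitution type (A→G in genome orientation for plus-strand genes, T→C for
minus-strand ones), the test statistic is the two-sided Fisher exact
p-value of the 2×2 table [[n_ref, n_alt], [N_ref − n_ref, N_sub − n_alt]].
Subtracting the site's own counts from the background avoids testing a site
against itself; for realistic datasets the correction is negligible, for
tiny ones it keeps the two rows independent.

The contingency table could alternatively be built against *expected*
counts n·p rounded to integers (p the empirical A→G rate). At typical rates
around 10⁻³ and site coverages of tens of reads the expected count rounds
to zero and the table degenerates, so the count-versus-count form is the
default; the rounded-expectation form is available as
`CallerConfig(background_mode="expected")`.

The exact test is computed in log space: hypergeometric log-pmf over the
full support, two-sided mass summed over outcomes with pmf ≤ observed ×
(1 + 10⁻⁷) (the conventional tie tolerance, matching R and scipy), via
`logsumexp`. This matters because strongly edited sites against large
backgrounds produce p-values far below double precision (10⁻⁴⁰⁰ and
smaller); computing in probability space would underflow to an unrankable
0. `fisher_site_test` floors the returned probability at the smallest
positive double so the documented p ∈ (0, 1] contract holds; ranking and
reporting use the log₁₀ value.

Multiple testing is controlled by Benjamini–Hochberg step-up over the
family of sites that pass the hard filters (SNP mask, genic A→G pattern,
single substitution type, coverage, editing extent, region class). The
editing-extent threshold is applied before the FDR step — it defines the
tested family — mirroring the order in which the hard filters and the
significance cut are described in published practice; both choices are
configurable.

## Filters and parameters

| parameter | default | meaning |
|---|---|---|
| `min_base_quality` | 25 | Phred floor per counted RNA base (30 recommended for high-quality stranded libraries) |
| `min_coverage` | 10 | filtered reads required at a site |
| `min_editing_fraction` | 0.10 | G/(A+G) floor |
| `fdr_threshold` | 0.05 | BH-adjusted significance level |
| `region` | `cds` | region class tested (`cds`, `utr5`, `utr3`, `alt-exon`, `all`) |
| `end_trim` | 0 | bases removed from both read ends before counting |
| prefilter `max_n` | 2 | reads with more Ns are dropped |
| prefilter `min_mean_quality` | 20 | "very low quality" is undefined in the source protocols; a mean-Phred rule is stable across 50–101 bp reads and is configurable |
| DNA `min_quality` / `min_reads` | 30 / 5 | exome homozygosity rule |

The single-substitution filter excludes any site whose filtered pileup
contains a base other than reference and alternate. A consequence worth
knowing: a single stray sequencing error of a third base type at a
genuinely edited site removes that site (probability ≈ coverage × 2ε/3 per
site, ~3% at 50× and Q30 errors). This is faithful to the strategy being
implemented and is visible in the end-to-end recovery numbers below.

## Coordinates, strand and concordance

All external coordinates are 1-based inclusive; half-open arithmetic exists
only inside parsers. Chromosome names match by exact string equality.
Transcript→genome projection maps transcript base k to the k-th exonic base
in genomic order (plus strand) or counting down from the highest exonic
coordinate (minus strand), splitting read blocks at exon boundaries.
Concordance requires *exact* equality of chromosome, strand and block set
between the projected transcriptome placement and the direct genome
placement, both unique; overlap tolerance would readmit exactly the
paralog-induced misplacements the comparison exists to remove. For pairs,
both mates must agree or the pair is dropped.

For unstranded libraries the annotation strand decides which pattern (A→G
vs T→C) a site must show; for stranded libraries the majority read
orientation at the site decides, and the gene annotation is restricted to
that strand. Sites whose reference base is not A (plus) / T (minus) are
never tested. When annotations conflict, CDS beats UTR beats alternative
exon beats intron, and the reporting transcript is the one with the longest
CDS — a declared convention, since published tables report one consequence
per site. "Alternative exon" is defined relative to a designated reference
transcript set; with no reference set given, every transcript is reference.

The substitution spectrum is accumulated over all covered non-SNP sites in
reference-genome orientation (12 types, no strand collapsing). Masking SNPs
from the spectrum as well as from calling is deliberate: true polymorphisms
are not sequencing noise and would inflate the A→G background
unpredictably. Region restriction of the spectrum is available but off by
default.

## Likelihood-ratio support

For exome-confirmed homozygous-reference sites, the per-read mixture
likelihood under editing level f is
L_i(f) = f·P(b_i | alt, ε_i) + (1−f)·P(b_i | ref, ε_i), with
P(b | true x, ε) = 1−ε if b = x, else ε/3, and ε_i = 10^(−q_i/10). The
statistic is log₁₀ of max_f Π L_i(f) over Π L_i(0), maximised on [0, 1] by
bounded 1-D search (tolerance 10⁻⁴) with both endpoints evaluated
explicitly, so LLR = 0 exactly when the data prefer f = 0. Base-10
logarithms put the statistic on the same scale as the reported p-value
exponents; the ε/3 uniform-miscall model is the standard choice in this
family of methods.

## What the simulator emulates — and what it does not

`make_reference` builds a deterministic random genome (default: six
three-exon genes of 450 nt transcripts, 150 nt exons, 100 nt introns,
30 nt UTRs, alternating strands, 200 nt spacers — sized so a full
simulate-detect cycle runs in about a second while every gene still spans
splice junctions on both strands). `plant_sites` places editing at
transcribed-strand adenosines in CDS (levels 10–100%) and het/hom SNPs at
other exonic positions, disjoint from editing. Reads carry the edited base
independently per read with probability equal to the site level, then
uniform miscalls at the error model's rate (default Q30, ε = 10⁻³ —
matching the quality regime of the libraries this strategy targets); DNA
reads carry SNP alleles by haplotype but never editing. The paralog decoy
appends an intronless copy of one transcript with G→A differences, and
`misaligned_copy` reroutes a chosen fraction of that gene's genome
alignments onto it, reproducing the retrocopy failure mode that concordance
filtering must catch.

Reads are emitted already truth-placed, so the tests isolate the statistics
from aligner behaviour; aligner artefacts other than the modelled paralog
misplacement (soft-clipping, indel errors, splice-site misassignment,
quality drift along reads, coverage bias) are *not* simulated. Passing
tests therefore demonstrate the correctness of the counting, filtering and
inference machinery under calibrated noise, not robustness to every
artefact of real libraries.

## Verification

Every statistical component is checked against an independent oracle: the
exact test against exact-rational hypergeometric enumeration (and scipy's
implementation on moderate tables), BH against the naive O(m²) definition
and statsmodels, the LLR maximiser against a 10⁻⁵-step grid search,
projection against a per-base coordinate map, and codon consequences
against direct CDS translation. Derived columns of the two bundled
published tables (editing extents and their means, codon/amino-acid
changes, the 6-of-12 exome homozygosity verdicts) are recomputed from the
printed counts. End-to-end, twenty seeded simulations at 50× coverage, 30%
editing, Q30 errors, with planted SNPs and an expressed, half-misaligned
paralog decoy, recover 98/100 planted sites (the two losses are
single-substitution-filter exclusions as analysed above) with zero calls at
non-planted positions, SNPs or decoy sites.

## Known limitations

- The spectrum and caller assume one fixed base-quality threshold per run;
  mixing thresholds is rejected rather than reconciled.
- No C-to-U calling, no somatic-variant logic, no multi-sample joint
  calling, no rescue of discordant reads by re-alignment, and no prediction
  of new splice sites.
- Repeat (e.g. Alu) overlap is annotation-only, from a user-supplied BED.
- Printed p-values of the published tables are not reproducible from the
  bundled rows alone: they depend on the full-dataset background spectrum,
  which is not part of the printed record. The same holds for the published
  LLR values, which depend on unpublished per-base qualities.
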