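"""Per-site Fisher exact calling of A-to-G editing against the empirical
substitution background, with BH FDR control and hard filters.

Each genic adenosine site (genomic A on plus-strand genes, T on minus-strand
ones) is tested by comparing its quality-filtered reference/alternate base
counts to the dataset-wide counts of the same substitution type from the
substitution spectrum, in a 2x2 exact test.  Sites passing coverage,
editing-extent, single-substitution, SNP-masking and region filters form the
FDR family; survivors are ranked by ascending p-value.

The exact test itself is computed in log space (hypergeometric enumeration
with the usual 1+1e-7 two-sided tie tolerance) so that astronomically small
p-values still rank correctly instead of underflowing to an unordered 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .annotate import GeneIndex, RegionAnnotation, assign_region, codon_effect
from .io import BASE_INDEX
from .spectrum import SiteCounts, SubstitutionSpectrum, spectrum_frequencies

_LN10 = np.log(10.0)
_TINY_P = 5e-324  # smallest positive double: floor after exp() underflow


@dataclass
class CallerConfig:
    """Thresholds and switches for candidate calling.

    Defaults follow the published protocol for brain RNA-seq: base quality
    >= 25, coverage >= 10 reads, editing extent >= 10%, BH FDR <= 0.05,
    coding regions only.
    """

    min_base_quality: int = 25
    min_coverage: int = 10
    min_editing_fraction: float = 0.10
    fdr_threshold: float = 0.05
    region: str = "cds"  # cds | utr5 | utr3 | alt-exon | all
    stranded: bool = False
    end_trim: int = 0
    background_mode: str = "counts"  # counts | expected
    alternative: str = "two-sided"

    def __post_init__(self):
        if not 0 <= self.min_editing_fraction <= 1:
            raise ValueError("min_editing_fraction outside [0, 1]")
        if self.min_coverage <= 0 or self.fdr_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.region not in ("cds", "utr5", "utr3", "alt-exon", "all"):
            raise ValueError(f"unknown region filter {self.region!r}")
        if self.background_mode not in ("counts", "expected"):
            raise ValueError(f"unknown background mode {self.background_mode!r}")


@dataclass
class CandidateSite:
    """One putative editing site with its evidence and statistics."""

    chrom: str
    position: int
    ref_base: str
    substitution_type: str  # AG on plus-strand genes, TC on minus-strand
    counts_filtered: np.ndarray
    counts_raw: np.ndarray
    editing_fraction: float
    p_value: float
    log10_p: float
    fdr: float = 1.0
    gene: str | None = None
    transcript_id: str | None = None
    region: str | None = None
    strand: str | None = None
    codon_effect: object | None = None
    dna_evidence: object | None = None
    llr: object | None = None
    rna_observations: list = field(default_factory=list, repr=False)

    @property
    def coverage(self) -> int:
        return int(self.counts_filtered.sum())


def editing_fraction(sc: SiteCounts, ref_base: str, alt_base: str) -> float:
    """Edited fraction: alt / (ref + alt) among quality-filtered bases."""
    if ref_base == alt_base:
        raise ValueError("reference and alternate base must differ")
    ref_n = sc.count(ref_base)
    alt_n = sc.count(alt_base)
    total = ref_n + alt_n
    return alt_n / total if total else 0.0


def _fisher_log10(site_ref, site_alt, bg_ref, bg_alt, alternative="two-sided") -> float:
    """log10 p of the exact test on [[site_ref, site_alt], [bg_ref, bg_alt]].

    Hypergeometric enumeration over the site's alternate count with fixed
    margins, summed in log space.
    """
    n = site_ref + site_alt  # site row total
    M = n + bg_ref + bg_alt  # grand total
    K = site_alt + bg_alt  # alternate-column total
    kmin = max(0, n - (M - K))
    kmax = min(n, K)
    support = np.arange(kmin, kmax + 1)
    logpmf = hypergeom.logpmf(support, M, K, n)
    obs = logpmf[site_alt - kmin]
    if alternative == "two-sided":
        sel = logpmf <= obs + np.log1p(1e-7)
    elif alternative == "greater":  # enrichment of the alternate base
        sel = support >= site_alt
    elif alternative == "less":
        sel = support <= site_alt
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    log10p = logsumexp(logpmf[sel]) / _LN10
    # the full-support sum is exactly 1; absorb logsumexp rounding at the top
    return float(min(log10p, 0.0)) if log10p < -1e-12 else 0.0


def fisher_site_test(
    site_ref: int,
    site_alt: int,
    bg_ref: int,
    bg_alt: int,
    alternative: str = "two-sided",
) -> float:
    """Exact-test p-value for a site's ref/alt counts against the background.

    All counts must be non-negative and the site row non-empty.  The return
    value is in (0, 1]; p-values beyond double-precision range are floored
    at the smallest positive double (use :func:`fisher_site_test_log10` when
    the magnitude itself matters).
    """
    counts = (site_ref, site_alt, bg_ref, bg_alt)
    if any(c < 0 for c in counts):
        raise ValueError("negative count in contingency table")
    if site_ref + site_alt == 0:
        raise ValueError("empty site row in contingency table")
    log10p = _fisher_log10(site_ref, site_alt, bg_ref, bg_alt, alternative)
    return max(float(10.0 ** log10p), _TINY_P)


def fisher_site_test_log10(site_ref, site_alt, bg_ref, bg_alt, alternative="two-sided") -> float:
    if site_ref + site_alt == 0 or min(site_ref, site_alt, bg_ref, bg_alt) < 0:
        raise ValueError("invalid contingency table")
    return _fisher_log10(site_ref, site_alt, bg_ref, bg_alt, alternative)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_i = min_{j >= i} m * p_(j) / j over the ascending ordering, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    # mathematically adjusted >= raw; enforce against last-ulp rounding
    return np.maximum(adjusted, p)


def _site_background(spectrum, freq, sc, ref, alt, mode):
    """Background (ref, alt) row for a site's 2x2 table."""
    n_ref = sc.count(ref)
    n_alt = sc.count(alt)
    if mode == "counts":
        bg_match, bg_sub = spectrum.background_counts(ref, alt)
        # subtract the tested site's own contribution to avoid self-comparison
        return max(bg_match - n_ref, 0), max(bg_sub - n_alt, 0)
    rate = freq[1][(ref, alt)]
    expected_alt = int(round((n_ref + n_alt) * rate))
    return n_ref + n_alt - expected_alt, expected_alt


_ALT_FOR_STRAND = {"+": ("A", "G"), "-": ("T", "C")}


def call_candidates(
    sites,
    spectrum: SubstitutionSpectrum,
    snp_table,
    gene_models,
    config: CallerConfig,
    genome=None,
    reference_transcripts=None,
    repeat_index=None,
) -> list[CandidateSite]:
    """Run the full per-site filtering and testing cascade.

    A site is tested when it (i) is not a known SNP, (ii) lies in a gene and
    shows the A→G pattern on the transcribed strand, (iii) carries no
    filtered base other than reference and alternate, (iv) reaches the
    coverage floor, (v) reaches the editing-extent floor and (vii) falls in
    the configured region class.  The surviving family is BH-adjusted and
    thresholded at the FDR cutoff (vi), then sorted by ascending p-value
    with (chrom, position) tie-breaks.
    """
    if spectrum.min_quality != config.min_base_quality:
        raise ValueError(
            f"spectrum built at Q{spectrum.min_quality}, caller configured for "
            f"Q{config.min_base_quality}"
        )
    index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)
    freq = spectrum_frequencies(spectrum)
    region_wanted = {
        "cds": {"CDS"}, "utr5": {"UTR5"}, "utr3": {"UTR3"}, "alt-exon": {"alt-exon"},
        "all": {"CDS", "UTR5", "UTR3", "alt-exon", "intron"},
    }[config.region]

    family: list[CandidateSite] = []
    for sc in sites:
        if snp_table is not None and (sc.chrom, sc.position) in snp_table:
            continue
        if config.stranded:
            if sc.n_plus == sc.n_minus == 0:
                continue
            strand = "+" if sc.n_plus >= sc.n_minus else "-"
            ann = assign_region(
                sc.chrom, sc.position, index, reference_transcripts, repeat_index,
                strand=strand,
            )
        else:
            ann = assign_region(
                sc.chrom, sc.position, index, reference_transcripts, repeat_index
            )
            strand = ann.strand
        if ann.label == "intergenic" or strand is None:
            continue
        ref, alt = _ALT_FOR_STRAND[strand]
        if sc.ref_base != ref:
            continue
        ref_i, alt_i = BASE_INDEX[ref], BASE_INDEX[alt]
        others = [i for i in range(4) if i not in (ref_i, alt_i)]
        if sc.counts_filtered[others].sum() > 0:
            continue  # multiple substitution types at the site
        if sc.coverage < config.min_coverage:
            continue
        fraction = editing_fraction(sc, ref, alt)
        if fraction < config.min_editing_fraction:
            continue
        if ann.label not in region_wanted:
            continue
        bg_ref, bg_alt = _site_background(
            spectrum, freq, sc, ref, alt, config.background_mode
        )
        log10p = _fisher_log10(
            sc.count(ref), sc.count(alt), bg_ref, bg_alt, config.alternative
        )
        effect = None
        if ann.label == "CDS" and genome is not None:
            model = next(
                m for m in index.overlapping(sc.chrom, sc.position)
                if m.transcript_id == ann.transcript_id
            )
            effect = codon_effect(sc.chrom, sc.position, model, genome, "G")
        family.append(
            CandidateSite(
                chrom=sc.chrom,
                position=sc.position,
                ref_base=ref,
                substitution_type=ref + alt,
                counts_filtered=sc.counts_filtered.copy(),
                counts_raw=sc.counts_raw.copy(),
                editing_fraction=fraction,
                p_value=max(float(10.0 ** log10p), _TINY_P),
                log10_p=log10p,
                gene=ann.gene,
                transcript_id=ann.transcript_id,
                region=ann.label,
                strand=strand,
                codon_effect=effect,
            )
        )

    if not family:
        return []
    fdrs = bh_adjust([c.p_value for c in family])
    for c, q in zip(family, fdrs):
        c.fdr = float(q)
    kept = [c for c in family if c.fdr <= config.fdr_threshold]
    kept.sort(key=lambda c: (c.log10_p, c.chrom, c.position))
    return kept
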