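"""Exome/DNA validation of RNA editing candidates.

An RNA A-to-G mismatch at a genomically homozygous-reference position cannot
be a SNP, so candidates are checked against DNA alignments: at least 5
independent reads of quality >= 30, all matching the reference, confirm the
site.  For confirmed sites a log-likelihood ratio contrasts a mixture model
(editing at level f) against pure sequencing error (f = 0) over the
individual RNA base observations and their Phred-derived error rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .io import BASES
from .spectrum import BaseObservation, SiteCounts, collect_observations, pileup_site_counts

STATUS_CONFIRMED = "confirmed"
STATUS_VARIANT = "genomic_variant"
STATUS_LOW_COVERAGE = "insufficient_coverage"
STATUS_UNCOVERED = "uncovered"


@dataclass
class DnaEvidence:
    """DNA base counts at a candidate site plus the homozygosity verdict."""

    counts: SiteCounts
    homozygous_reference: bool
    status: str

    @property
    def coverage(self) -> int:
        return self.counts.coverage

    @property
    def counts_filtered(self):
        return self.counts.counts_filtered


@dataclass
class LlrResult:
    """Editing-vs-error likelihood ratio (log10) and the ML editing level."""

    llr: float
    f_hat: float


def dna_site_counts(dna_records, genome, chrom, position, min_quality: int = 30) -> SiteCounts:
    """Quality-filtered DNA base counts at one site, duplicates excluded."""
    obs = collect_observations(
        (r for r in dna_records if not r.duplicate), [(chrom, position)]
    )[(chrom, position)]
    ref = genome[chrom].base(position)
    sc = pileup_site_counts(obs, ref, min_quality=min_quality)
    sc.chrom, sc.position = chrom, position
    return sc


def homozygous_reference(sc: SiteCounts, ref_base: str, min_reads: int = 5) -> DnaEvidence:
    """Apply the homozygosity rule to a site's DNA counts.

    Homozygous reference iff at least ``min_reads`` filtered reads and every
    filtered base equals the reference; any non-reference base marks a
    genomic variant, coverage below the floor (all-reference) is
    insufficient, zero coverage is uncovered.
    """
    cov = sc.coverage
    non_ref = cov - sc.count(ref_base)
    if cov == 0:
        status, hom = STATUS_UNCOVERED, False
    elif non_ref > 0:
        status, hom = STATUS_VARIANT, False
    elif cov < min_reads:
        status, hom = STATUS_LOW_COVERAGE, False
    else:
        status, hom = STATUS_CONFIRMED, True
    return DnaEvidence(sc, hom, status)


def _log_likelihood(f: float, is_alt: np.ndarray, eps: np.ndarray) -> float:
    """Sum of per-read log likelihoods under editing level f.

    A read's base is the alternate with probability f*(1-e) + (1-f)*e/3 and
    the reference with probability f*e/3 + (1-f)*(1-e), e the miscall rate;
    each specific wrong base is called with probability e/3.
    """
    p_alt = f * (1.0 - eps) + (1.0 - f) * eps / 3.0
    p_ref = f * eps / 3.0 + (1.0 - f) * (1.0 - eps)
    return float(np.sum(np.log(np.where(is_alt, p_alt, p_ref))))


def llr_editing(rna_observations, ref_base: str, alt_base: str) -> LlrResult:
    """Maximum-likelihood editing level and log10 likelihood ratio vs f = 0.

    Observations carrying neither the reference nor the alternate base are
    ignored (they were already excluded upstream by the caller's
    single-substitution filter).  The level is maximised over [0, 1] by
    bounded 1-D search to 1e-4 tolerance with the closed endpoints checked
    explicitly, so llr = 0 exactly when the data prefer f = 0.
    """
    obs = [o for o in rna_observations if o.base in (ref_base, alt_base)]
    if not obs:
        raise ValueError("no usable observations for likelihood ratio")
    is_alt = np.array([o.base == alt_base for o in obs])
    eps = np.array([10.0 ** (-o.phred / 10.0) for o in obs])

    ll0 = _log_likelihood(0.0, is_alt, eps)
    res = minimize_scalar(
        lambda f: -_log_likelihood(f, is_alt, eps),
        bounds=(0.0, 1.0),
        method="bounded",
        options={"xatol": 1e-4},
    )
    candidates = [(0.0, ll0), (float(res.x), -float(res.fun))]
    candidates.append((1.0, _log_likelihood(1.0, is_alt, eps)))
    f_hat, ll_hat = max(candidates, key=lambda t: t[1])
    llr = (ll_hat - ll0) / np.log(10.0)
    if llr <= 0.0 or f_hat <= 0.0:
        return LlrResult(0.0, 0.0)
    return LlrResult(float(llr), f_hat)


def validate_candidates(
    candidates,
    dna_records,
    genome,
    rna_records=None,
    min_quality: int = 30,
    min_reads: int = 5,
):
    """Annotate candidates in place with DNA evidence and, where the genome
    is homozygous reference, the editing LLR from RNA observations.

    RNA observations are gathered from ``rna_records`` at the candidate
    positions unless the candidates already carry them; ordering of the
    candidate list is preserved.
    """
    targets = [(c.chrom, c.position) for c in candidates]
    rna_obs = None
    if rna_records is not None:
        rna_obs = collect_observations(rna_records, targets)
    for c in candidates:
        sc = dna_site_counts(dna_records, genome, c.chrom, c.position, min_quality)
        ref = genome[c.chrom].base(c.position)
        c.dna_evidence = homozygous_reference(sc, ref, min_reads)
        c.llr = None
        if c.dna_evidence.homozygous_reference:
            obs = c.rna_observations or (
                rna_obs[(c.chrom, c.position)] if rna_obs is not None else []
            )
            alt = c.substitution_type[1]
            usable = [o for o in obs if o.base in (c.ref_base, alt)]
            if usable:
                c.llr = llr_editing(usable, c.ref_base, alt)
    return candidates
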