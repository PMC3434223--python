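"""Quality-filtered pileup counting and the empirical substitution spectrum.

The spectrum is the dataset-wide tally of the 12 reference→observed mismatch
types (plus reference-matching totals) at a fixed base-quality cutoff.  Its
relative frequencies supply the expectation against which each candidate
site's A/G composition is tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BASES, BASE_INDEX, GenomeSequence
from .mapping import trim_record_ends

SUBSTITUTION_TYPES = tuple(
    (r, o) for r in BASES for o in BASES if r != o
)  # 12 ordered mismatch types


@dataclass
class BaseObservation:
    """One aligned base at one genomic site."""

    base: str
    phred: int
    strand: str = "+"
    read_id: str = ""
    duplicate: bool = False

    def __post_init__(self):
        if self.phred < 0:
            raise ValueError("negative Phred quality")


@dataclass
class SiteCounts:
    """Per-site A/C/G/T counts before and after the base-quality filter."""

    chrom: str
    position: int
    ref_base: str
    counts_filtered: np.ndarray
    counts_raw: np.ndarray
    n_plus: int = 0  # filtered coverage from forward-strand reads
    n_minus: int = 0

    @property
    def coverage(self) -> int:
        return int(self.counts_filtered.sum())

    @property
    def raw_coverage(self) -> int:
        return int(self.counts_raw.sum())

    def count(self, base: str, filtered: bool = True) -> int:
        arr = self.counts_filtered if filtered else self.counts_raw
        return int(arr[BASE_INDEX[base]])


def pileup_site_counts(observations, ref_base: str, min_quality: int = 25) -> SiteCounts:
    """Tally one site's observations into raw and quality-filtered counts.

    N bases and duplicate-flagged observations contribute to neither tally.
    """
    raw = np.zeros(4, dtype=np.int64)
    filt = np.zeros(4, dtype=np.int64)
    n_plus = n_minus = 0
    for ob in observations:
        if ob.duplicate or ob.base not in BASE_INDEX:
            continue
        i = BASE_INDEX[ob.base]
        raw[i] += 1
        if ob.phred >= min_quality:
            filt[i] += 1
            if ob.strand == "+":
                n_plus += 1
            else:
                n_minus += 1
    return SiteCounts("", 0, ref_base, filt, raw, n_plus, n_minus)


_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in BASE_INDEX.items():
    _BASE_CODE[ord(_b)] = _i


def pileup_alignments(
    records,
    genome: dict[str, GenomeSequence],
    min_quality: int = 25,
    end_trim: int = 0,
) -> list[SiteCounts]:
    """Traverse alignments position by position and count observed bases.

    Returns SiteCounts for every covered position, ordered by (chrom,
    position).  Duplicate-flagged records and N bases are skipped; the raw
    tally ignores the quality filter, the filtered tally requires Phred >=
    ``min_quality``.  ``end_trim`` removes that many bases from both read
    ends before counting.
    """
    per_chrom: dict[str, tuple] = {}

    def arrays(chrom):
        if chrom not in per_chrom:
            n = len(genome[chrom]) + 1
            per_chrom[chrom] = (
                np.zeros((4, n), dtype=np.int32),  # raw
                np.zeros((4, n), dtype=np.int32),  # filtered
                np.zeros(n, dtype=np.int32),  # filtered fwd coverage
                np.zeros(n, dtype=np.int32),  # filtered rev coverage
            )
        return per_chrom[chrom]

    for rec in records:
        if rec.duplicate:
            continue
        if end_trim:
            rec = trim_record_ends(rec, end_trim)
            if rec is None:
                continue
        raw, filt, fwd, rev = arrays(rec.ref_name)
        codes = _BASE_CODE[np.frombuffer(rec.bases.encode(), dtype=np.uint8)]
        quals = np.asarray(rec.quals)
        positions = np.concatenate([np.arange(s, e + 1) for s, e in rec.blocks])
        ok = codes >= 0
        pos_ok, codes_ok, q_ok = positions[ok], codes[ok], quals[ok]
        np.add.at(raw, (codes_ok, pos_ok), 1)
        hi = q_ok >= min_quality
        np.add.at(filt, (codes_ok[hi], pos_ok[hi]), 1)
        strand_arr = fwd if rec.strand == "+" else rev
        np.add.at(strand_arr, pos_ok[hi], 1)

    sites = []
    for chrom in sorted(per_chrom):
        raw, filt, fwd, rev = per_chrom[chrom]
        covered = np.nonzero(raw.sum(axis=0) > 0)[0]
        seq = genome[chrom].seq
        for pos in covered:
            sites.append(
                SiteCounts(
                    chrom=chrom,
                    position=int(pos),
                    ref_base=seq[pos - 1],
                    counts_filtered=filt[:, pos].astype(np.int64),
                    counts_raw=raw[:, pos].astype(np.int64),
                    n_plus=int(fwd[pos]),
                    n_minus=int(rev[pos]),
                )
            )
    return sites


def collect_observations(records, targets, end_trim: int = 0):
    """Gather per-base observations at selected (chrom, position) sites.

    Returns a dict mapping each requested site to its list of
    BaseObservation (duplicate records skipped).  Used for the per-read
    likelihood computations that need individual qualities, not just counts.
    """
    wanted = set(targets)
    out = {k: [] for k in wanted}
    for rec in records:
        if rec.duplicate:
            continue
        if end_trim:
            rec = trim_record_ends(rec, end_trim)
            if rec is None:
                continue
        offset = 0
        for s, e in rec.blocks:
            for pos in range(s, e + 1):
                key = (rec.ref_name, pos)
                if key in wanted:
                    i = offset + pos - s
                    out[key].append(
                        BaseObservation(
                            base=rec.bases[i],
                            phred=rec.quals[i],
                            strand=rec.strand,
                            read_id=rec.read_id,
                        )
                    )
            offset += e - s + 1
    return out


@dataclass
class SubstitutionSpectrum:
    """Dataset-wide mismatch tallies versus the reference genome.

    ``sub_counts`` maps each of the 12 ordered mismatch types to its
    quality-filtered base count, ``match_counts`` holds the
    reference-matching totals per reference base.  Tallied in
    reference-genome orientation (no strand collapsing).
    """

    sub_counts: dict = field(default_factory=lambda: {t: 0 for t in SUBSTITUTION_TYPES})
    match_counts: dict = field(default_factory=lambda: {b: 0 for b in BASES})
    min_quality: int = 25
    masked_positions: int = 0

    @property
    def total_substitutions(self) -> int:
        return sum(self.sub_counts.values())

    def background_counts(self, ref: str, alt: str) -> tuple[int, int]:
        """(reference-matching, mismatching) totals for one substitution type."""
        return self.match_counts[ref], self.sub_counts[(ref, alt)]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# min_quality={self.min_quality}\n")
            fh.write(f"# masked_positions={self.masked_positions}\n")
            for (r, o), c in self.sub_counts.items():
                fh.write(f"{r}>{o}\t{c}\n")
            for b, c in self.match_counts.items():
                fh.write(f"{b}={b}\t{c}\n")

    @classmethod
    def from_tsv(cls, path) -> "SubstitutionSpectrum":
        spec = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("# min_quality="):
                    spec.min_quality = int(line.split("=")[1])
                elif line.startswith("# masked_positions="):
                    spec.masked_positions = int(line.split("=")[1])
                elif ">" in line:
                    key, count = line.split("\t")
                    r, o = key.split(">")
                    spec.sub_counts[(r, o)] = int(count)
                elif "=" in line and "\t" in line:
                    key, count = line.split("\t")
                    spec.match_counts[key.split("=")[0]] = int(count)
        return spec


def build_spectrum(site_counts, snp_table=None, min_quality: int = 25) -> SubstitutionSpectrum:
    """Accumulate the empirical substitution spectrum over covered sites.

    Sites listed in ``snp_table`` are masked: true polymorphisms are not
    sequencing noise and would inflate the A→G background.  The stream must
    have been counted at the same quality threshold recorded here.
    """
    spectrum = SubstitutionSpectrum(min_quality=min_quality)
    for sc in site_counts:
        if snp_table is not None and (sc.chrom, sc.position) in snp_table:
            spectrum.masked_positions += 1
            continue
        ref = sc.ref_base
        if ref not in BASE_INDEX:
            continue
        for base in BASES:
            n = sc.count(base)
            if n == 0:
                continue
            if base == ref:
                spectrum.match_counts[ref] += n
            else:
                spectrum.sub_counts[(ref, base)] += n
    return spectrum


def spectrum_frequencies(spectrum: SubstitutionSpectrum):
    """Relative frequency of each mismatch type, two normalisations.

    ``type_freq`` divides each type by the total number of substitutions
    (sums to 1 when any substitution was seen); ``per_ref_rate`` divides by
    all observed bases over that reference base (matches + mismatches).
    """
    total = spectrum.total_substitutions
    type_freq = {
        t: (c / total if total else 0.0) for t, c in spectrum.sub_counts.items()
    }
    per_ref_rate = {}
    for (r, o), c in spectrum.sub_counts.items():
        denom = spectrum.match_counts[r] + sum(
            spectrum.sub_counts[(r, z)] for z in BASES if z != r
        )
        per_ref_rate[(r, o)] = c / denom if denom else 0.0
    return type_freq, per_ref_rate
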