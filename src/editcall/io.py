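"""Readers and writers for the external formats the pipeline touches.

Genomes come in as FASTA, gene models as GTF or BED12, alignments as SAM,
known SNPs as a two-column chrom/position table, and candidate sites go out
as a tab-separated report.  All coordinates exposed by this module are
1-based inclusive, the convention used when reporting sites such as
``chr4:57670991``; zero-based half-open arithmetic is confined to the parsing
internals of each reader.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Genome


@dataclass
class GenomeSequence:
    """One reference chromosome as an uppercase A/C/G/T/N string."""

    name: str
    seq: str

    def __post_init__(self):
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"empty sequence for {self.name}")

    def __len__(self) -> int:
        return len(self.seq)

    def base(self, position: int) -> str:
        """Base at a 1-based position."""
        if not 1 <= position <= len(self.seq):
            raise IndexError(f"{self.name}:{position} outside [1, {len(self.seq)}]")
        return self.seq[position - 1]


def read_fasta(path) -> dict[str, GenomeSequence]:
    """Load a FASTA reference into memory, keyed by sequence name."""
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq))
    return genome


def write_fasta(genome: dict[str, GenomeSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for gs in genome.values():
            fh.write(f">{gs.name}\n")
            for i in range(0, len(gs.seq), width):
                fh.write(gs.seq[i : i + width] + "\n")


def genome_base(genome: dict[str, GenomeSequence], chrom: str, position: int) -> str:
    return genome[chrom].base(position)


# ---------------------------------------------------------------------------
# Gene models


@dataclass
class GeneModel:
    """A transcript: ordered exons on a genome strand, optionally with a CDS.

    ``exons`` are 1-based inclusive genomic intervals sorted by start;
    ``cds_start``/``cds_end`` bound the coding region in genomic coordinates
    (``cds_start`` <= ``cds_end`` regardless of strand) or are ``None`` for
    non-coding transcripts.
    """

    transcript_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = tuple((int(s), int(e)) for s, e in self.exons)
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        prev_end = 0
        for s, e in self.exons:
            if s > e or s <= prev_end:
                raise ValueError(f"{self.transcript_id}: exons not sorted/disjoint")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def transcript_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def genomic_positions(self) -> np.ndarray:
        """Genomic position of every transcript base, in transcript order.

        Index ``k`` (0-based) holds the genomic coordinate of transcript base
        ``k+1``: ascending through the exons for plus-strand models,
        descending from the highest exonic coordinate for minus-strand ones.
        """
        pos = np.concatenate([np.arange(s, e + 1) for s, e in self.exons])
        return pos if self.strand == "+" else pos[::-1]

    def transcript_seq(self, genome: dict[str, GenomeSequence]) -> str:
        chrom_seq = genome[self.chrom].seq
        spliced = "".join(chrom_seq[s - 1 : e] for s, e in self.exons)
        return spliced if self.strand == "+" else revcomp(spliced)

    def cds_transcript_interval(self) -> tuple[int, int] | None:
        """CDS bounds in 1-based transcript coordinates (start <= end)."""
        if self.cds_start is None:
            return None
        gpos = self.genomic_positions()
        idx = np.nonzero((gpos >= self.cds_start) & (gpos <= self.cds_end))[0]
        if idx.size == 0:
            raise ValueError(f"{self.transcript_id}: CDS outside exons")
        return int(idx[0]) + 1, int(idx[-1]) + 1

    def cds_length(self) -> int:
        iv = self.cds_transcript_interval()
        return 0 if iv is None else iv[1] - iv[0] + 1


_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(path) -> list[GeneModel]:
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}: malformed GTF line {lineno}")
            chrom, _src, feat, start, end, _score, strand, _frame, attrs = fields[:9]
            if feat not in ("exon", "CDS"):
                continue
            try:
                start, end = int(start), int(end)
            except ValueError:
                raise ValueError(f"{path}: non-integer coordinate on line {lineno}")
            ad = dict(_GTF_ATTR.findall(attrs))
            tid = ad.get("transcript_id")
            if tid is None:
                raise ValueError(f"{path}: missing transcript_id on line {lineno}")
            gene = ad.get("gene_name", ad.get("gene_id", tid))
            meta.setdefault(tid, (gene, chrom, strand))
            (exons if feat == "exon" else cds).setdefault(tid, []).append((start, end))
    models = []
    for tid, (gene, chrom, strand) in meta.items():
        ex = sorted(exons.get(tid, []))
        cs = ce = None
        if tid in cds:
            intervals = cds[tid]
            cs = min(s for s, _ in intervals)
            ce = max(e for _, e in intervals)
        models.append(GeneModel(tid, gene, chrom, strand, tuple(ex), cs, ce))
    return models


def _parse_bed12(path) -> list[GeneModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 12:
                raise ValueError(f"{path}: BED12 needs 12 fields, line {lineno}")
            try:
                chrom_start, chrom_end = int(f[1]), int(f[2])
                n_blocks = int(f[9])
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                thick_start, thick_end = int(f[6]), int(f[7])
            except ValueError:
                raise ValueError(f"{path}: malformed BED12 line {lineno}")
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}: block count mismatch on line {lineno}")
            exons = tuple(
                (chrom_start + st + 1, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            )
            cs = ce = None
            if thick_end > thick_start:
                cs, ce = thick_start + 1, thick_end
            models.append(GeneModel(f[3], f[3], f[0], f[5], exons, cs, ce))
    return models


def read_gene_models(path, dialect: str) -> list[GeneModel]:
    """Read transcript models from a GTF or BED12 file.

    Exon coordinates are normalised to 1-based inclusive whichever dialect
    is used; BED12 thickStart/thickEnd become the CDS when non-empty.
    """
    dialect = dialect.upper()
    if dialect == "GTF":
        return _parse_gtf(path)
    if dialect == "BED12":
        return _parse_bed12(path)
    raise ValueError(f"unknown gene-model dialect {dialect!r} (use GTF or BED12)")


def write_bed12(models: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(e - s + 1) for s, e in m.exons)
            starts = ",".join(str(s - m.start) for s, e in m.exons)
            thick = (m.cds_start - 1, m.cds_end) if m.cds_start else (m.start - 1, m.start - 1)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        m.chrom, m.start - 1, m.end, m.transcript_id, 0, m.strand,
                        thick[0], thick[1], 0, len(m.exons), sizes, starts,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Known-SNP table


class SnpTable:
    """Set of known polymorphic positions, (chrom, 1-based position)."""

    def __init__(self, positions=()):
        self._positions = set(positions)

    def __contains__(self, key) -> bool:
        return tuple(key) in self._positions

    def __len__(self) -> int:
        return len(self._positions)

    def add(self, chrom: str, position: int) -> None:
        self._positions.add((chrom, int(position)))

    def __iter__(self):
        return iter(self._positions)


def read_snp_table(path) -> SnpTable:
    """Read a two-column chrom/position table (dbSNP-style dump)."""
    table = SnpTable()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if lineno == 1 and len(fields) >= 2 and not _is_int(fields[1]):
                continue  # header row
            if len(fields) < 2 or not _is_int(fields[1]):
                raise ValueError(f"{path}: non-integer position on line {lineno}")
            table.add(fields[0], int(fields[1]))
    return table


def write_snp_table(table: SnpTable, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos in sorted(table):
            fh.write(f"{chrom}\t{pos}\n")


def _is_int(s: str) -> bool:
    try:
        int(s)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Alignments (SAM)


@dataclass
class AlignmentRecord:
    """One aligned read in genome (or transcriptome) space.

    ``blocks`` are the gapped/spliced aligned segments as 1-based inclusive
    reference intervals; ``bases`` and ``quals`` run left-to-right across the
    blocks in reference orientation, exactly as SAM stores them.
    """

    read_id: str
    ref_name: str
    start: int
    strand: str
    blocks: tuple[tuple[int, int], ...]
    bases: str
    quals: tuple[int, ...]
    paired: bool = False
    mate: int = 1
    unique: bool = True
    duplicate: bool = False

    def __post_init__(self):
        self.blocks = tuple((int(s), int(e)) for s, e in self.blocks)
        span = sum(e - s + 1 for s, e in self.blocks)
        if span != len(self.bases) or len(self.bases) != len(self.quals):
            raise ValueError(
                f"{self.read_id}: blocks span {span} but {len(self.bases)} bases"
                f" / {len(self.quals)} qualities"
            )

    @property
    def length(self) -> int:
        return len(self.bases)

    def mean_quality(self) -> float:
        return float(np.mean(self.quals))

    def n_count(self) -> int:
        return self.bases.count("N")

    def key(self):
        return (self.read_id, self.mate)


def _blocks_to_cigar(blocks) -> list[tuple[int, int]]:
    cigar = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1] - 1
            cigar.append((3, gap))  # N
        cigar.append((0, e - s + 1))  # M
    return cigar


def write_sam(records, path, ref_lengths: dict[str, int]) -> None:
    """Write records as plain-text SAM with standard FLAG/NH conventions."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.reference_name = r.ref_name
            a.reference_start = r.start - 1
            a.query_sequence = r.bases
            a.query_qualities = list(r.quals)
            a.cigartuples = _blocks_to_cigar(r.blocks)
            flag = 0
            if r.paired:
                flag |= 0x1 | (0x40 if r.mate == 1 else 0x80)
            if r.strand == "-":
                flag |= 0x10
            if r.duplicate:
                flag |= 0x400
            a.flag = flag
            a.mapping_quality = 60 if r.unique else 0
            a.set_tag("NH", 1 if r.unique else 2)
            out.write(a)


def read_sam(path) -> list[AlignmentRecord]:
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.query_sequence is None:
                continue
            blocks = tuple((s + 1, e) for s, e in a.get_blocks())
            nh = a.get_tag("NH") if a.has_tag("NH") else 1
            records.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    ref_name=a.reference_name,
                    start=a.reference_start + 1,
                    strand="-" if a.is_reverse else "+",
                    blocks=blocks,
                    bases=a.query_sequence.upper(),
                    quals=tuple(a.query_qualities),
                    paired=a.is_paired,
                    mate=2 if (a.is_paired and a.is_read2) else 1,
                    unique=(nh == 1 and a.mapping_quality > 0),
                    duplicate=a.is_duplicate,
                )
            )
    return records


def write_fastq(records, path) -> None:
    """Export reads in original read orientation (reverse strand flipped back)."""
    with open(path, "w") as fh:
        for r in records:
            bases, quals = r.bases, list(r.quals)
            if r.strand == "-":
                bases, quals = revcomp(bases), quals[::-1]
            qstring = pysam.qualities_to_qualitystring(quals)
            name = r.read_id + (f"/{r.mate}" if r.paired else "")
            fh.write(f"@{name}\n{bases}\n+\n{qstring}\n")


# ---------------------------------------------------------------------------
# Candidate table

_CANDIDATE_COLUMNS = [
    "Position", "Gene", "Ref", "ST", "CC", "AAC", "CodP", "CovR",
    "BCR [A, C, G, T]", "BCR-F [A, C, G, T]", "%Editing", "Pvalue", "FDR",
]
_DNA_COLUMNS = ["CovE", "BCE [A, C, G, T]", "Status", "LLR"]


def _fmt_counts(counts) -> str:
    return "[" + ", ".join(str(int(c)) for c in counts) + "]"


def _parse_counts(text: str) -> np.ndarray:
    return np.array([int(x) for x in text.strip("[] ").split(",")], dtype=int)


def _fmt_p(p: float) -> str:
    return f"{p:.2e}"


def write_candidate_table(candidates, path, with_dna: bool = False, header_lines=()) -> None:
    """Write ranked candidates as TSV in the published report layout.

    One row per site, sorted by ascending p-value (the caller already ranks
    them); ``with_dna`` appends the exome-evidence columns.  ``header_lines``
    are emitted first, '#'-prefixed, for run metadata.
    """
    cols = _CANDIDATE_COLUMNS + (_DNA_COLUMNS if with_dna else [])
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(cols) + "\n")
        for c in candidates:
            eff = c.codon_effect
            row = [
                f"{c.chrom}:{c.position}",
                c.gene or ".",
                c.ref_base,
                c.substitution_type,
                f"{eff.ref_codon} --> {eff.edited_codon}" if eff else ".",
                f"{eff.ref_aa} --> {eff.edited_aa}" if eff else ".",
                str(eff.codon_position) if eff else ".",
                str(int(c.coverage)),
                _fmt_counts(c.counts_filtered),
                _fmt_counts(c.counts_raw),
                f"{100 * c.editing_fraction:.2f}",
                _fmt_p(c.p_value),
                _fmt_p(c.fdr),
            ]
            if with_dna:
                ev = c.dna_evidence
                row += [
                    str(int(ev.coverage)) if ev else ".",
                    _fmt_counts(ev.counts_filtered) if ev else ".",
                    ev.status if ev else ".",
                    f"{c.llr.llr:.2f}" if c.llr is not None else "ND",
                ]
            fh.write("\t".join(row) + "\n")


def read_candidate_table(path):
    """Re-read a candidate table into a pandas DataFrame with parsed counts."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("BCR [A, C, G, T]", "BCR-F [A, C, G, T]", "BCE [A, C, G, T]"):
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: _parse_counts(v) if isinstance(v, str) and v != "." else None
            )
    if "Position" in df.columns:
        parts = df["Position"].str.split(":", expand=True)
        df["chrom"] = parts[0]
        df["position"] = parts[1].astype(int)
    return df


# ---------------------------------------------------------------------------
# Misc exports


def write_junctions(junctions, path) -> None:
    """Tab-separated donor/acceptor export of an exon-exon junction set."""
    with open(path, "w") as fh:
        fh.write("chrom\tdonor\tacceptor\tstrand\n")
        for chrom, donor, acceptor, strand in sorted(junctions):
            fh.write(f"{chrom}\t{donor}\t{acceptor}\t{strand}\n")
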