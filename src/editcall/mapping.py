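"""Double-mapping concordance logic.

RNA reads are aligned twice — once to an assembled transcriptome, once to the
genome.  Transcriptome hits are projected through their gene model into
genomic coordinates and only reads whose two placements coincide exactly are
kept, which removes the paralog- and retrocopy-induced misplacements that
otherwise masquerade as A-to-G editing signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AlignmentRecord, GeneModel, revcomp


@dataclass
class TranscriptAlignment:
    """A read placed on a transcript, in 1-based transcript coordinates."""

    read_id: str
    transcript_id: str
    start: int
    bases: str
    quals: tuple[int, ...]
    strand: str = "+"  # orientation of the read on the transcript
    mate: int = 1
    unique: bool = True

    def __post_init__(self):
        if self.start < 1:
            raise ValueError(f"{self.read_id}: transcript start {self.start} < 1")
        if len(self.bases) != len(self.quals):
            raise ValueError(f"{self.read_id}: base/quality length mismatch")

    @property
    def length(self) -> int:
        return len(self.bases)


@dataclass
class ProjectedAlignment:
    """A transcript alignment lifted to the genome: spliced blocks plus the
    read's bases/qualities re-oriented to the reference strand."""

    read_id: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    bases: str
    quals: tuple[int, ...]
    mate: int = 1
    unique: bool = True

    def key(self):
        return (self.read_id, self.mate)


def prefilter_reads(records, max_n: int = 2, min_mean_quality: float = 20.0):
    """Drop reads with too many N calls or low overall quality.

    Keeps exactly the records with at most ``max_n`` N characters and a mean
    Phred of at least ``min_mean_quality``; input order is preserved.
    """
    return [
        r
        for r in records
        if r.n_count() <= max_n and r.mean_quality() >= min_mean_quality
    ]


def _positions_to_blocks(positions: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Group sorted ascending genomic positions into maximal runs."""
    breaks = np.nonzero(np.diff(positions) != 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [positions.size - 1]))
    return tuple((int(positions[s]), int(positions[e])) for s, e in zip(starts, ends))


def project_to_genome(ta: TranscriptAlignment, model: GeneModel) -> ProjectedAlignment:
    """Lift a transcript-space alignment into genome coordinates.

    Transcript base ``k`` maps to the k-th exonic base in genomic order for
    plus-strand models and to the k-th base counting down from the highest
    exonic coordinate for minus-strand ones; blocks split at exon boundaries.
    The reported strand composes the read's orientation on the transcript
    with the model's genome strand.
    """
    if ta.transcript_id != model.transcript_id:
        raise ValueError(
            f"alignment is on {ta.transcript_id}, model is {model.transcript_id}"
        )
    gpos = model.genomic_positions()
    if ta.start + ta.length - 1 > gpos.size:
        raise ValueError(
            f"{ta.read_id}: alignment overruns transcript {model.transcript_id}"
        )
    span = gpos[ta.start - 1 : ta.start - 1 + ta.length]
    bases, quals = ta.bases, list(ta.quals)
    if model.strand == "-":
        # genomic order is the reverse complement of transcript order
        span = span[::-1]
        bases = revcomp(bases)
        quals = quals[::-1]
    strand = "+" if ta.strand == model.strand else "-"
    return ProjectedAlignment(
        read_id=ta.read_id,
        chrom=model.chrom,
        strand=strand,
        blocks=_positions_to_blocks(span),
        bases=bases,
        quals=tuple(quals),
        mate=ta.mate,
        unique=ta.unique,
    )


def genome_to_transcript(model: GeneModel, chrom: str, position: int) -> int | None:
    """Inverse of the projection map: 1-based transcript coordinate of a
    genomic position, or None when the position is not exonic."""
    if chrom != model.chrom:
        return None
    gpos = model.genomic_positions()
    hits = np.nonzero(gpos == position)[0]
    return int(hits[0]) + 1 if hits.size else None


def junctions_from_models(models) -> set[tuple[str, int, int, str]]:
    """Distinct exon-exon junctions (chrom, donor end, acceptor start, strand)
    across all models, deduplicated set-wise."""
    junctions = set()
    for m in models:
        for (s1, e1), (s2, e2) in zip(m.exons, m.exons[1:]):
            junctions.add((m.chrom, e1, s2, m.strand))
    return junctions


def concordance_filter(projected, genomic) -> list[AlignmentRecord]:
    """Keep genome alignments that agree with the projected transcriptome
    placement of the same read.

    Agreement means the same chromosome, strand and the identical set of
    genomic blocks; both placements must be unique.  For paired reads both
    mates must agree or the whole pair is dropped.
    """
    proj_by_key: dict = {}
    ambiguous = set()
    for p in projected:
        k = p.key()
        if k in proj_by_key:
            ambiguous.add(k)
        proj_by_key[k] = p

    def concordant(rec: AlignmentRecord) -> bool:
        k = rec.key()
        if k in ambiguous or not rec.unique:
            return False
        p = proj_by_key.get(k)
        return (
            p is not None
            and p.unique
            and p.chrom == rec.ref_name
            and p.strand == rec.strand
            and p.blocks == rec.blocks
        )

    passing = {r.key() for r in genomic if concordant(r)}
    kept = []
    for r in genomic:
        if r.key() not in passing:
            continue
        if r.paired:
            other = (r.read_id, 2 if r.mate == 1 else 1)
            if other not in passing:
                continue
        kept.append(r)
    return kept


def trim_record_ends(record: AlignmentRecord, n: int) -> AlignmentRecord | None:
    """Drop the first and last ``n`` aligned bases of a record (both read
    ends), splitting/shrinking blocks accordingly.  Returns None when nothing
    remains."""
    if n <= 0:
        return record
    if record.length <= 2 * n:
        return None
    positions = np.concatenate(
        [np.arange(s, e + 1) for s, e in record.blocks]
    )[n:-n]
    return AlignmentRecord(
        read_id=record.read_id,
        ref_name=record.ref_name,
        start=int(positions[0]),
        strand=record.strand,
        blocks=_positions_to_blocks(positions),
        bases=record.bases[n:-n],
        quals=record.quals[n:-n],
        paired=record.paired,
        mate=record.mate,
        unique=record.unique,
        duplicate=record.duplicate,
    )
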