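"""Gene-region assignment and codon-level consequences of A-to-G edits.

A candidate position is classified as CDS, 5'/3'UTR, intron, alternative
exon (exonic only outside the designated reference transcript set) or
intergenic.  For coding positions the affected codon is reconstructed in
spliced, strand-aware CDS coordinates and translated before and after the
edit with the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .io import GeneModel, GenomeSequence

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

REGION_LABELS = ("CDS", "UTR5", "UTR3", "intron", "alt-exon", "intergenic")


@dataclass
class RegionAnnotation:
    gene: str | None
    transcript_id: str | None
    label: str
    strand: str | None
    repeat_overlap: bool = False


@dataclass
class CodonEffect:
    codon_position: int  # 1, 2 or 3
    ref_codon: str
    edited_codon: str
    ref_aa: str
    edited_aa: str

    @property
    def synonymous(self) -> bool:
        return self.ref_aa == self.edited_aa


class GeneIndex:
    """Interval index over gene model spans for point queries."""

    def __init__(self, models):
        self._trees: dict[str, IntervalTree] = {}
        for m in models:
            self._trees.setdefault(m.chrom, IntervalTree()).addi(
                m.start, m.end + 1, m
            )

    def overlapping(self, chrom: str, position: int):
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(position)]


def build_repeat_index(intervals) -> dict[str, IntervalTree]:
    """Index repeat intervals given as (chrom, start, end) 1-based inclusive."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals:
        trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
    return trees


def read_repeat_bed(path):
    """Repeat intervals from BED (0-based half-open) as 1-based inclusive."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.split()
            out.append((f[0], int(f[1]) + 1, int(f[2])))
    return out


def _exon_containing(model: GeneModel, position: int):
    for s, e in model.exons:
        if s <= position <= e:
            return (s, e)
    return None


def _classify_in_model(model: GeneModel, position: int) -> str | None:
    """Label of a position within one model's span, or None if outside."""
    if not (model.start <= position <= model.end):
        return None
    if _exon_containing(model, position) is None:
        return "intron"
    if model.cds_start is None:
        return "exon"  # non-coding transcript: exonic, no UTR/CDS structure
    if model.cds_start <= position <= model.cds_end:
        return "CDS"
    upstream = position < model.cds_start
    if model.strand == "+":
        return "UTR5" if upstream else "UTR3"
    return "UTR3" if upstream else "UTR5"


def assign_region(
    chrom: str,
    position: int,
    gene_models,
    reference_transcripts: set | None = None,
    repeat_index=None,
    strand: str | None = None,
) -> RegionAnnotation:
    """Classify a genomic position against transcript annotations.

    CDS beats UTR beats alt-exon beats intron; the reporting transcript for a
    CDS label is the one with the longest CDS.  Positions exonic only in
    transcripts outside ``reference_transcripts`` (when given) are
    alternative exons.  ``strand`` restricts the candidate models.
    """
    index = gene_models if isinstance(gene_models, GeneIndex) else GeneIndex(gene_models)
    models = index.overlapping(chrom, position)
    if strand is not None:
        models = [m for m in models if m.strand == strand]

    repeat = False
    if repeat_index is not None:
        tree = repeat_index.get(chrom)
        repeat = bool(tree is not None and tree.at(position))

    best: dict[str, GeneModel] = {}
    for m in models:
        label = _classify_in_model(m, position)
        if label is None:
            continue
        is_reference = reference_transcripts is None or m.transcript_id in reference_transcripts
        if label == "exon" or not is_reference:
            label = "alt-exon" if label != "intron" else "intron"
        if label not in best:
            best[label] = m
        elif label == "CDS" and m.cds_length() > best[label].cds_length():
            best[label] = m
        elif label != "CDS" and m.transcript_length > best[label].transcript_length:
            best[label] = m

    for label in ("CDS", "UTR5", "UTR3", "alt-exon", "intron"):
        if label in best:
            m = best[label]
            return RegionAnnotation(m.gene_name, m.transcript_id, label, m.strand, repeat)
    return RegionAnnotation(None, None, "intergenic", None, repeat)


def codon_effect(
    chrom: str,
    position: int,
    model: GeneModel,
    genome: dict[str, GenomeSequence],
    alt_base: str = "G",
) -> CodonEffect:
    """Consequence of substituting ``alt_base`` (transcribed-strand) at a
    CDS position: the containing codon before and after, both translated.

    Raises when the position is outside the model's CDS or the CDS length is
    not a multiple of three.
    """
    if model.cds_start is None or not (model.cds_start <= position <= model.cds_end):
        raise ValueError(f"{chrom}:{position} not in CDS of {model.transcript_id}")
    cds_iv = model.cds_transcript_interval()
    cds_len = cds_iv[1] - cds_iv[0] + 1
    if cds_len % 3:
        raise ValueError(f"{model.transcript_id}: CDS length {cds_len} not divisible by 3")

    gpos = model.genomic_positions()
    tx_index = np.nonzero(gpos == position)[0]
    if tx_index.size == 0:
        raise ValueError(f"{chrom}:{position} is intronic in {model.transcript_id}")
    cds_offset = int(tx_index[0]) + 1 - cds_iv[0]  # 0-based within spliced CDS
    codon_idx = cds_offset // 3
    codon_position = cds_offset % 3 + 1

    chrom_seq = genome[model.chrom].seq
    codon_genomic = gpos[cds_iv[0] - 1 + 3 * codon_idx : cds_iv[0] - 1 + 3 * codon_idx + 3]
    ref_codon = "".join(
        chrom_seq[p - 1] if model.strand == "+" else _COMPLEMENT[chrom_seq[p - 1]]
        for p in codon_genomic
    )
    edited = list(ref_codon)
    edited[codon_position - 1] = alt_base
    edited_codon = "".join(edited)
    return CodonEffect(
        codon_position=codon_position,
        ref_codon=ref_codon,
        edited_codon=edited_codon,
        ref_aa=str(Seq(ref_codon).translate()),
        edited_aa=str(Seq(edited_codon).translate()),
    )


def codon_change_effect(ref_codon: str, edited_codon: str) -> CodonEffect:
    """CodonEffect from an explicit codon pair (for re-deriving published
    amino-acid columns from printed codon changes)."""
    diffs = [i for i in range(3) if ref_codon[i] != edited_codon[i]]
    if len(diffs) != 1:
        raise ValueError(f"codons {ref_codon}->{edited_codon} differ at {len(diffs)} positions")
    return CodonEffect(
        codon_position=diffs[0] + 1,
        ref_codon=ref_codon,
        edited_codon=edited_codon,
        ref_aa=str(Seq(ref_codon).translate()),
        edited_aa=str(Seq(edited_codon).translate()),
    )
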