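"""Synthetic data generator: small multi-gene genomes, spliced transcripts,
stranded/unstranded reads with Phred-calibrated errors, planted editing
sites and SNPs, matched DNA reads, and paralog decoys.

Reads are emitted already truth-placed as genome-space spliced alignments,
isolating the downstream statistics from aligner behaviour; an optional
FASTQ export supports external-aligner integration.  The paralog decoy
reproduces the retrocopy failure mode in which a gene's reads also align
perfectly, and contiguously, to an intronless near-identical copy elsewhere
in the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import AlignmentRecord, GeneModel, GenomeSequence, SnpTable, revcomp
from .mapping import ProjectedAlignment, _positions_to_blocks

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
_BASES = np.array(list("ACGT"))


@dataclass
class ErrorModel:
    """Uniform per-base miscall model: constant Phred, wrong base uniform."""

    phred: int = 30

    @property
    def miscall_rate(self) -> float:
        return 10.0 ** (-self.phred / 10.0)


@dataclass
class EditingSite:
    chrom: str
    position: int
    strand: str  # transcribed strand
    level: float


@dataclass
class PlantedSnp:
    chrom: str
    position: int
    ref: str
    alt: str  # genome plus-strand alternate allele
    genotype: str  # "het" | "hom"


@dataclass
class SimulationTruth:
    """Everything the generator decided: the ground truth for all tests."""

    genome: dict
    models: list
    editing_sites: list = field(default_factory=list)
    snps: list = field(default_factory=list)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    seed: int = 0

    def editing_positions(self) -> set:
        return {(e.chrom, e.position) for e in self.editing_sites}

    def snp_table(self) -> SnpTable:
        return SnpTable((s.chrom, s.position) for s in self.snps)

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tchrom\tposition\tstrand_or_genotype\tlevel_or_alt\n")
            for e in self.editing_sites:
                fh.write(f"editing\t{e.chrom}\t{e.position}\t{e.strand}\t{e.level}\n")
            for s in self.snps:
                fh.write(f"snp\t{s.chrom}\t{s.position}\t{s.genotype}\t{s.ref}>{s.alt}\n")


@dataclass
class DecoyInfo:
    """Location of an intronless paralog copy of a source transcript."""

    chrom: str
    start: int
    end: int
    source_transcript_id: str
    mismatch_positions: tuple  # genomic positions where the decoy differs


def make_reference(
    seed: int,
    n_genes: int = 6,
    exons_per_gene: int = 3,
    exon_len: int = 150,
    intron_len: int = 100,
    utr5_len: int = 30,
    utr3_len: int = 30,
    spacer: int = 200,
    chrom: str = "chr_sim",
):
    """Deterministic random genome with non-overlapping genes on both strands.

    Each gene has ``exons_per_gene`` exons of ``exon_len``; the transcript
    carries a 5'UTR, a CDS whose length must be a multiple of three, and a
    3'UTR.  Strands alternate so half the genes are minus-strand.
    """
    if min(n_genes, exons_per_gene, exon_len, intron_len, spacer) <= 0:
        raise ValueError("all sizes must be positive")
    tx_len = exons_per_gene * exon_len
    cds_len = tx_len - utr5_len - utr3_len
    if cds_len <= 0 or cds_len % 3:
        raise ValueError(
            f"CDS length {cds_len} (transcript {tx_len} minus UTRs) must be a "
            "positive multiple of 3"
        )
    rng = np.random.default_rng(seed)
    gene_span = exons_per_gene * exon_len + (exons_per_gene - 1) * intron_len
    total = spacer + n_genes * (gene_span + spacer)
    seq = "".join(rng.choice(_BASES, size=total))
    genome = {chrom: GenomeSequence(chrom, seq)}

    models = []
    cursor = spacer + 1
    for i in range(n_genes):
        strand = "+" if i % 2 == 0 else "-"
        exons = []
        pos = cursor
        for _ in range(exons_per_gene):
            exons.append((pos, pos + exon_len - 1))
            pos += exon_len + intron_len
        model = GeneModel(f"tx{i + 1}", f"gene{i + 1}", chrom, strand, tuple(exons))
        gpos = model.genomic_positions()
        cds_positions = gpos[utr5_len : utr5_len + cds_len]
        model.cds_start = int(cds_positions.min())
        model.cds_end = int(cds_positions.max())
        models.append(model)
        cursor += gene_span + spacer
    return genome, models


def plant_sites(
    genome,
    models,
    n_editing: int = 5,
    levels=0.4,
    n_het_snps: int = 2,
    n_hom_snps: int = 2,
    seed: int = 0,
    error_model: ErrorModel | None = None,
    cds_only: bool = True,
) -> SimulationTruth:
    """Choose editing positions (transcribed-strand adenosines) and SNP
    positions (any exonic base), disjoint, and record them as ground truth."""
    rng = np.random.default_rng(seed)
    levels = np.broadcast_to(np.asarray(levels, dtype=float), (n_editing,))
    if np.any((levels < 0) | (levels > 1)):
        raise ValueError("editing levels must lie in [0, 1]")

    eligible_a = []  # (chrom, genomic position, strand): transcript base is A
    exonic = []
    for m in models:
        gpos = m.genomic_positions()
        tx_seq = m.transcript_seq(genome)
        lo, hi = (m.cds_transcript_interval() or (1, m.transcript_length))
        for k in range(m.transcript_length):
            g = int(gpos[k])
            exonic.append((m.chrom, g))
            in_cds = lo <= k + 1 <= hi
            if tx_seq[k] == "A" and (in_cds or not cds_only):
                eligible_a.append((m.chrom, g, m.strand))
    if len(eligible_a) < n_editing:
        raise ValueError(
            f"only {len(eligible_a)} eligible adenosines for {n_editing} sites"
        )
    picked = rng.choice(len(eligible_a), size=n_editing, replace=False)
    editing = [
        EditingSite(*eligible_a[i], level=float(lv)) for i, lv in zip(picked, levels)
    ]
    taken = {(e.chrom, e.position) for e in editing}

    snp_pool = [p for p in dict.fromkeys(exonic) if p not in taken]
    n_snps = n_het_snps + n_hom_snps
    if len(snp_pool) < n_snps:
        raise ValueError("not enough exonic positions for requested SNPs")
    snp_idx = rng.choice(len(snp_pool), size=n_snps, replace=False)
    snps = []
    for j, i in enumerate(snp_idx):
        chrom, pos = snp_pool[i]
        ref = genome[chrom].base(pos)
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        snps.append(
            PlantedSnp(chrom, pos, ref, alt, "het" if j < n_het_snps else "hom")
        )
    return SimulationTruth(
        genome=genome,
        models=models,
        editing_sites=editing,
        snps=snps,
        error_model=error_model or ErrorModel(),
        seed=seed,
    )


def _apply_errors(bases: list, rng, rate: float) -> None:
    hits = np.nonzero(rng.random(len(bases)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != bases[i]]
        bases[i] = choices[rng.integers(3)]


def _genome_record(
    model, tx_start0, bases_tx, phred, tx_orient, read_id, paired, mate, strand_override=None
) -> AlignmentRecord:
    """Place transcript-orientation read bases as a spliced genome record."""
    gpos = model.genomic_positions()
    span = gpos[tx_start0 : tx_start0 + len(bases_tx)]
    bases = "".join(bases_tx)
    quals = [phred] * len(bases_tx)
    if model.strand == "-":
        span = span[::-1]
        bases = revcomp(bases)
    strand = model.strand if tx_orient == "+" else ("-" if model.strand == "+" else "+")
    return AlignmentRecord(
        read_id=read_id,
        ref_name=model.chrom,
        start=int(span[0]),
        strand=strand_override or strand,
        blocks=_positions_to_blocks(span),
        bases=bases,
        quals=tuple(quals),
        paired=paired,
        mate=mate,
    )


def simulate_reads(
    truth: SimulationTruth,
    mean_coverage: float = 50,
    read_len: int = 50,
    paired: bool = False,
    stranded: bool = True,
    seed: int = 0,
) -> list[AlignmentRecord]:
    """Draw reads from each transcript with planted editing, SNPs and errors.

    At every planted editing site each covering read independently carries
    the edited base with probability equal to the site's level, before
    sequencing errors are injected at the error model's miscall rate.
    Heterozygous SNPs segregate per fragment (one of two haplotypes),
    homozygous-alternate ones appear on every read.
    """
    rng = np.random.default_rng(seed)
    eps = truth.error_model.miscall_rate
    phred = truth.error_model.phred
    records = []
    edit_by_pos = {(e.chrom, e.position): e.level for e in truth.editing_sites}
    snp_by_pos = {(s.chrom, s.position): s for s in truth.snps}

    for model in truth.models:
        if read_len > model.transcript_length:
            raise ValueError(
                f"read length {read_len} exceeds transcript {model.transcript_id}"
            )
        gpos = model.genomic_positions()
        tx_seq = list(model.transcript_seq(truth.genome))
        edit_tx = {}  # 0-based transcript index -> level
        snp_tx = {}  # 0-based transcript index -> (alt on transcript strand, genotype)
        for k in range(model.transcript_length):
            key = (model.chrom, int(gpos[k]))
            if key in edit_by_pos:
                edit_tx[k] = edit_by_pos[key]
            if key in snp_by_pos:
                s = snp_by_pos[key]
                alt = s.alt if model.strand == "+" else _COMP[s.alt]
                snp_tx[k] = (alt, s.genotype)

        per_read = read_len * (2 if paired else 1)
        n_frags = max(1, round(mean_coverage * model.transcript_length / per_read))
        for i in range(n_frags):
            hap = int(rng.integers(2))
            if paired:
                frag_len = min(
                    model.transcript_length,
                    2 * read_len + int(rng.integers(0, 51)),
                )
                fs = int(rng.integers(0, model.transcript_length - frag_len + 1))
                mate_specs = [
                    (fs, "+", 1),
                    (fs + frag_len - read_len, "-", 2),
                ]
            else:
                fs = int(rng.integers(0, model.transcript_length - read_len + 1))
                mate_specs = [(fs, "+", 1)]
            flip = (not stranded) and rng.random() < 0.5
            for start0, orient, mate in mate_specs:
                bases = tx_seq[start0 : start0 + read_len].copy()
                for k, (alt, genotype) in snp_tx.items():
                    if start0 <= k < start0 + read_len and (
                        genotype == "hom" or hap == 1
                    ):
                        bases[k - start0] = alt
                for k, level in edit_tx.items():
                    if start0 <= k < start0 + read_len and rng.random() < level:
                        bases[k - start0] = "G"
                _apply_errors(bases, rng, eps)
                if flip:
                    orient = "-" if orient == "+" else "+"
                records.append(
                    _genome_record(
                        model, start0, bases, phred, orient,
                        f"{model.transcript_id}|{i}", paired, mate,
                    )
                )
    return records


def simulate_dna_reads(
    truth: SimulationTruth,
    mean_coverage: float = 30,
    read_len: int = 100,
    seed: int = 0,
) -> list[AlignmentRecord]:
    """Genomic (exome-like) reads: SNPs segregate, editing never appears."""
    rng = np.random.default_rng(seed)
    eps = truth.error_model.miscall_rate
    phred = truth.error_model.phred
    snp_by_pos = {(s.chrom, s.position): s for s in truth.snps}
    records = []
    for chrom, gs in truth.genome.items():
        L = len(gs)
        n_reads = max(1, round(mean_coverage * L / read_len))
        for i in range(n_reads):
            start = int(rng.integers(1, L - read_len + 2))
            bases = list(gs.seq[start - 1 : start - 1 + read_len])
            hap = int(rng.integers(2))
            for j in range(read_len):
                s = snp_by_pos.get((chrom, start + j))
                if s is not None and (s.genotype == "hom" or hap == 1):
                    bases[j] = s.alt
            _apply_errors(bases, rng, eps)
            records.append(
                AlignmentRecord(
                    read_id=f"dna|{chrom}|{i}",
                    ref_name=chrom,
                    start=start,
                    strand="+" if rng.random() < 0.5 else "-",
                    blocks=((start, start + read_len - 1),),
                    bases="".join(bases),
                    quals=tuple([phred] * read_len),
                )
            )
    return records


def add_paralog_decoy(
    genome,
    models,
    source_index: int = 0,
    n_mismatches: int = 3,
    seed: int = 0,
    spacer: int = 100,
):
    """Append an intronless near-copy of one transcript to the genome.

    The copy differs from the source cDNA at ``n_mismatches`` positions,
    chosen where the transcript has G and the decoy gets A — so reads
    misassigned to the decoy fake an A-to-G editing pattern there.  Returns
    the extended genome, the model list with the decoy gene appended, and a
    DecoyInfo describing the copy.
    """
    rng = np.random.default_rng(seed)
    source = models[source_index]
    cdna = source.transcript_seq(genome)
    lo, hi = source.cds_transcript_interval() or (1, len(cdna))
    g_positions = [k for k in range(lo - 1, hi) if cdna[k] == "G"]
    if len(g_positions) < n_mismatches:
        raise ValueError("source CDS has too few G bases for the requested decoy")
    picked = sorted(rng.choice(g_positions, size=n_mismatches, replace=False))
    decoy_seq = list(cdna)
    for k in picked:
        decoy_seq[k] = "A"

    gs = genome[source.chrom]
    pad = "".join(rng.choice(_BASES, size=spacer))
    start = len(gs.seq) + spacer + 1
    new_seq = gs.seq + pad + "".join(decoy_seq)
    new_genome = dict(genome)
    new_genome[source.chrom] = GenomeSequence(source.chrom, new_seq)

    decoy_model = GeneModel(
        transcript_id=f"decoy_{source.transcript_id}",
        gene_name=f"decoy_{source.gene_name}",
        chrom=source.chrom,
        strand="+",
        exons=((start, start + len(cdna) - 1),),
        cds_start=start + lo - 1,
        cds_end=start + hi - 1,
    )
    info = DecoyInfo(
        chrom=source.chrom,
        start=start,
        end=start + len(cdna) - 1,
        source_transcript_id=source.transcript_id,
        mismatch_positions=tuple(start + k for k in picked),
    )
    return new_genome, models + [decoy_model], info


def misaligned_copy(records, models, decoy: DecoyInfo, fraction: float, seed: int = 0):
    """Emulate a genome aligner that sends a fraction of the source gene's
    reads to the intronless decoy locus instead of their true spliced origin.

    Returned records stand in for the genome-alignment stream; the input
    records (true placements) play the transcriptome projections.
    """
    rng = np.random.default_rng(seed)
    by_tx = {m.transcript_id: m for m in models}
    source = by_tx[decoy.source_transcript_id]
    g_to_tx = {int(g): k for k, g in enumerate(source.genomic_positions())}
    out = []
    for rec in records:
        if (
            rec.read_id.split("|")[0] != decoy.source_transcript_id
            or rng.random() >= fraction
        ):
            out.append(rec)
            continue
        genomic = np.concatenate([np.arange(s, e + 1) for s, e in rec.blocks])
        tx_idx = sorted(g_to_tx[int(g)] for g in genomic)
        tx0 = tx_idx[0]
        bases = rec.bases if source.strand == "+" else revcomp(rec.bases)
        quals = rec.quals if source.strand == "+" else rec.quals[::-1]
        tx_orient = "+" if rec.strand == source.strand else "-"
        out.append(
            AlignmentRecord(
                read_id=rec.read_id,
                ref_name=decoy.chrom,
                start=decoy.start + tx0,
                strand=tx_orient,
                blocks=((decoy.start + tx0, decoy.start + tx0 + len(bases) - 1),),
                bases=bases,
                quals=quals,
                paired=rec.paired,
                mate=rec.mate,
            )
        )
    return out


def as_projected(records) -> list[ProjectedAlignment]:
    """View truth-placed records as transcriptome-projection results (the
    simulator emits reads at their correct genomic placement, which is what
    projecting a correct transcriptome alignment yields)."""
    return [
        ProjectedAlignment(
            read_id=r.read_id,
            chrom=r.ref_name,
            strand=r.strand,
            blocks=r.blocks,
            bases=r.bases,
            quals=r.quals,
            mate=r.mate,
            unique=r.unique,
        )
        for r in records
    ]
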