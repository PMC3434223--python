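"""End-to-end orchestration: prefilter → concordance → pileup → spectrum →
call → annotate → optional DNA support, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field

from . import __version__
from .caller import CallerConfig, call_candidates
from .dna import validate_candidates
from .io import write_candidate_table
from .mapping import concordance_filter, prefilter_reads
from .spectrum import build_spectrum, pileup_alignments


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    version: str = __version__
    config: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> sha256 digest
    seed: int | None = None
    n_reads_in: int = 0
    n_reads_used: int = 0
    n_sites: int = 0
    n_candidates: int = 0
    timestamp: str = ""

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_detect(
    config: CallerConfig,
    genome,
    gene_models,
    rna_records,
    snp_table=None,
    projected=None,
    dna_records=None,
    reference_transcripts=None,
    repeat_index=None,
    max_n: int = 2,
    min_mean_quality: float = 20.0,
    dna_min_quality: int = 30,
    dna_min_reads: int = 5,
    seed: int | None = None,
    input_digests=None,
):
    """Run the whole detection cascade on in-memory inputs.

    When ``projected`` (transcriptome-projected alignments) is given, the
    genome alignments are concordance-filtered against them first.  When
    ``dna_records`` is given, surviving candidates get DNA evidence and LLR
    support.  Returns (candidates, spectrum, manifest).
    """
    manifest = RunManifest(
        config={
            **asdict(config),
            "max_n": max_n,
            "min_mean_quality": min_mean_quality,
            "dna_min_quality": dna_min_quality,
            "dna_min_reads": dna_min_reads,
        },
        inputs=dict(input_digests or {}),
        seed=seed,
        n_reads_in=len(rna_records),
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    records = prefilter_reads(rna_records, max_n=max_n, min_mean_quality=min_mean_quality)
    if projected is not None:
        records = concordance_filter(projected, records)
    manifest.n_reads_used = len(records)

    sites = pileup_alignments(
        records, genome, min_quality=config.min_base_quality, end_trim=config.end_trim
    )
    manifest.n_sites = len(sites)
    spectrum = build_spectrum(sites, snp_table, min_quality=config.min_base_quality)
    candidates = call_candidates(
        sites,
        spectrum,
        snp_table,
        gene_models,
        config,
        genome=genome,
        reference_transcripts=reference_transcripts,
        repeat_index=repeat_index,
    )
    if dna_records is not None:
        validate_candidates(
            candidates,
            dna_records,
            genome,
            rna_records=records,
            min_quality=dna_min_quality,
            min_reads=dna_min_reads,
        )
    manifest.n_candidates = len(candidates)
    return candidates, spectrum, manifest


def config_header_lines(config: CallerConfig, manifest: RunManifest | None = None):
    """'#'-prefixed metadata lines echoed into candidate-table output."""
    lines = [f"editcall {__version__}"]
    lines += [f"{k}={v}" for k, v in sorted(asdict(config).items())]
    if manifest is not None and manifest.seed is not None:
        lines.append(f"seed={manifest.seed}")
    return lines


def write_outputs(candidates, config, manifest, out_path, manifest_path=None, with_dna=False):
    write_candidate_table(
        candidates,
        out_path,
        with_dna=with_dna,
        header_lines=config_header_lines(config, manifest),
    )
    if manifest_path is not None:
        manifest.write(manifest_path)
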