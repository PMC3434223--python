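"""Bundled reference tables from published A-to-I editing surveys.

Two candidate tables ship with the package, as printed in the original
reports: a pooled human-brain survey (unstranded 2x50 bp RNA-seq, 19 coding
candidates) and a single-individual spinal-cord survey (stranded 2x101 bp
RNA-seq with matched exome, 15 coding candidates).  Base counts are given as
``bcr_*`` (RNA-seq, after quality filtering), ``bcrf_*`` (before filtering)
and, for the spinal-cord set, ``bce_*`` (exome, Q>=30, duplicates removed).
They serve as worked inputs for re-deriving editing extents, codon
consequences and the exome homozygosity rule.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .spectrum import SiteCounts


def _load(name: str) -> pd.DataFrame:
    with (resources.files("editcall") / "data" / name).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"llr": str})
    parts = df["position"].str.split(":", expand=True)
    df["chrom"] = parts[0]
    df["pos"] = parts[1].astype(int)
    return df


def load_brain_candidates() -> pd.DataFrame:
    """The 19 coding-region candidates of the pooled brain survey."""
    return _load("brain_candidates.tsv")


def load_spinal_cord_candidates() -> pd.DataFrame:
    """The 15 coding-region candidates of the spinal-cord survey, with
    matched exome base counts."""
    return _load("spinal_cord_candidates.tsv")


def row_site_counts(row, which: str = "bcr") -> SiteCounts:
    """SiteCounts built from one table row's printed count columns.

    ``which`` selects ``bcr`` (filtered RNA), ``bcrf`` (raw RNA) or ``bce``
    (exome) columns; raw and filtered tallies are set to the same vector
    since the table prints one snapshot per filtering stage.
    """
    counts = np.array(
        [int(row[f"{which}_{b}"]) for b in ("a", "c", "g", "t")], dtype=np.int64
    )
    return SiteCounts(
        chrom=row["chrom"],
        position=int(row["pos"]),
        ref_base=row["ref"],
        counts_filtered=counts,
        counts_raw=counts.copy(),
    )
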