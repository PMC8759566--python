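"""Shared domain containers used across the pipeline.

The pipeline's in-memory currency is a :class:`CountMatrix` — an integer
miRNA-by-sample count table plus per-sample metadata (tissue, study) — together
with light dataclasses for reference miRNA sequences and sequencing reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TISSUES = ("pCRC", "nCR", "mLi", "nLi", "mLu", "nLu", "PM")

#: metastatic site -> tumour-adjacent normal tissue (PM has none)
SITE_NORMAL = {"mLi": "nLi", "mLu": "nLu", "PM": None}

ALPHABET = "ACGT"


@dataclass(frozen=True)
class MiRNAReference:
    """A mature miRNA reference sequence.

    clade_tag distinguishes the target clade (the species under study) from
    contaminant clades, which supports contamination screening during QC.
    celltype_label marks miRNAs expressed predominantly in one cell type
    (e.g. hepatocytes for Mir-122), or ``None``.
    """

    annotation_id: str
    mature_seq: str
    clade_tag: str = "target"
    celltype_label: str | None = None

    def __post_init__(self) -> None:
        if not (18 <= len(self.mature_seq) <= 25):
            raise ValueError(
                f"{self.annotation_id}: mature sequence length "
                f"{len(self.mature_seq)} outside [18, 25]"
            )
        if set(self.mature_seq) - set(ALPHABET):
            raise ValueError(f"{self.annotation_id}: non-ACGT characters")


@dataclass
class ReadRecord:
    """A sequencing read with per-base Phred quality scores."""

    read_id: str
    seq: str
    qual: np.ndarray  # integer Phred scores, same length as seq

    def __post_init__(self) -> None:
        self.qual = np.asarray(self.qual, dtype=int)
        if len(self.seq) != len(self.qual):
            raise ValueError(f"{self.read_id}: seq/qual length mismatch")

    def __len__(self) -> int:
        return len(self.seq)

    def qual_string(self) -> str:
        return "".join(chr(q + 33) for q in self.qual)


@dataclass
class CountMatrix:
    """Integer miRNA x sample counts with sample metadata.

    counts: DataFrame, rows = miRNA annotation (group) ids, columns = sample ids.
    meta:   DataFrame indexed by sample id with columns 'tissue' and 'study'.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not set(self.counts.columns) <= set(self.meta.index):
            missing = set(self.counts.columns) - set(self.meta.index)
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if "tissue" not in self.meta.columns:
            raise ValueError("meta must have a 'tissue' column")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("negative counts")

    @property
    def annotations(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def tissue_samples(self, tissue: str) -> list[str]:
        return list(self.meta.index[self.meta["tissue"] == tissue].intersection(
            self.counts.columns))

    def subset(self, tissues: list[str]) -> "CountMatrix":
        samples = [s for s in self.samples if self.meta.loc[s, "tissue"] in tissues]
        return CountMatrix(self.counts[samples], self.meta.loc[samples])

    def rpm(self) -> pd.DataFrame:
        """Per-sample reads-per-million over miRNA-assigned reads."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            zero = list(totals.index[totals == 0])
            raise ValueError(f"all-zero samples: {zero}")
        return self.counts / totals * 1e6

    def write(self, counts_path: str | Path, meta_path: str | Path) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="annotation_id")
        self.meta.to_csv(meta_path, sep="\t", index_label="sample_id")

    @classmethod
    def read(cls, counts_path: str | Path, meta_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        return cls(counts, meta)


@dataclass
class SyntheticTruth:
    """Planted ground truth of a simulation, for recovery testing.

    met_de / bg_de are sets of (miRNA, site, sign) triples; sign is +1/-1.
    Background entries mean the miRNA differs between the site's organ and
    colorectal tissue for composition reasons, not because of metastasis.
    """

    met_de: set[tuple[str, str, int]] = field(default_factory=set)
    bg_de: set[tuple[str, str, int]] = field(default_factory=set)
    celltype_specific: dict[str, str] = field(default_factory=dict)
    suppressed_gene_sets: set[str] = field(default_factory=set)

    def met_mirnas(self, site: str) -> dict[str, int]:
        return {m: s for m, st, s in self.met_de if st == site}

    def bg_mirnas(self, site: str) -> dict[str, int]:
        return {m: s for m, st, s in self.bg_de if st == site}
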